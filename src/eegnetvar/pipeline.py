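"""End-to-end orchestration: preprocess -> connectivity -> graph metrics ->
variability -> group statistics.

The central entry points are :func:`analyze_patient` (five recordings in,
one variability profile out), :func:`analyze_cohort` (cohort in, tidy
patient table out) and :func:`run_pipeline` (cohort in, results directory
with tables, QC report and run manifest out).  Recordings that fail the
30%-bad-epochs rule exclude their patient from group statistics; the
exclusion is recorded in the QC report, never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import session_connectivity
from .graph_metrics import network_metrics
from .montage import CHANNELS
from .preprocessing import (
    RawRecording,
    UnusableRecordingError,
    preprocess_recording,
    qc_report,
)
from .stats import (
    kendall_correlation,
    kruskal_wallis,
    pairwise_mwu_bonferroni,
    per_electrode_contrast,
    results_table,
)
from .variability import patient_variability

log = logging.getLogger("eegnetvar")

SCALAR_METRICS = ("degree_mean", "cpl", "cc", "bc_mean", "nmi_mean", "gev")
CV_METRICS = ("cv_cpl", "cv_cc", "cv_bc_mean")


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain."""

    target_fs: float = 500.0
    band: tuple[float, float] = (1.0, 45.0)
    epoch_length_s: float = 10.0
    channel_z: float = 3.0
    epoch_z: float = 5.0
    wpli_window_s: float = 2.0
    wpli_overlap_s: float = 1.0
    partition_algorithm: str = "greedy"
    partition_seed: int = 0
    cv_ddof: int = 1
    fdr_q: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.epoch_length_s < self.wpli_window_s:
            raise ValueError("epoch must be at least one wPLI window long")
        if self.partition_algorithm not in ("greedy", "louvain"):
            raise ValueError("partition_algorithm must be 'greedy' or 'louvain'")
        if self.cv_ddof not in (0, 1):
            raise ValueError("cv_ddof must be 0 (population) or 1 (sample)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written alongside every results directory."""

    config_hash: str
    inputs: list[str]
    stages: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, out_dir: Path) -> None:
        (out_dir / "manifest.json").write_text(
            json.dumps(asdict(self), indent=2)
        )


def analyze_patient(
    sessions: list[RawRecording],
    config: PipelineConfig | None = None,
):
    """Full single-patient analysis of five session recordings.

    Returns (PatientVariability, list of per-session NetworkMetrics,
    list of QC dicts).  Raises UnusableRecordingError when any session
    fails the 30% rule.
    """
    config = config or PipelineConfig()
    if len(sessions) != 5:
        raise ValueError(f"expected 5 sessions, got {len(sessions)}")

    patterns, metrics, qc = [], [], []
    for rec in sessions:
        ep = preprocess_recording(
            rec, target_fs=config.target_fs, band=config.band,
            epoch_length_s=config.epoch_length_s,
            channel_z=config.channel_z, epoch_z=config.epoch_z,
        )
        qc.append(qc_report(ep))
        kept = ep.kept()  # raises UnusableRecordingError if needed
        cm = session_connectivity(
            kept, ep.fs, tuple(ep.channel_names),
            window_s=config.wpli_window_s, overlap_s=config.wpli_overlap_s,
            band=config.band,
        )
        patterns.append(cm)
        metrics.append(network_metrics(cm))

    var = patient_variability(
        metrics, patterns, seed=config.partition_seed,
        algorithm=config.partition_algorithm, ddof=config.cv_ddof,
    )
    return var, metrics, qc


def _patient_row(pid: str, group: str, crsr: int, var, metrics) -> dict:
    row = {
        "patient_id": pid, "group": group, "crsr": crsr,
        "degree_mean": float(np.mean([m.degree.mean() for m in metrics])),
        "cpl": float(np.mean([m.cpl for m in metrics])),
        "cc": float(np.mean([m.cc for m in metrics])),
        "bc_mean": float(np.mean([m.bc_mean for m in metrics])),
        "nmi_mean": var.nmi_mean,
        "gev": var.gev,
        "cv_cpl": var.cv_cpl,
        "cv_cc": var.cv_cc,
        "cv_bc_mean": var.cv_bc_mean,
    }
    for k, v in enumerate(var.nmi_series):
        row[f"nmi_t{k + 1}{k + 2}"] = float(v)
    for ch, v in zip(var.channel_names, var.cv_degree):
        row[f"cv_degree_{ch}"] = float(v)
    for ch, v in zip(var.channel_names, var.cv_bc):
        row[f"cv_bc_{ch}"] = float(v)
    return row


def analyze_cohort(
    cohort,
    config: PipelineConfig | None = None,
    meta: pd.DataFrame | None = None,
):
    """Analyze a whole cohort into a tidy patient table.

    ``cohort`` is either a list of SyntheticPatient objects or a mapping
    patient_id -> list of 5 RawRecording (then ``meta`` must carry group
    and crsr per patient_id).  Returns (table, qc_events, excluded).
    """
    config = config or PipelineConfig()
    if isinstance(cohort, dict):
        if meta is None:
            raise ValueError("meta table required with a plain session mapping")
        items = [
            (pid, str(meta.set_index("patient_id").loc[pid, "group"]),
             int(meta.set_index("patient_id").loc[pid, "crsr"]), recs)
            for pid, recs in cohort.items()
        ]
    else:
        items = [(p.patient_id, p.group, p.crsr, p.sessions) for p in cohort]

    rows, qc_events, excluded = [], [], []
    for pid, group, crsr, sessions in items:
        try:
            var, metrics, qc = analyze_patient(sessions, config)
        except UnusableRecordingError as err:
            log.warning("excluding patient %s: %s", pid, err)
            excluded.append({"patient_id": pid, "reason": str(err)})
            continue
        qc_events.extend(qc)
        rows.append(_patient_row(pid, group, crsr, var, metrics))
    table = pd.DataFrame(rows)
    return table, qc_events, excluded


def run_group_statistics(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict[str, pd.DataFrame]:
    """The full contrast battery on a cohort table.

    Returns tidy tables: omnibus Kruskal-Wallis and pairwise Mann-Whitney
    with Bonferroni for every scalar metric and CV metric; per-electrode
    CV contrasts (degree and betweenness) with BH-FDR per group pair; and
    Kendall tau-b of the CV metrics against the CRS-R score.
    """
    config = config or PipelineConfig()
    omnibus, pairwise, correlations, electrode = [], [], [], []

    for metric in SCALAR_METRICS + CV_METRICS:
        if metric not in table.columns:
            continue
        omnibus.append(kruskal_wallis(table, metric))
        pairwise.extend(pairwise_mwu_bonferroni(table, metric, alpha=config.alpha))

    groups = list(dict.fromkeys(table["group"]))
    import itertools

    for prefix in ("cv_degree", "cv_bc"):
        for a, b in itertools.combinations(groups, 2):
            res = per_electrode_contrast(
                table, prefix, CHANNELS, groups=(a, b), q=config.fdr_q,
            )
            for r in res:
                r.extra["pair"] = f"{a} vs {b}"
                r.extra["metric"] = prefix
            electrode.extend(res)

    for metric in CV_METRICS:
        correlations.append(kendall_correlation(table, metric))

    return {
        "omnibus": results_table(omnibus),
        "pairwise": results_table(pairwise),
        "per_electrode": results_table(electrode),
        "correlations": results_table(correlations),
    }


def run_pipeline(
    cohort,
    out_dir: Path | str,
    config: PipelineConfig | None = None,
    meta: pd.DataFrame | None = None,
    inputs: list[str] | None = None,
) -> Path:
    """Run the whole analysis and write a results directory.

    Writes cohort_table.csv, the four statistics tables, qc_report.json,
    the serialized config and a run manifest.  Patients excluded by QC are
    listed in the QC report and absent from the statistics.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.hash(),
        inputs=inputs or [],
        started=datetime.now(timezone.utc).isoformat(),
    )

    table, qc_events, excluded = analyze_cohort(cohort, config, meta=meta)
    manifest.stages["analysis"] = f"ok ({len(table)} patients)"
    table.to_csv(out_dir / "cohort_table.csv", index=False)
    (out_dir / "qc_report.json").write_text(json.dumps(
        {"recordings": qc_events, "excluded_patients": excluded}, indent=2))

    group_sizes = table.groupby("group").size() if not table.empty else pd.Series(dtype=int)
    if table.empty or (group_sizes < 2).any():
        manifest.stages["statistics"] = (
            "skipped (fewer than 2 usable patients in some group)")
    else:
        stats_tables = run_group_statistics(table, config)
        for name, df in stats_tables.items():
            df.to_csv(out_dir / f"stats_{name}.csv", index=False)
        manifest.stages["statistics"] = "ok"

    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out_dir)
    return out_dir
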