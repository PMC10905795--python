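"""Reading and writing session recordings and cohort metadata.

Recordings are exchanged as BrainVision triplets (.vhdr/.vmrk text headers
plus IEEE float32 multiplexed .eeg) or EDF; reading goes through MNE.
Cohort metadata travels as CSV and the latent ground-truth coupling
matrices of synthetic cohorts as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS
from .preprocessing import RawRecording

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """\
Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0
"""


def write_brainvision(rec: RawRecording, path: Path | str) -> Path:
    """Write a recording as a BrainVision triplet; returns the .vhdr path.

    Data are stored multiplexed IEEE float32 in µV (unit resolution 1).
    """
    path = Path(path)
    if path.suffix == ".vhdr":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.name

    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.montage)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=rec.n_channels,
        sampling_interval_us=int(round(1e6 / rec.fs)),
        channel_lines=channel_lines,
    )
    (path.with_suffix(".vhdr")).write_text(vhdr, encoding="utf-8")
    (path.with_suffix(".vmrk")).write_text(
        _VMRK_TEMPLATE.format(stem=stem), encoding="utf-8"
    )
    rec.data.T.astype("<f4").tofile(path.with_suffix(".eeg"))
    return path.with_suffix(".vhdr")


def read_recording(
    path: Path | str,
    fmt: str | None = None,
    session_label: str = "T1",
    patient_id: str = "",
) -> RawRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into a RawRecording.

    Channel names are matched case-insensitively against the canonical
    montage and reordered to it; extra channels are dropped with a warning
    and missing ones are an error.
    """
    import warnings

    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"cannot infer format of {path}; pass fmt=")

    lower_map = {name.lower(): name for name in raw.ch_names}
    missing = [c for c in CHANNELS if c.lower() not in lower_map]
    if missing:
        raise ValueError(
            f"{path.name}: missing {len(missing)} montage channels: {missing}"
        )
    extra = [n for n in raw.ch_names if n.lower() not in {c.lower() for c in CHANNELS}]
    if extra:
        warnings.warn(f"{path.name}: dropping extra channels {extra}", stacklevel=2)
    picks = [lower_map[c.lower()] for c in CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # MNE uses volts internally
    return RawRecording(
        data=data, fs=float(raw.info["sfreq"]),
        session_label=session_label, patient_id=patient_id,
    )


def write_cohort(cohort, out_dir: Path | str) -> Path:
    """Write a synthetic cohort: recordings, metadata CSV, ground-truth JSON.

    Layout: ``<out_dir>/<patient_id>/<session>.vhdr`` plus
    ``cohort.csv`` and ``ground_truth.json`` at the top level.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, truth = [], {}
    for patient in cohort:
        pdir = out_dir / patient.patient_id
        for rec in patient.sessions:
            write_brainvision(rec, pdir / rec.session_label)
        rows.append({
            "patient_id": patient.patient_id,
            "group": patient.group,
            "crsr": patient.crsr,
        })
        truth[patient.patient_id] = [m.tolist() for m in patient.ground_truth]
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
    return out_dir


def read_cohort(in_dir: Path | str) -> tuple[pd.DataFrame, dict[str, list[RawRecording]]]:
    """Read a cohort directory written by :func:`write_cohort`.

    Returns the metadata table and a mapping patient_id -> 5 recordings in
    session order.
    """
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "cohort.csv")
    sessions: dict[str, list[RawRecording]] = {}
    for _, row in meta.iterrows():
        pid = str(row["patient_id"])
        recs = []
        for label in ("T1", "T2", "T3", "T4", "T5"):
            vhdr = in_dir / pid / f"{label}.vhdr"
            recs.append(read_recording(vhdr, session_label=label, patient_id=pid))
        sessions[pid] = recs
    return meta, sessions


def save_matrix_csv(values: np.ndarray, channel_names, path: Path | str) -> None:
    """Square connectivity matrix as CSV with a channel-name header."""
    pd.DataFrame(values, index=list(channel_names),
                 columns=list(channel_names)).to_csv(path)
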