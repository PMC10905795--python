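"""Nonparametric group contrasts and consciousness-score correlations.

The cohort table has one row per patient (group label, CRS-R score, scalar
metrics, per-electrode metric columns).  The contrast battery:
Kruskal-Wallis omnibus across the three diagnosis groups; pairwise
Mann-Whitney U tests with Bonferroni correction over the three comparisons;
per-electrode contrasts with Benjamini-Hochberg FDR control at Q = 0.05
across the 30 electrodes; Kendall tau-b correlation of variability metrics
with the CRS-R score.  All tests are two-sided and deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_COL = "group"
SCORE_COL = "crsr"


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    test: str
    contrast: str
    statistic: float
    p_raw: float
    p_adjusted: float
    correction: str = "none"
    n_per_group: dict[str, int] = field(default_factory=dict)
    significant: bool | None = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "test": self.test,
            "contrast": self.contrast,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "correction": self.correction,
            "significant": self.significant,
        }
        row.update({f"n_{k}": v for k, v in self.n_per_group.items()})
        row.update(self.extra)
        return row


def _group_samples(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    out = {}
    for label, sub in table.groupby(GROUP_COL, sort=False):
        out[str(label)] = sub[metric].to_numpy(dtype=float)
    return out


def kruskal_wallis(table: pd.DataFrame, metric: str) -> TestResult:
    """Omnibus rank test of ``metric`` across all diagnosis groups."""
    samples = _group_samples(table, metric)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    small = [g for g, x in samples.items() if x.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    h, p = sps.kruskal(*samples.values())
    return TestResult(
        test="kruskal_wallis", contrast=f"{metric} ~ {GROUP_COL}",
        statistic=float(h), p_raw=float(p), p_adjusted=float(p),
        n_per_group={g: int(x.size) for g, x in samples.items()},
    )


def pairwise_mwu_bonferroni(
    table: pd.DataFrame, metric: str, alpha: float = 0.05
) -> list[TestResult]:
    """Two-sided Mann-Whitney U for every group pair, Bonferroni-corrected.

    The adjusted p-value is min(1, m * p) with m the number of pairwise
    comparisons (three for the three diagnosis groups).
    """
    samples = _group_samples(table, metric)
    if any(x.size == 0 for x in samples.values()):
        raise ValueError("empty group")
    pairs = list(itertools.combinations(samples, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        u, p = sps.mannwhitneyu(samples[a], samples[b],
                                alternative="two-sided", method="auto")
        p_adj = min(1.0, m * float(p))
        results.append(TestResult(
            test="mann_whitney_u", contrast=f"{metric}: {a} vs {b}",
            statistic=float(u), p_raw=float(p), p_adjusted=p_adj,
            correction="bonferroni",
            n_per_group={a: int(samples[a].size), b: int(samples[b].size)},
            significant=bool(p_adj < alpha),
        ))
    return results


def per_electrode_contrast(
    table: pd.DataFrame,
    electrode_metric: str,
    channel_names: tuple[str, ...],
    groups: tuple[str, ...] | None = None,
    q: float = 0.05,
) -> list[TestResult]:
    """Per-electrode between-group contrast with BH-FDR control at Q.

    ``electrode_metric`` is a column prefix (e.g. ``cv_bc``); per-electrode
    columns are ``{prefix}_{channel}``.  With two groups the test is
    Mann-Whitney U, with more it is Kruskal-Wallis; p-values are corrected
    across the electrodes by the Benjamini-Hochberg step-up procedure and
    the resulting significance mask is suitable for topographic export.
    """
    sub = table if groups is None else table[table[GROUP_COL].isin(groups)]
    cols = [f"{electrode_metric}_{ch}" for ch in channel_names]
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"missing electrode columns: {missing[:5]} ...")

    raw_p, stats_ = [], []
    for col in cols:
        samples = list(_group_samples(sub, col).values())
        if len(samples) == 2:
            s, p = sps.mannwhitneyu(samples[0], samples[1],
                                    alternative="two-sided", method="auto")
            name = "mann_whitney_u"
        else:
            s, p = sps.kruskal(*samples)
            name = "kruskal_wallis"
        raw_p.append(float(p))
        stats_.append((name, float(s)))

    reject, p_adj, _, _ = multipletests(raw_p, alpha=q, method="fdr_bh")
    n_per = {g: int(x.size) for g, x in
             _group_samples(sub, cols[0]).items()}
    results = []
    for ch, col, (name, s), p, pa, rej in zip(
            channel_names, cols, stats_, raw_p, p_adj, reject):
        results.append(TestResult(
            test=name, contrast=f"{electrode_metric} @ {ch}",
            statistic=s, p_raw=p, p_adjusted=float(pa),
            correction="fdr_bh", n_per_group=n_per,
            significant=bool(rej), extra={"electrode": ch},
        ))
    return results


def friedman_session_effect(
    session_values: np.ndarray,
) -> TestResult:
    """Friedman repeated-measures test of a session effect within a group.

    ``session_values`` is (n_patients, n_sessions); the test asks whether
    the metric differs systematically across the five daily recordings.
    Provided for fidelity with repeated-measures usage of the Friedman
    test; the between-group electrode contrast uses rank-sum tests.
    """
    session_values = np.asarray(session_values, dtype=float)
    if session_values.ndim != 2 or session_values.shape[1] < 3:
        raise ValueError("need (n_patients, >=3 sessions)")
    stat, p = sps.friedmanchisquare(*session_values.T)
    return TestResult(
        test="friedman", contrast="session effect",
        statistic=float(stat), p_raw=float(p), p_adjusted=float(p),
        n_per_group={"patients": session_values.shape[0]},
    )


def kendall_correlation(
    table: pd.DataFrame, metric: str, score: str = SCORE_COL
) -> TestResult:
    """Kendall tau-b correlation of a metric with the consciousness score."""
    x = table[metric].to_numpy(dtype=float)
    y = table[score].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 patients")
    if np.all(x == x[0]):
        raise ValueError(f"metric {metric!r} is constant; correlation undefined")
    tau, p = sps.kendalltau(x, y)
    return TestResult(
        test="kendall_tau", contrast=f"{metric} ~ {score}",
        statistic=float(tau), p_raw=float(p), p_adjusted=float(p),
        n_per_group={"patients": int(x.size)},
        extra={"tau": float(tau)},
    )


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table."""
    return pd.DataFrame([r.as_row() for r in results])
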