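"""Large-timescale network variability statistics.

A patient contributes five session connectivity patterns (T1..T5, one per
daily recording).  Variability across them is quantified three ways:

* NMI — each session pattern is partitioned into modules (greedy weighted
  modularity communities by default) and normalized mutual information is
  computed for the four neighboring session pairs; high NMI means the
  modular organization is stable across the day.
* GEV — the share of total pattern variance explained by the average
  pattern: vectorize each pattern's upper triangle p_k, let g be their
  mean, then GEV = sum_k corr(p_k, g)^2 ||p_k||^2 / sum_k ||p_k||^2.
* CV — the relative coefficient of variation (sample SD / mean) of each
  network statistic over the five sessions, both for scalar metrics (path
  length, clustering, mean betweenness) and per electrode (degree and
  betweenness vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .graph_metrics import NetworkMetrics, WeightedGraph


@dataclass
class ModulePartition:
    """Assignment of every node to exactly one module (ids contiguous from 1)."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(1, ids.size + 1)):
            # relabel to contiguous ids starting at 1, preserving order of
            # first appearance
            remap = {old: new for new, old in enumerate(dict.fromkeys(a.tolist()), 1)}
            a = np.array([remap[x] for x in a])
        self.assignment = a

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())


@dataclass
class PatientVariability:
    """All variability statistics for one patient's five sessions."""

    nmi_series: np.ndarray  # 4 values: T1-T2, T2-T3, T3-T4, T4-T5
    nmi_mean: float
    gev: float
    cv_cpl: float
    cv_cc: float
    cv_bc_mean: float
    cv_degree: np.ndarray  # per channel
    cv_bc: np.ndarray  # per channel
    channel_names: tuple[str, ...] = ()


def partition_modules(
    cm: ConnectivityMatrix | np.ndarray,
    seed: int = 0,
    algorithm: str = "greedy",
) -> ModulePartition:
    """Community structure of a session pattern by modularity maximization.

    ``algorithm`` is "greedy" (Clauset-Newman-Moore, deterministic) or
    "louvain" (seeded).  A degenerate single-module output is permitted.
    """
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, float)
    if values.size == 0:
        raise ValueError("empty graph")
    G = WeightedGraph(values).to_networkx()
    if algorithm == "greedy":
        communities = nx.community.greedy_modularity_communities(G, weight="weight")
    elif algorithm == "louvain":
        communities = nx.community.louvain_communities(G, weight="weight", seed=int(seed))
    else:
        raise ValueError(f"unknown partition algorithm {algorithm!r}")
    assignment = np.zeros(values.shape[0], dtype=int)
    for mid, nodes in enumerate(communities, start=1):
        for node in nodes:
            assignment[node] = mid
    if np.any(assignment == 0):  # isolated nodes not covered by communities
        nxt = assignment.max()
        for i in np.flatnonzero(assignment == 0):
            nxt += 1
            assignment[i] = nxt
    return ModulePartition(assignment)


def nmi(a: ModulePartition, b: ModulePartition) -> float:
    """Normalized mutual information between two module partitions.

        NMI(A, B) = -2 sum_ij N_ij log(N_ij N / (N_i N_j))
                    / [sum_i N_i log(N_i / N) + sum_j N_j log(N_j / N)]

    where N_ij is the contingency table of shared nodes, N_i / N_j the
    module sizes and N the node count; 0*log(0) terms are 0.  Ranges from 0
    (independent partitions) to 1 (identical partitions); symmetric.
    """
    if a.n_nodes != b.n_nodes:
        raise ValueError("partitions must cover the same node set")
    n = a.n_nodes
    ca, cb = a.n_modules, b.n_modules
    table = np.zeros((ca, cb))
    for ia, ib in zip(a.assignment, b.assignment):
        table[ia - 1, ib - 1] += 1
    ni = table.sum(axis=1)
    nj = table.sum(axis=0)

    pos = table > 0
    logterm = np.zeros_like(table)
    logterm[pos] = np.log(table[pos] * n / np.outer(ni, nj)[pos])
    num = -2.0 * np.sum(table * logterm)
    den = np.sum(ni * np.log(ni / n)) + np.sum(nj * np.log(nj / n))
    if den == 0:
        # both partitions are a single module: identical by definition
        return 1.0
    if num == 0:
        return 0.0
    val = num / den
    if val > 1.0 - 1e-12:  # identical partitions, up to float rounding
        return 1.0
    return float(min(max(val, 0.0), 1.0))


def session_nmi(
    patterns: list[ConnectivityMatrix],
    seed: int = 0,
    algorithm: str = "greedy",
) -> tuple[np.ndarray, float]:
    """NMI of the four neighboring session pairs and its mean."""
    if len(patterns) != 5:
        raise ValueError(f"expected 5 session patterns, got {len(patterns)}")
    parts = [partition_modules(p, seed=seed, algorithm=algorithm) for p in patterns]
    series = np.array([nmi(parts[k], parts[k + 1]) for k in range(4)])
    return series, float(series.mean())


def gev(patterns: list[ConnectivityMatrix | np.ndarray]) -> float:
    """Global explained variance of the average connectivity pattern.

    Patterns are vectorized (upper triangle), the template g is their mean,
    and GEV = sum_k corr(p_k, g)^2 ||p_k||^2 / sum_k ||p_k||^2, the
    norm-weighted squared correlation used for microstate templates.
    """
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    vecs = []
    for p in patterns:
        v = p.values if isinstance(p, ConnectivityMatrix) else np.asarray(p, float)
        iu = np.triu_indices(v.shape[0], k=1)
        vecs.append(v[iu])
    P = np.asarray(vecs)
    if np.any(P.std(axis=1) == 0):
        raise ValueError("constant (zero-variance) pattern: GEV undefined")
    template = P.mean(axis=0)
    if template.std() == 0:
        raise ValueError("average pattern is constant: GEV undefined")
    corrs = np.array([np.corrcoef(p, template)[0, 1] for p in P])
    norms2 = np.sum(P ** 2, axis=1)
    return float(np.sum(corrs ** 2 * norms2) / np.sum(norms2))


def cv(values: np.ndarray, ddof: int = 1) -> float:
    """Relative coefficient of variation: sample SD divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(values.std(ddof=ddof) / mean)


def _cv_vector(series: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Per-column CV of a (n_sessions, n_channels) array.

    Columns that are identically zero get CV 0 (no signal, no variability);
    a zero-mean column with nonzero spread is an error.
    """
    mean = series.mean(axis=0)
    sd = series.std(axis=0, ddof=ddof)
    out = np.zeros(series.shape[1])
    zero = mean == 0
    if np.any(zero & (sd > 0)):
        raise ValueError("zero-mean, nonzero-spread series: CV undefined")
    out[~zero] = sd[~zero] / mean[~zero]
    return out


def patient_variability(
    session_metrics: list[NetworkMetrics],
    patterns: list[ConnectivityMatrix],
    seed: int = 0,
    algorithm: str = "greedy",
    ddof: int = 1,
) -> PatientVariability:
    """Assemble the full variability profile from five sessions."""
    if len(session_metrics) != 5 or len(patterns) != 5:
        raise ValueError("expected exactly 5 sessions of metrics and patterns")
    series, mean_nmi = session_nmi(patterns, seed=seed, algorithm=algorithm)
    g = gev(patterns)
    cpl = np.array([m.cpl for m in session_metrics])
    cc = np.array([m.cc for m in session_metrics])
    bcm = np.array([m.bc_mean for m in session_metrics])
    deg = np.stack([m.degree for m in session_metrics])
    bc = np.stack([m.bc for m in session_metrics])
    return PatientVariability(
        nmi_series=series,
        nmi_mean=mean_nmi,
        gev=g,
        cv_cpl=cv(cpl, ddof=ddof),
        cv_cc=cv(cc, ddof=ddof),
        cv_bc_mean=cv(bcm, ddof=ddof),
        cv_degree=_cv_vector(deg, ddof=ddof),
        cv_bc=_cv_vector(bc, ddof=ddof),
        channel_names=session_metrics[0].channel_names,
    )
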