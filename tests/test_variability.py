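"""Session-to-session variability: module partitions, NMI, GEV, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegnetvar import (
    ConnectivityMatrix,
    ModulePartition,
    cv,
    gev,
    nmi,
    partition_modules,
    patient_variability,
    session_nmi,
)


def planted_two_blocks(eps=0.01, n=30):
    """Two 15-node near-cliques with weak cross-links."""
    v = np.full((n, n), eps)
    v[:15, :15] = 0.9
    v[15:, 15:] = 0.9
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(v, tuple(f"ch{i}" for i in range(n)))


def as_cm(v):
    return ConnectivityMatrix(np.asarray(v, float), tuple(f"ch{i}" for i in range(v.shape[0])))


class TestPartition:
    def test_planted_blocks_recovered(self):
        part = partition_modules(planted_two_blocks())
        assert part.n_modules == 2
        first = part.assignment[:15]
        second = part.assignment[15:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_uniform_graph_returns_partition(self):
        v = np.full((10, 10), 0.5)
        np.fill_diagonal(v, 0.0)
        part = partition_modules(as_cm(v))
        assert part.n_nodes == 10

    def test_deterministic(self):
        cm = planted_two_blocks(eps=0.1)
        a = partition_modules(cm, seed=1)
        b = partition_modules(cm, seed=1)
        assert np.array_equal(a.assignment, b.assignment)

    def test_louvain_seeded(self):
        cm = planted_two_blocks(eps=0.1)
        a = partition_modules(cm, seed=5, algorithm="louvain")
        b = partition_modules(cm, seed=5, algorithm="louvain")
        assert np.array_equal(a.assignment, b.assignment)


class TestNMI:
    def test_identical_partitions_are_one(self):
        p = ModulePartition(np.array([1] * 10 + [2] * 10 + [3] * 10))
        assert nmi(p, p) == 1.0

    def test_uniform_contingency_is_zero(self):
        a = ModulePartition(np.array([1, 1, 2, 2]))
        b = ModulePartition(np.array([1, 2, 1, 2]))
        assert nmi(a, b) == 0.0

    def test_against_information_theoretic_oracle(self):
        from sklearn.metrics import normalized_mutual_info_score

        a = ModulePartition(np.array([1, 1, 1, 2, 2, 2]))
        b = ModulePartition(np.array([1, 1, 2, 2, 2, 2]))
        expected = normalized_mutual_info_score(
            a.assignment, b.assignment, average_method="arithmetic")
        assert nmi(a, b) == pytest.approx(expected, abs=1e-12)

    def test_random_partitions_properties(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(20)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            a = ModulePartition(rng.integers(1, 5, n))
            b = ModulePartition(rng.integers(1, 5, n))
            v = nmi(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(nmi(b, a), abs=1e-12)
            assert nmi(a, a) == 1.0
            expected = normalized_mutual_info_score(
                a.assignment, b.assignment, average_method="arithmetic")
            assert v == pytest.approx(expected, abs=1e-10)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(ModulePartition(np.array([1, 2])), ModulePartition(np.array([1, 2, 2])))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(4, 30), st.integers(0, 2 ** 31 - 1))
    def test_bounded_symmetric_and_exact_on_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        a = ModulePartition(rng.integers(1, 5, n))
        b = ModulePartition(rng.integers(1, 5, n))
        v = nmi(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(nmi(b, a), abs=1e-12)
        assert nmi(a, a) == 1.0


class TestSessionNMI:
    def test_identical_patterns(self):
        cm = planted_two_blocks()
        series, mean = session_nmi([cm] * 5)
        assert series == pytest.approx(np.ones(4))
        assert mean == 1.0

    def test_output_length_four(self):
        cm = planted_two_blocks()
        series, _ = session_nmi([cm] * 5)
        assert len(series) == 4

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            session_nmi([planted_two_blocks()] * 4)

    def test_alternating_plants(self):
        a = planted_two_blocks()
        # orthogonal two-block structure (even/odd split)
        v = np.full((30, 30), 0.01)
        idx = np.arange(30)
        even, odd = idx[idx % 2 == 0], idx[idx % 2 == 1]
        v[np.ix_(even, even)] = 0.9
        v[np.ix_(odd, odd)] = 0.9
        np.fill_diagonal(v, 0.0)
        b = as_cm(v)
        pa = partition_modules(a)
        pb = partition_modules(b)
        cross = nmi(pa, pb)
        series, mean = session_nmi([a, b, a, b, a])
        assert series == pytest.approx([cross] * 4, abs=1e-12)
        assert mean == pytest.approx(cross)


class TestGEV:
    def test_identical_patterns_explain_everything(self):
        rng = np.random.default_rng(21)
        v = rng.uniform(0.1, 0.9, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        assert gev([as_cm(v)] * 5) == pytest.approx(1.0)

    def test_hand_computed_two_pattern_toy(self):
        p1 = np.array([1.0, 2.0, 3.0])  # upper triangles of 3x3 patterns
        p2 = np.array([2.0, 2.0, 2.5])
        def to_cm(p):
            v = np.zeros((3, 3))
            v[np.triu_indices(3, 1)] = p
            return v + v.T  # raw symmetric pattern, gev vectorizes it
        template = (p1 + p2) / 2
        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]
        expected = (corr(p1, template) ** 2 * (p1 ** 2).sum()
                    + corr(p2, template) ** 2 * (p2 ** 2).sum()) / (
                        (p1 ** 2).sum() + (p2 ** 2).sum())
        assert gev([to_cm(p1), to_cm(p2)]) == pytest.approx(expected, abs=1e-12)

    def test_noise_ladder_monotone_decreasing(self):
        rng = np.random.default_rng(22)
        base = rng.uniform(0.2, 0.8, 45)
        noise = rng.standard_normal((5, 45))
        vals = []
        for level in np.linspace(0, 0.8, 10):
            cms = []
            for k in range(5):
                p = np.clip(base + level * noise[k], 0.01, None)
                v = np.zeros((10, 10))
                v[np.triu_indices(10, 1)] = p
                cms.append(v + v.T)
            vals.append(gev(cms))
        assert all(b < a + 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < vals[0]

    def test_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            cms = []
            for _ in range(4):
                v = rng.uniform(0, 1, (5, 5))
                v = (v + v.T) / 2
                np.fill_diagonal(v, 0)
                cms.append(as_cm(v))
            assert 0.0 <= gev(cms) <= 1.0

    def test_constant_pattern_rejected(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0)
        with pytest.raises(ValueError):
            gev([as_cm(v), as_cm(v)])


class TestCV:
    def test_constant_series_zero(self):
        assert cv(np.array([3.0, 3.0, 3.0])) == 0.0

    def test_hand_computed(self):
        assert cv(np.array([1, 2, 3, 4, 5.0])) == pytest.approx(np.sqrt(2.5) / 3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(24)
        x = rng.uniform(1, 5, 10)
        assert cv(7.3 * x) == pytest.approx(cv(x), abs=1e-12)

    def test_population_variant(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cv(x, ddof=0) == pytest.approx(np.std(x) / 2.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv(np.array([-1.0, 1.0]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=20),
           st.floats(0.01, 50.0))
    def test_scale_invariance_property(self, values, c):
        x = np.asarray(values)
        assert cv(c * x) == pytest.approx(cv(x), rel=1e-9, abs=1e-12)


class TestPatientVariability:
    def test_degenerate_patient_has_no_variability(self, default_base, quiet_profile):
        from eegnetvar.pipeline import analyze_patient
        from eegnetvar.synthetic import simulate_patient

        pat = simulate_patient(quiet_profile, default_base, "Q", 10,
                               duration_s=40, fs=500, seed=3)
        var, metrics, _ = analyze_patient(pat.sessions)
        assert var.cv_cpl <= 0.02
        assert var.cv_cc <= 0.02
        assert var.cv_bc_mean <= 0.02
        assert var.nmi_mean >= 0.9

    def test_per_electrode_vectors_have_montage_length(self, short_patient):
        from eegnetvar.pipeline import analyze_patient

        var, _, _ = analyze_patient(short_patient.sessions)
        assert var.cv_degree.shape == (30,)
        assert var.cv_bc.shape == (30,)
        assert len(var.nmi_series) == 4

    def test_deterministic(self, short_patient):
        from eegnetvar.pipeline import analyze_patient

        a, _, _ = analyze_patient(short_patient.sessions)
        b, _, _ = analyze_patient(short_patient.sessions)
        assert a.cv_cpl == b.cv_cpl
        assert np.array_equal(a.nmi_series, b.nmi_series)
        assert a.gev == b.gev

    def test_missing_session_rejected(self, short_patient):
        from eegnetvar.pipeline import analyze_patient

        with pytest.raises(ValueError):
            analyze_patient(short_patient.sessions[:4])
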