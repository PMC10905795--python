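import numpy as np
import pytest

from eegnetvar import CHANNELS, N_CHANNELS, GroupProfile
from eegnetvar.synthetic import simulate_patient


def single_edge_base(i: int = 0, j: int = 1, weight: float = 1.0) -> np.ndarray:
    """30x30 coupling matrix with exactly one coupled pair."""
    base = np.zeros((N_CHANNELS, N_CHANNELS))
    base[i, j] = base[j, i] = weight
    return base


@pytest.fixture(scope="session")
def default_base():
    from eegnetvar import default_base_coupling

    return default_base_coupling()


@pytest.fixture(scope="session")
def quiet_profile():
    """No session-to-session variability, no noise: degenerate conditions."""
    return GroupProfile("QUIET", (10, 10), coupling_strength=1.3,
                        coupling_jitter_sd=0.0, hub_rotation_sd=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def short_patient(default_base):
    """One patient with 40 s sessions under the MCS-like profile (fast)."""
    profile = GroupProfile("MCS", (7, 14), coupling_strength=1.3,
                           coupling_jitter_sd=0.28, hub_rotation_sd=0.3,
                           noise_sd=3.0)
    return simulate_patient(profile, default_base, "P0", 10,
                            duration_s=40.0, fs=500.0, seed=7)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)


assert len(CHANNELS) == 30
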