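"""Canonical 30-channel 10/10 montage.

Every matrix and vector in the package uses this channel order.  Positions
are unit-sphere projections of the standard 10/10 electrode locations and
are used for spherical-spline interpolation and for the spatial structure
of the synthetic coupling model.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Canonical channel order (frontal to occipital), 10/10 names.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

N_CHANNELS = len(CHANNELS)

#: Centro-parietal electrodes treated as network hubs by the synthetic model.
CENTRO_PARIETAL: tuple[str, ...] = ("Cz", "C3", "C4", "CP1", "CP2", "Pz", "P3", "P4")


@lru_cache(maxsize=1)
def channel_positions() -> np.ndarray:
    """Unit-sphere electrode positions, shape (30, 3), in CHANNELS order.

    Positions come from the standard 10/10 template montage, re-centred on
    the electrode centroid and projected radially onto the unit sphere.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    xyz = np.array([pos_map[name] for name in CHANNELS], dtype=float)
    xyz -= xyz.mean(axis=0)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return xyz


def channel_index(name: str) -> int:
    """Index of a channel name (case-insensitive) in the canonical order."""
    lowered = [c.lower() for c in CHANNELS]
    try:
        return lowered.index(name.lower())
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; montage has {CHANNELS}") from None
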