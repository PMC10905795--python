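"""Weighted phase lag index (wPLI) connectivity.

wPLI is a conservative phase-synchronization estimator built from the
imaginary part of the cross-spectrum,

    wPLI_ij = |E{Im(X_i X_j*)}| / E{|Im(X_i X_j*)|},

so zero-lag (volume-conducted) coupling, whose cross-spectrum is purely
real, contributes nothing.  The expectation pools cross-spectral samples
over sliding windows (2 s length, 1 s step by default) and over the
frequency bins of the 1-45 Hz broadband analytic signal; a per-bin variant
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative channel x channel wPLI pattern."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    scope: str = "epoch"  # "epoch" or "session"
    band: tuple[float, float] = (1.0, 45.0)
    n_epochs_consolidated: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if v.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("wPLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("wPLI diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("wPLI entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def analytic_signal(epoch: np.ndarray, fs: float) -> np.ndarray:
    """Analytic extension x + i*H(x) per channel (Hilbert transform).

    The input is assumed already band-limited (1-45 Hz in the pipeline);
    magnitude is instantaneous amplitude, angle instantaneous phase.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size == 0:
        raise ValueError("empty input")
    return hilbert(epoch, axis=-1)


def _windowed_cross_imag(
    epoch: np.ndarray,
    fs: float,
    window_s: float,
    overlap_s: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Imaginary cross-spectral samples, shape (n_windows, n_bins, ch, ch).

    Each 2-s window is Hann-tapered and Fourier transformed; for every
    retained in-band frequency bin the imaginary part of X_i X_j* is one
    sample of the expectation in the wPLI formula.
    """
    analytic = analytic_signal(epoch, fs)
    n_ch, n_samp = analytic.shape
    wlen = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    if wlen > n_samp:
        raise ValueError(
            f"window of {window_s} s exceeds epoch length of {n_samp / fs} s"
        )
    if step < 1:
        raise ValueError("overlap must be shorter than the window")
    starts = range(0, n_samp - wlen + 1, step)
    taper = sps.get_window("hann", wlen)
    freqs = np.fft.fftfreq(wlen, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])

    samples = []
    for s0 in starts:
        seg = analytic[:, s0 : s0 + wlen] * taper
        X = np.fft.fft(seg, axis=1)[:, keep]  # (ch, n_bins)
        cross = np.einsum("if,jf->fij", X, np.conj(X))
        samples.append(cross.imag)
    return np.stack(samples, axis=0)


def wpli_epoch(
    epoch: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
    band: tuple[float, float] = (1.0, 45.0),
    channel_names: tuple[str, ...] | None = None,
    per_bin: bool = False,
) -> ConnectivityMatrix:
    """wPLI matrix for one epoch.

    The expectation pools all (window x in-band frequency bin) imaginary
    cross-spectral samples; with ``per_bin=True`` wPLI is computed per
    frequency bin first and then averaged over bins.  Pairs whose
    denominator is identically zero are set to 0 (treated as unconnected);
    the diagonal is zero by convention (Im(X_i X_i*) = 0).
    """
    epoch = np.asarray(epoch, dtype=float)
    imag = _windowed_cross_imag(epoch, fs, window_s, overlap_s, band)

    if per_bin:
        # expectation over windows only, then average the per-bin wPLI
        num = np.abs(imag.mean(axis=0))
        den = np.abs(imag).mean(axis=0)
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        w = w.mean(axis=0)
    else:
        # expectation pools windows and in-band frequency bins
        flat = imag.reshape(-1, *imag.shape[2:])
        num = np.abs(flat.mean(axis=0))
        den = np.abs(flat).mean(axis=0)
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)  # symmetric up to floating-point noise
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(epoch.shape[0]))
    return ConnectivityMatrix(values=w, channel_names=tuple(channel_names),
                              scope="epoch", band=band)


def node_degree(cm: ConnectivityMatrix, mean: bool = False) -> np.ndarray:
    """Weighted degree of each node: the sum of its wPLI weights.

    With ``mean=True`` the sum is divided by (n-1), giving the mean
    connection intensity per neighbor.
    """
    deg = cm.values.sum(axis=1)
    if mean:
        deg = deg / (cm.n_channels - 1)
    return deg


def consolidate_session(epoch_cms: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean of per-epoch matrices: the session connectivity pattern."""
    if not epoch_cms:
        raise ValueError("need at least one epoch matrix")
    names = epoch_cms[0].channel_names
    for cm in epoch_cms[1:]:
        if cm.channel_names != names:
            raise ValueError("all epoch matrices must share the channel set")
    mean = np.mean([cm.values for cm in epoch_cms], axis=0)
    return ConnectivityMatrix(
        values=mean, channel_names=names, scope="session",
        band=epoch_cms[0].band, n_epochs_consolidated=len(epoch_cms),
    )


def session_connectivity(
    epochs: np.ndarray,
    fs: float,
    channel_names: tuple[str, ...],
    window_s: float = 2.0,
    overlap_s: float = 1.0,
    band: tuple[float, float] = (1.0, 45.0),
) -> ConnectivityMatrix:
    """wPLI per epoch, averaged into one session-scope pattern."""
    cms = [
        wpli_epoch(ep, fs, window_s=window_s, overlap_s=overlap_s,
                   band=band, channel_names=channel_names)
        for ep in epochs
    ]
    return consolidate_session(cms)
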