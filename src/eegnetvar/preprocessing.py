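"""Pre-processing chain for session EEG recordings.

The fixed stage order is: resample + band-pass filter, cut into
non-overlapping fixed-length epochs, detect and interpolate bad channels,
reject bad epochs (a recording with more than 30% bad epochs is marked
unusable), and finally re-reference to the common average.

All rejection rules are deterministic threshold rules on robust statistics
(no visual inspection step), so re-running on identical input always gives
identical QC decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import CHANNELS, channel_positions


class UnusableRecordingError(RuntimeError):
    """Raised when a recording fails recording-level QC (>30% bad epochs)."""


@dataclass
class RawRecording:
    """A channels x samples signal block for one session.

    data is in µV, one row per channel in ``montage`` order.
    """

    data: np.ndarray
    fs: float
    montage: tuple[str, ...] = CHANNELS
    session_label: str = "T1"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage lists "
                f"{len(self.montage)} channels"
            )
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochArray:
    """Non-overlapping fixed-length epochs cut from one recording.

    epochs has shape (n_epochs, n_channels, samples_per_epoch).  QC state
    travels with the array: per-epoch rejection flags, per-channel
    interpolation flags, and a recording-level usable flag.
    """

    epochs: np.ndarray
    epoch_length_s: float
    fs: float
    channel_names: tuple[str, ...] = CHANNELS
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated: tuple[str, ...] = ()
    reference: str = "original"
    usable: bool = True
    session_label: str = "T1"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, channels, samples)")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples per epoch ({self.epochs.shape[2]}) must equal "
                f"epoch_length_s * fs ({expected})"
            )
        if self.rejected is None:
            self.rejected = np.zeros(self.epochs.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def kept(self) -> np.ndarray:
        """Epochs that survived QC, shape (n_kept, channels, samples)."""
        if not self.usable:
            raise UnusableRecordingError(
                f"recording {self.patient_id}/{self.session_label} was marked "
                "unusable (>30% bad epochs)"
            )
        return self.epochs[~self.rejected]


def _bandpass_kernel(fs: float, band: tuple[float, float], transition_hz: float) -> np.ndarray:
    # Symmetric (linear-phase, type I) FIR; applied centred so the net
    # filter is zero-phase, which matters because wPLI lives on phases.
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length
    return signal.firwin(numtaps, band, pass_zero=False, fs=fs, window="hamming")


def resample_filter(
    rec: RawRecording,
    target_fs: float = 500.0,
    band: tuple[float, float] = (1.0, 45.0),
    transition_hz: float = 1.0,
) -> RawRecording:
    """Downsample to target_fs and zero-phase band-pass filter.

    Resampling uses the polyphase method (with its own anti-alias filter);
    band-passing uses a symmetric Hamming-window FIR applied centred via
    FFT convolution, so no group delay is introduced.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= target_fs / 2:
        raise ValueError(
            f"band upper edge {high} Hz is at or above Nyquist ({target_fs / 2} Hz)"
        )
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the recording rate")

    data = rec.data
    if target_fs != rec.fs:
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)

    h = _bandpass_kernel(target_fs, band, transition_hz)
    filtered = signal.fftconvolve(data, h[None, :], mode="same", axes=1)
    return replace(rec, data=filtered, fs=float(target_fs))


def epoch(rec: RawRecording, epoch_length_s: float = 10.0) -> EpochArray:
    """Cut into non-overlapping epochs; the trailing remainder is dropped."""
    samples_per = int(round(epoch_length_s * rec.fs))
    n_epochs = rec.data.shape[1] // samples_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{epoch_length_s:.0f} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * samples_per]
    cube = trimmed.reshape(rec.n_channels, n_epochs, samples_per).transpose(1, 0, 2)
    return EpochArray(
        epochs=cube,
        epoch_length_s=epoch_length_s,
        fs=rec.fs,
        channel_names=tuple(rec.montage),
        session_label=rec.session_label,
        patient_id=rec.patient_id,
    )


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(x)
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def detect_bad_channels(
    ep: EpochArray,
    z_threshold: float = 3.0,
    band: tuple[float, float] = (1.0, 45.0),
) -> list[str]:
    """Flag channels that are spectral or kurtosis outliers.

    A channel is bad when the robust z-score (median/MAD) of its log band
    power in ``band`` or of its signal kurtosis across all samples exceeds
    z_threshold.  Deterministic given the input.
    """
    if ep.n_channels < 4:
        raise ValueError("need at least 4 channels for outlier statistics")
    flat = ep.epochs.transpose(1, 0, 2).reshape(ep.n_channels, -1)

    nper = min(flat.shape[1], int(2 * ep.fs))
    freqs, psd = signal.welch(flat, fs=ep.fs, nperseg=nper, axis=1)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    log_power = np.log(psd[:, in_band].mean(axis=1) + 1e-30)

    from scipy.stats import kurtosis

    kurt = kurtosis(flat, axis=1, fisher=True, bias=False)

    z_pow = np.abs(_robust_z(log_power))
    z_kurt = _robust_z(kurt)  # one-sided: only heavy tails are artifacts
    bad = (z_pow > z_threshold) | (z_kurt > z_threshold)
    if bad.all():
        raise UnusableRecordingError("every channel flagged as bad; recording unusable")
    return [name for name, b in zip(ep.channel_names, bad) if b]


def _spline_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    # Spherical-spline basis g(cos angle) built from Legendre polynomials.
    from scipy.special import eval_legendre

    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness)
    # evaluate sum_n coef_n * P_n(x) over the flattened argument
    x = np.asarray(cosang, dtype=float)
    out = np.zeros_like(x)
    for ni, cn in zip(n, coef):
        out += cn * eval_legendre(ni, x)
    return out / (4 * np.pi)


def _interpolation_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray, reg: float = 1e-5
) -> np.ndarray:
    """Spherical-spline mapping from good-channel data to bad-channel estimates."""
    G = _spline_g(good_pos @ good_pos.T)
    G_to = _spline_g(bad_pos @ good_pos.T)
    m = good_pos.shape[0]
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = G + reg * np.eye(m)
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    A[m, m] = 0.0
    A_inv = np.linalg.inv(A)
    ext = np.hstack([G_to, np.ones((bad_pos.shape[0], 1))])
    return ext @ A_inv[:, :m]


def interpolate_channels(ep: EpochArray, bad: list[str]) -> EpochArray:
    """Replace bad-channel data by spherical-spline interpolation."""
    if not bad:
        return ep
    names = list(ep.channel_names)
    unknown = [b for b in bad if b not in names]
    if unknown:
        raise ValueError(f"channels not in montage: {unknown}")
    bad_idx = np.array([names.index(b) for b in bad])
    good_idx = np.array([i for i in range(len(names)) if i not in bad_idx])
    if good_idx.size < 4:
        raise UnusableRecordingError(
            f"only {good_idx.size} good channels remain; cannot interpolate"
        )
    pos = channel_positions()
    M = _interpolation_matrix(pos[good_idx], pos[bad_idx])
    new = ep.epochs.copy()
    # epochs: (n_ep, ch, t) -> interpolate over the channel axis
    new[:, bad_idx, :] = np.einsum("bg,egt->ebt", M, ep.epochs[:, good_idx, :])
    return replace(ep, epochs=new, interpolated=tuple(sorted(set(ep.interpolated) | set(bad))))


def reject_bad_epochs(
    ep: EpochArray, prob_z: float = 5.0, max_bad_fraction: float = 0.30
) -> EpochArray:
    """Flag improbable-amplitude epochs; mark the recording unusable if the
    rejected fraction is strictly greater than max_bad_fraction.

    Each epoch is summarised per channel by its mean negative Gaussian
    log-likelihood under that channel's whole-recording amplitude
    distribution; the epoch score is the worst channel.  Epochs whose robust
    z-score of this joint amplitude-probability measure exceeds prob_z are
    rejected.
    """
    if ep.n_epochs < 1:
        raise ValueError("need at least one epoch")
    mu = ep.epochs.mean(axis=(0, 2), keepdims=True)
    sd = ep.epochs.std(axis=(0, 2), keepdims=True) + 1e-12
    nll = 0.5 * ((ep.epochs - mu) / sd) ** 2  # per-sample Gaussian surprise
    per_channel = nll.mean(axis=2)  # (n_ep, ch)
    score = per_channel.max(axis=1)
    med = np.median(score)
    mad = np.median(np.abs(score - med))
    # the MAD of a handful of clean epochs can be arbitrarily small; floor
    # the scale at a fraction of the typical score so only genuinely
    # improbable amplitude distributions are flagged
    scale = max(1.4826 * mad, 0.05 * abs(med), 1e-12)
    z = (score - med) / scale
    rejected = z > prob_z
    frac = rejected.mean()
    usable = not (frac > max_bad_fraction)
    return replace(ep, rejected=rejected | ep.rejected, usable=ep.usable and usable)


def rereference_average(ep: EpochArray) -> EpochArray:
    """Subtract the per-sample channel mean (common average reference)."""
    if not ep.usable:
        raise UnusableRecordingError(
            f"recording {ep.patient_id}/{ep.session_label} is unusable; "
            "refusing to re-reference"
        )
    demeaned = ep.epochs - ep.epochs.mean(axis=1, keepdims=True)
    return replace(ep, epochs=demeaned, reference="common_average")


def preprocess_recording(
    rec: RawRecording,
    target_fs: float = 500.0,
    band: tuple[float, float] = (1.0, 45.0),
    epoch_length_s: float = 10.0,
    channel_z: float = 3.0,
    epoch_z: float = 5.0,
) -> EpochArray:
    """Run the full fixed-order chain on one recording.

    Raises UnusableRecordingError via the returned array's usable flag only
    when downstream stages access it; QC outcomes are recorded either way.
    """
    rec = resample_filter(rec, target_fs=target_fs, band=band)
    ep = epoch(rec, epoch_length_s=epoch_length_s)
    bad = detect_bad_channels(ep, z_threshold=channel_z, band=band)
    ep = interpolate_channels(ep, bad)
    ep = reject_bad_epochs(ep, prob_z=epoch_z)
    if ep.usable:
        ep = rereference_average(ep)
    return ep


def qc_report(ep: EpochArray) -> dict:
    """JSON-serialisable QC summary for one recording."""
    return {
        "patient_id": ep.patient_id,
        "session": ep.session_label,
        "usable": bool(ep.usable),
        "interpolated_channels": list(ep.interpolated),
        "n_epochs": int(ep.n_epochs),
        "rejected_epochs": [int(i) for i in np.flatnonzero(ep.rejected)],
        "rejected_fraction": float(ep.rejected.mean()),
        "reference": ep.reference,
    }
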