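"""Synthetic session-resolved EEG cohort generator.

Recordings from patients with disorders of consciousness are not publicly
available, so the pipeline is exercised on a generative stand-in whose
statistical structure matches what the analysis assumes.  Each session is a
mixture of narrowband oscillatory sources (1-45 Hz): pairwise sources
shared between coupled channels with a fixed nonzero phase lag (the
structured network, including a centro-parietal hub system), a diffuse
traveling-wave background giving every pair a weak consistently lagged
coupling, 1/f noise, and a zero-lag common component that mimics volume
conduction.  Phase-lag-based connectivity responds only to the
consistently lagged parts, so the latent coupling matrix is the ground
truth the pipeline should recover.

Between-session variability is controlled per diagnosis group:

* ``coupling_jitter_sd`` governs the unstable-background-state mechanism —
  a log-normal rescaling of the session's noise level that moves the whole
  measured connectivity level (hence characteristic path length and, via
  nonuniform compression of the pattern, clustering) — plus a milder
  edge-specific jitter of the peripheral lattice.  Low-consciousness
  profiles use larger values.
* ``hub_rotation_sd`` rescales the gateway edges linking the
  centro-parietal hubs to the rest of the scalp (mostly independently per
  hub, relocating the dominant hub from session to session), which drives
  hub-electrode variability in degree and betweenness.  High-consciousness
  profiles use larger values.

Source frequencies, lags, mixing and phase trajectories are drawn from a
patient-level stream, so with both knobs and the noise at zero the five
sessions are bit-identical; all session-to-session variation is injected
explicitly.  Seeds follow a splittable scheme: master seed -> per-patient
seed -> per-(patient, session) stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CHANNELS, CENTRO_PARIETAL, N_CHANNELS, channel_positions
from .preprocessing import RawRecording

SESSION_LABELS = ("T1", "T2", "T3", "T4", "T5")

#: radians/sample phase-diffusion of each narrowband source (at 500 Hz this
#: decorrelates source phase over roughly a second, i.e. ~0.5 Hz linewidth)
PHASE_DIFFUSION = 0.07

#: per-channel SD (µV) of the source mixture at coupling_strength = 1.  The
#: mixture is rescaled channel-wise to this level; wPLI is invariant to
#: per-channel scaling, so this only sets the source-to-noise ratio and
#: keeps channel powers homogeneous across the montage.
SOURCE_SD = 4.0

#: diffuse background synchrony: a few broadly mixed narrowband sources
#: give every channel pair a weak, consistently lagged coupling well above
#: the finite-sample wPLI floor, so shortest paths always run over genuine
#: coupling whose level co-varies with the structured edges.  The share is
#: the fraction of source power carried by the background mixture.
N_BACKGROUND = 12
BACKGROUND_SHARE = 0.45


@dataclass(frozen=True)
class GroupProfile:
    """Generative profile for one diagnosis group."""

    label: str
    crsr_range: tuple[int, int]
    coupling_strength: float
    coupling_jitter_sd: float
    hub_rotation_sd: float
    noise_sd: float

    def __post_init__(self) -> None:
        lo, hi = self.crsr_range
        if not (0 <= lo <= hi <= 23):
            raise ValueError("crsr_range must be an integer interval within [0, 23]")
        for name in ("coupling_strength", "coupling_jitter_sd", "hub_rotation_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticPatient:
    """One simulated patient: five ordered sessions plus latent ground truth."""

    patient_id: str
    group: str
    crsr: int
    sessions: list[RawRecording]
    ground_truth: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.sessions) != 5 or len(self.ground_truth) != 5:
            raise ValueError("a patient has exactly 5 sessions")
        labels = tuple(s.session_label for s in self.sessions)
        if labels != SESSION_LABELS:
            raise ValueError(f"session labels must be {SESSION_LABELS}, got {labels}")


def default_profiles() -> list[GroupProfile]:
    """Default generator profiles for the three diagnosis groups.

    CRS-R ranges bracket the typical scores of each group; coupling jitter
    decreases and hub rotation increases with the level of consciousness.
    """
    return [
        GroupProfile("VS/UWS", (3, 7), coupling_strength=1.0,
                     coupling_jitter_sd=0.55, hub_rotation_sd=0.05, noise_sd=3.0),
        GroupProfile("MCS", (7, 14), coupling_strength=1.3,
                     coupling_jitter_sd=0.28, hub_rotation_sd=0.30, noise_sd=3.0),
        GroupProfile("EMCS", (16, 23), coupling_strength=1.6,
                     coupling_jitter_sd=0.10, hub_rotation_sd=1.20, noise_sd=3.0),
    ]


#: the anchor pair: adjacent frontal electrodes, far from the hub system
_ANCHOR_PAIR = ("Fp1", "Fp2")


def default_base_coupling(hub_gain: float = 1.8, length_scale: float = 0.55,
                          threshold: float = 0.28, n_gateways: int = 1,
                          gateway_weight: float = 0.85,
                          core_weight: float = 0.0,
                          anchor_weight: float = 2.0,
                          compress_floor: float = 0.6) -> np.ndarray:
    """Hub-routed 30x30 base coupling matrix.

    Edge classes emulate a centro-parietal hub architecture:

    * a short-range lattice coupling nearby electrodes (strength decaying
      in chord distance, pruned at ``threshold`` and compressed into a
      narrow band so every lattice edge stays well above the finite-sample
      wPLI floor of non-coupled pairs);
    * gateways from every peripheral electrode to its ``n_gateways``
      nearest hubs (load-balanced across hubs), so distant scalp regions
      reach each other through the hub system in few hops; an optional
      intra-hub core of weight ``core_weight``;
    * one strong anchor edge between the frontal pair, pinned as the
      network's maximum weight.

    Edges touching hubs are boosted by ``hub_gain``: hubs carry many
    sources, and the boost offsets the per-edge dilution of their mixed
    signal so hub routes keep high measured connectivity.
    """
    pos = channel_positions()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    w = np.exp(-((d / length_scale) ** 2))
    np.fill_diagonal(w, 0.0)
    w[w < threshold] = 0.0
    nz = w > 0
    w[nz] = compress_floor + (1.0 - compress_floor) * w[nz] / w[nz].max()

    hub_idx = np.array([CHANNELS.index(c) for c in CENTRO_PARIETAL])
    w[np.ix_(hub_idx, hub_idx)] = core_weight
    # balanced gateway assignment: each peripheral electrode links to its
    # nearest hubs, capped per hub so no hub's signal budget is split over
    # many more gateways than another's
    periph = [i for i in range(N_CHANNELS) if i not in hub_idx]
    cap = int(np.ceil(n_gateways * len(periph) / len(hub_idx)))
    load = {int(h): 0 for h in hub_idx}
    for i in sorted(periph, key=lambda i: d[i, hub_idx].min()):
        order = hub_idx[np.argsort(d[i, hub_idx])]
        chosen = [h for h in order if load[int(h)] < cap][:n_gateways]
        for h in chosen:
            w[i, h] = w[h, i] = max(w[i, h], gateway_weight)
            load[int(h)] += 1

    gain = np.ones(N_CHANNELS)
    gain[hub_idx] = hub_gain
    w = w * np.outer(gain, gain)

    if anchor_weight > 0:
        # one peripheral anchor pair carries the strongest coupling in the
        # network; because weighted clustering rescales all weights by the
        # network maximum, anchoring the maximum away from the rotating
        # hub system keeps hub rotation from leaking into clustering
        a, b = (CHANNELS.index(c) for c in _ANCHOR_PAIR)
        w[a, b] = w[b, a] = anchor_weight * w.max()
    np.fill_diagonal(w, 0.0)
    return w


def _validate_coupling(base: np.ndarray) -> np.ndarray:
    base = np.asarray(base, dtype=float)
    if base.shape != (N_CHANNELS, N_CHANNELS):
        raise ValueError(f"base coupling must be {N_CHANNELS}x{N_CHANNELS}")
    if not np.allclose(base, base.T):
        raise ValueError("base coupling matrix must be symmetric")
    if np.any(np.diag(base) != 0):
        raise ValueError("base coupling matrix must have a zero diagonal")
    if np.any(base < 0):
        raise ValueError("base coupling entries must be >= 0")
    return base


#: The session-to-session perturbation controlled by coupling_jitter_sd has
#: two faces.  A background-state (arousal) fluctuation rescales the noise
#: level by exp(_JITTER_NOISE * sd * N(0,1)): because wPLI of a coupled
#: pair rises and falls with its source-to-noise ratio, this moves the
#: whole connectivity level — and hence the characteristic path length —
#: without reorganizing the graph.  An edge-specific multiplicative
#: log-normal jitter (log-SD = _JITTER_EDGE * sd) reshapes the coupling
#: pattern, moving the clustering structure between sessions.
_JITTER_NOISE = 0.8
_JITTER_EDGE = 0.8

#: hub rotation: per-session log-normal rescaling of the edges linking the
#: centro-parietal hubs to the rest of the scalp, split into a component
#: common to all hubs (moves how strongly paths route through the hub
#: system as a whole) and a dominant per-hub component that relocates the
#: strongest hub from session to session.
_HUB_COMMON = 0.3
_HUB_LOCAL = 1.1


def _session_coupling(profile: GroupProfile, base: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Edge jitter, hub rotation and background state for one session.

    Returns the realized coupling matrix and the session's noise-level
    factor.  Draw order from ``rng`` is fixed: noise factor, edge jitter,
    hub factors.
    """
    noise_factor = float(np.exp(
        _JITTER_NOISE * profile.coupling_jitter_sd * rng.standard_normal()
    ))

    iu, ju = np.triu_indices(N_CHANNELS, k=1)
    jitter = np.exp(_JITTER_EDGE * profile.coupling_jitter_sd
                    * rng.standard_normal(iu.size))
    m = np.zeros_like(base)
    m[iu, ju] = jitter
    m += m.T

    hub_idx = [CHANNELS.index(c) for c in CENTRO_PARIETAL]
    # edge jitter reshapes the peripheral lattice only; edges touching the
    # hub system are governed by the hub_rotation knob instead, so the two
    # variability mechanisms stay independently controllable
    m[hub_idx, :] = 1.0
    m[:, hub_idx] = 1.0
    z_common = rng.standard_normal()
    z_local = rng.standard_normal(len(hub_idx))
    s = np.ones(N_CHANNELS)
    s[hub_idx] = np.exp(profile.hub_rotation_sd
                        * (_HUB_COMMON * z_common + _HUB_LOCAL * z_local))
    rot = np.outer(s, s)
    rot[np.ix_(hub_idx, hub_idx)] = 1.0
    sess = profile.coupling_strength * base * m * rot
    np.fill_diagonal(sess, 0.0)
    return sess, noise_factor


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude noise with the requested per-channel SD."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    pink *= sd / pink.std(axis=1, keepdims=True)
    return pink


def simulate_session(
    profile: GroupProfile,
    base_coupling: np.ndarray,
    session_index: int,
    duration_s: float = 150.0,
    fs: float = 500.0,
    seed: int = 0,
    patient_id: str = "",
    background_share: float = BACKGROUND_SHARE,
) -> tuple[RawRecording, np.ndarray]:
    """Simulate one session and return (recording, realized coupling matrix).

    ``seed`` is the patient-level seed: source frequencies, lags and phase
    trajectories depend only on it, while jitter, hub rotation and noise are
    drawn from a stream keyed additionally on ``session_index``.
    ``background_share`` is the fraction of source power carried by the
    diffuse background mixture (0 disables it, leaving only the pairwise
    coupled sources).
    """
    base = _validate_coupling(base_coupling)
    if not 1 <= session_index <= 5:
        raise ValueError("session_index must be in 1..5")
    if duration_s < 30:
        raise ValueError("duration_s must be >= 30 s (room for at least one epoch)")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")

    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    rng_patient = np.random.default_rng([int(seed), 0])
    rng_session = np.random.default_rng([int(seed), int(session_index)])

    iu, ju = np.triu_indices(N_CHANNELS, k=1)
    edge_mask = base[iu, ju] > 0
    edges = list(zip(iu[edge_mask], ju[edge_mask]))

    # patient-level source parameters (identical across the 5 sessions)
    freqs = rng_patient.uniform(2.0, 44.0, size=len(edges))
    phase0 = rng_patient.uniform(0, 2 * np.pi, size=len(edges))
    lags = rng_patient.uniform(np.pi / 6, np.pi / 2, size=len(edges))
    lags *= rng_patient.choice([-1.0, 1.0], size=len(edges))
    vc_gain = rng_patient.uniform(0.5, 1.0, size=N_CHANNELS)

    sess_coupling, noise_factor = _session_coupling(profile, base, rng_session)

    sources = np.zeros((N_CHANNELS, n_samples))
    for k, (i, j) in enumerate(edges):
        amp = sess_coupling[i, j]
        walk = np.cumsum(PHASE_DIFFUSION * rng_patient.standard_normal(n_samples))
        if amp == 0:
            continue
        arg = 2 * np.pi * freqs[k] * t + phase0[k] + walk
        c, s = np.cos(arg), np.sin(arg)
        sources[i] += amp * c
        sources[j] += amp * (np.cos(lags[k]) * c + np.sin(lags[k]) * s)

    # diffuse background synchrony: broadly mixed narrowband sources whose
    # channel phases follow one patient-level spatial gradient (a traveling
    # wave across the scalp), so every channel pair keeps a consistently
    # signed phase lag and hence a genuine weak wPLI well above the
    # finite-sample floor
    background = np.zeros((N_CHANNELS, n_samples))
    bg_freqs = rng_patient.uniform(2.0, 44.0, size=N_BACKGROUND)
    bg_phase0 = rng_patient.uniform(0, 2 * np.pi, size=N_BACKGROUND)
    bg_gains = rng_patient.uniform(0.4, 1.0, size=(N_BACKGROUND, N_CHANNELS))
    g_dir = rng_patient.standard_normal(3)
    g_dir /= np.linalg.norm(g_dir)
    psi = 1.3 * (channel_positions() @ g_dir)  # per-channel phase offset
    if background_share > 0 and profile.coupling_strength > 0:
        cos_psi, sin_psi = np.cos(psi), np.sin(psi)
        for k in range(N_BACKGROUND):
            walk = np.cumsum(PHASE_DIFFUSION
                             * rng_patient.standard_normal(n_samples))
            arg = 2 * np.pi * bg_freqs[k] * t + bg_phase0[k] + walk
            c, s = np.cos(arg), np.sin(arg)
            background += bg_gains[k][:, None] * (
                (cos_psi[:, None] * c[None, :])
                + (sin_psi[:, None] * s[None, :])
            )

    # Equalize per-channel source power (wPLI only reads phase relations,
    # so this rescaling leaves connectivity untouched while keeping the
    # montage free of power outliers); the level scales with the group's
    # coupling strength and sets the source-to-noise ratio.
    target = SOURCE_SD * profile.coupling_strength
    sd = sources.std(axis=1, keepdims=True)
    nonzero = sd[:, 0] > 0
    sources[nonzero] *= (np.sqrt(1.0 - background_share) * target
                         / sd[nonzero])
    bg_sd = background.std(axis=1, keepdims=True)
    bg_nonzero = bg_sd[:, 0] > 0
    background[bg_nonzero] *= (np.sqrt(background_share) * target
                               / bg_sd[bg_nonzero])

    data = sources + background
    session_noise_sd = profile.noise_sd * noise_factor
    data += _pink_noise(rng_session, N_CHANNELS, n_samples, fs, session_noise_sd)
    # zero-lag common component: a volume-conduction surrogate that the
    # phase-lag based connectivity estimate must ignore
    common_sd = 0.5 * session_noise_sd
    if common_sd > 0:
        common = _pink_noise(rng_session, 1, n_samples, fs, common_sd)
        data += vc_gain[:, None] * common

    rec = RawRecording(
        data=data, fs=float(fs),
        session_label=SESSION_LABELS[session_index - 1],
        patient_id=patient_id,
    )
    return rec, sess_coupling


def simulate_patient(
    profile: GroupProfile,
    base_coupling: np.ndarray,
    patient_id: str,
    crsr: int,
    duration_s: float,
    fs: float,
    seed: int,
) -> SyntheticPatient:
    sessions, truths = [], []
    for s in range(1, 6):
        rec, truth = simulate_session(
            profile, base_coupling, s, duration_s=duration_s, fs=fs,
            seed=seed, patient_id=patient_id,
        )
        sessions.append(rec)
        truths.append(truth)
    return SyntheticPatient(patient_id, profile.label, crsr, sessions, truths)


def simulate_cohort(
    profiles: list[GroupProfile] | None = None,
    n_per_group: int = 20,
    duration_s: float = 150.0,
    fs: float = 500.0,
    seed: int = 0,
    base_coupling: np.ndarray | None = None,
) -> list[SyntheticPatient]:
    """Simulate a full cohort; reproducible under a fixed seed."""
    if profiles is None:
        profiles = default_profiles()
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError(f"group labels must be unique, got {labels}")
    if base_coupling is None:
        base_coupling = default_base_coupling()

    master = np.random.SeedSequence(int(seed))
    children = master.spawn(len(profiles) * n_per_group)
    cohort: list[SyntheticPatient] = []
    idx = 0
    for profile in profiles:
        tag = profile.label.replace("/", "")
        for k in range(n_per_group):
            patient_seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            rng = np.random.default_rng([patient_seed, 99])
            crsr = int(rng.integers(profile.crsr_range[0], profile.crsr_range[1] + 1))
            cohort.append(
                simulate_patient(
                    profile, base_coupling,
                    patient_id=f"{tag}_{k:02d}", crsr=crsr,
                    duration_s=duration_s, fs=fs, seed=patient_seed,
                )
            )
    return cohort


@dataclass
class ArtifactLog:
    """Bookkeeping of injected contamination, for QC-recall tests."""

    bad_channels: list[str] = field(default_factory=list)
    bad_epochs: list[int] = field(default_factory=list)


def inject_artifacts(
    recording: RawRecording,
    bad_channel_ids: list[str],
    bad_epoch_fraction: float = 0.0,
    seed: int = 0,
    epoch_length_s: float = 10.0,
) -> tuple[RawRecording, ArtifactLog]:
    """Contaminate a recording with channel- and epoch-level artifacts.

    Designated channels receive a high-kurtosis spike train plus broadband
    noise; a random subset of epochs (``bad_epoch_fraction`` of them)
    receives large-amplitude low-frequency transients.
    """
    if not 0 <= bad_epoch_fraction <= 1:
        raise ValueError("bad_epoch_fraction must be in [0, 1]")
    names = list(recording.montage)
    unknown = [c for c in bad_channel_ids if c not in names]
    if unknown:
        raise ValueError(f"unknown channel ids: {unknown}")

    rng = np.random.default_rng([int(seed), 7])
    data = recording.data.copy()
    n_samples = data.shape[1]
    scale = np.median(np.abs(data)) * 1.4826 + 1e-12

    log = ArtifactLog()
    for ch in bad_channel_ids:
        i = names.index(ch)
        spikes = np.zeros(n_samples)
        n_spikes = max(3, int(n_samples / recording.fs))  # ~1 spike/s
        pos = rng.integers(0, n_samples, size=n_spikes)
        spikes[pos] = rng.choice([-1.0, 1.0], size=n_spikes) * 25.0 * scale
        data[i] += spikes + rng.standard_normal(n_samples) * 3.0 * scale
        log.bad_channels.append(ch)

    samples_per = int(round(epoch_length_s * recording.fs))
    n_epochs = n_samples // samples_per
    n_bad = int(round(bad_epoch_fraction * n_epochs))
    if n_bad > 0:
        chosen = sorted(rng.choice(n_epochs, size=n_bad, replace=False).tolist())
        tt = np.arange(samples_per) / recording.fs
        for e in chosen:
            sl = slice(e * samples_per, (e + 1) * samples_per)
            burst = 12.0 * scale * np.sin(2 * np.pi * 1.5 * tt)
            burst *= np.hanning(samples_per)
            data[:, sl] += burst[None, :]
            log.bad_epochs.append(int(e))

    rec = RawRecording(
        data=data, fs=recording.fs, montage=recording.montage,
        session_label=recording.session_label, patient_id=recording.patient_id,
    )
    return rec, log
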