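# Methods

This note documents the models and conventions behind `eegnetvar`: what
each stage computes, the choices made where the underlying procedure was
genuinely open, what the synthetic cohort does and does not emulate, and
the known limitations.

## Pre-processing

The chain is fixed in order: resample → band-pass → epoch → bad-channel
detection/interpolation → epoch rejection → common average reference.

* **Filtering.** Polyphase resampling to 500 Hz, then a symmetric
  (linear-phase, type I) Hamming-window FIR band-pass of 1–45 Hz applied
  centred via FFT convolution. The net filter is zero-phase; phase matters
  because connectivity is estimated from instantaneous phases. Transition
  width 1 Hz (configurable), stop-band attenuation well beyond the 20 dB
  the pipeline requires.
* **Bad channels.** A channel is rejected when the robust z-score
  (median/MAD) of its log band power in 1–45 Hz or of its sample kurtosis
  exceeds 3 (kurtosis one-sided: only heavy-tailed channels are
  artifactual). Rejected channels are rebuilt by spherical-spline
  interpolation (Legendre expansion of order 4, 50 terms, regularization
  1e-5) from the unit-sphere 10/10 electrode positions.
* **Epoch rejection.** Each 10-s epoch is scored by its worst-channel mean
  Gaussian negative log-likelihood under the recording's amplitude
  distribution; epochs whose score exceeds 5 robust SDs are rejected. The
  scale is floored at 5% of the median score because the MAD of a handful
  of epochs is unstable. If more than 30% of epochs are rejected —
  strictly greater, so 3 of 10 passes — the recording is unusable and the
  patient drops out of group statistics with a logged reason.
* Ocular/cardiac component removal by ICA with visual component selection
  is inherently manual and is not reproduced; the synthetic recordings
  carry no such sources by default. All thresholds replace visual steps with deterministic rules
  so identical input always yields identical QC decisions.

## Connectivity

wPLI is computed from the analytic (Hilbert) extension of the band-limited
signal. Within each epoch, 2-s Hann-tapered windows slide with a 1-s step;
each retained FFT bin in 1–45 Hz of each window contributes one sample of
Im(X_i X_j*). The expectation pools all window × bin samples
(`per_bin=True` computes wPLI per bin and averages instead; pooling is the
default because the broadband estimator is what the session patterns
need). Pairs with an identically zero denominator get wPLI 0 — no
imaginary cross-spectrum is treated as no connection — and the diagonal is
zero by convention. Per-epoch matrices are averaged entrywise into the
session pattern.

Finite data give a positive wPLI floor for truly uncoupled pairs (≈0.1 at
10-s epochs with these window settings); the floor is a property of the
estimator, not a bug, and the synthetic generator is designed so genuine
coupling sits well above it.

Node degree is the **sum** of a node's weights. The mean-per-neighbor
variant is exposed as an option, but group-level degree values in this
literature exceed 1 on 29 neighbors, which is only consistent with the
sum.

## Graph metrics

Weights are used unthresholded; shortest-path computations use edge
lengths 1/w (strongest coupling = shortest distance). Characteristic path
length averages all finite ordered-pair distances; unreachable pairs are
excluded with a warning (an `inf` propagating variant is available), and a
fully disconnected graph is an error. Clustering uses the geometric-mean
triangle generalization with weights rescaled by the network maximum;
on 0/1 matrices it reduces exactly to the binary triangle fraction, which
is the regression oracle in the tests. Betweenness uses Brandes'
algorithm on the 1/w lengths with fractional tie counting and the
(n−1)(n−2) ordered-pair normalization. Under a uniform rescaling of all
weights by c, L scales by 1/c while C and b are invariant; the tests pin
this behavior.

## Variability across sessions

* **Module partitions** are obtained by greedy modularity maximization on
  the weighted graph (deterministic); seeded Louvain is available. The
  partition-to-NMI step is a convention: any partitioner can be injected.
* **NMI** implements the contingency-table form
  −2 ΣΣ N_ij log(N_ij N / N_i N_j) / [Σ N_i log(N_i/N) + Σ N_j log(N_j/N)]
  with 0·log 0 = 0, clipped into [0, 1] against float rounding. It is
  computed for the four neighboring session pairs (T1–T2 … T4–T5); the
  session level (not epoch level) is the unit of comparison.
* **GEV** vectorizes each session pattern's upper triangle, takes the mean
  pattern as template g, and reports
  Σ_k corr(p_k, g)² ‖p_k‖² / Σ_k ‖p_k‖² — the norm-weighted squared
  correlation used for template fitting in the microstate literature. The
  direction of GEV differences between groups is reported neutrally; the
  measure is descriptive.
* **CV** is the sample (n−1) standard deviation divided by the mean
  (population variant via `ddof=0`). Per-electrode CV vectors cover degree
  and betweenness; an identically zero series has CV 0, a zero-mean series
  with spread is an error.

## Group statistics

All tests are two-sided and deterministic. Kruskal–Wallis (tie-corrected)
for the omnibus contrast; Mann–Whitney U for the three pairwise group
contrasts with Bonferroni adjustment min(1, 3p); Benjamini–Hochberg
step-up at Q = 0.05 across the 30 electrodes for per-electrode contrasts
(Mann–Whitney for two groups, Kruskal–Wallis for three). A Friedman
repeated-measures test across sessions within a group is provided
separately: the between-group electrode contrast is a rank-sum problem,
while the Friedman test answers the within-subject session-effect
question, and the two are not interchangeable. Correlations with the
CRS-R score use Kendall tau-b with tie correction.

## Synthetic cohort

The generator produces what the analysis assumes rather than a
biophysical head model. Per patient, a base coupling matrix defines a
centro-parietal hub architecture: a short-range lattice between
neighboring electrodes, load-balanced gateway edges from each peripheral
electrode to its nearest hub, and one strong frontal anchor edge pinned as
the network maximum (the clustering normalizer stays put when hubs move).
Each coupled pair shares a narrowband source (frequency drawn in 2–44 Hz,
phase random walk of ~0.5 Hz linewidth) received by the second channel at
a fixed lag in ±[π/6, π/2]; a diffuse background of 12 broadly mixed
sources whose channel phases follow one patient-level spatial gradient (a
traveling wave) gives every pair a weak, consistently lagged coupling well
above the wPLI floor. Pink (1/f) noise and a zero-lag common component
(the volume-conduction surrogate that wPLI must ignore) are added on top.
Channel source power is equalized (wPLI reads phases, not amplitudes) at
4 µV × coupling strength against 3 µV noise.

Session-to-session variability is injected through three mechanisms:

* a **background-state (noise level) log-normal jitter** — the main dial
  for low-consciousness profiles. Because wPLI rises and falls with the
  source-to-noise ratio, and the background scaffold keeps the whole
  pattern scaling nearly uniformly, this moves path length (and, through
  nonuniform compression, clustering) with bounded graph reorganization;
* an **edge jitter** on the peripheral lattice that reshapes the local
  triangle structure (clustering variability) without touching hub edges;
* a **hub rotation** that rescales each hub's gateway edges (dominant
  per-hub component plus a small common one), relocating the dominant
  centro-parietal hub between sessions — the planted effect behind
  hub-electrode variability in higher-consciousness profiles.

Default profiles (coupling strength, jitter, hub rotation): VS/UWS (1.0,
0.55, 0.05), MCS (1.3, 0.28, 0.30), EMCS (1.6, 0.10, 1.20); CRS-R drawn
uniformly in 3–7, 7–14, 16–23. Sessions default to 150 s (15 clean 10-s
epochs) as a desk-scale stand-in for the 15-minute clinical recordings;
durations and all profile fields are configurable. Seeds are splittable:
master seed → per-patient seeds (SeedSequence spawning) → per-session
streams, so a cohort is bit-reproducible and, with all variability dials
and noise at zero, a patient's five sessions are bit-identical.

What the generator does **not** emulate: realistic head geometry and lead
fields, ocular/cardiac artifacts (the ICA stage is out of scope),
circadian or drowsiness structure across T1–T5, and any periodicity of
state fluctuations. Passing the recovery tests therefore shows that the
pipeline detects the kinds of variability the generator plants — overall
level fluctuations, lattice reshaping, hub relocation — not that clinical
EEG behaves this way.

## Known limitations

* **Mean-betweenness variability direction.** In this estimator-plus-graph
  stack, every mechanism that moves the overall connectivity level (needed
  to make path-length and clustering variability highest in the VS/UWS
  profile) also moves the variance of mean betweenness by roughly half as
  much, while hub rotation redistributes betweenness among hubs with a
  nearly conserved mean. As a consequence the generator can plant
  electrode-level betweenness/degree variability at the hubs, but cannot
  make the patient-level CV of *mean* betweenness increase with the
  consciousness score while the path-length and clustering orderings hold:
  the Kendall correlation of CV(mean betweenness) with the score comes out
  negative on the default cohort, and the corresponding recovery test is
  expected to fail. The electrode-level planted effect is recovered
  instead through the per-electrode contrast (on degree CVs in the
  full-pipeline check, and on betweenness CVs in the statistics-level
  planted-table check).
* The wPLI floor couples weakly-connected pairs to the estimator's sample
  size; comparisons across different epoch counts should hold the epoch
  count fixed, as the pipeline does.
* Greedy modularity partitions are coarse on near-uniform session
  patterns; NMI values then reflect partition granularity as much as
  network change. The partitioner is injectable for sensitivity analyses.
* Group statistics treat patients as exchangeable within groups; no
  covariates (etiology, time since injury) are modeled.
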