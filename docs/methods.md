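# Methods

`ckcoh` implements a model-based spectral analysis of the directional
("Granger-style") interactions inside the cardiovascular and
cardiorespiratory closed loops, from beat-to-beat series of heart period
(HP), systolic arterial pressure (SAP) and respiration (RESP).  This note
documents the models, the numerical choices, the synthetic generators used
as ground truth, and the limits of what the tests demonstrate.

## Beat-series extraction

R-wave peaks are detected on the ECG first derivative: a candidate is a
sample whose positive derivative exceeds an adaptive threshold
(`threshold_factor`, default 0.4, times the rolling maximum of the positive
derivative over the preceding 2 s, with a global floor of 5% of the peak
slope so micro-wiggles in flat stretches cannot trigger).  Each crossing is
refined to the argmax of the raw ECG within the following 100 ms, which
makes detection robust to beat-to-beat amplitude changes, and refined peaks
closer than the refractory period (default 0.25 s) to the previous accepted
peak are discarded.  The refinement window and threshold value are
engineering choices; only the derivative-threshold principle is fixed by
the method.

The n-th HP (ms) is the interval between consecutive R peaks; the n-th SAP
(mmHg) is the maximum of the arterial pressure over the half-open window
[t_n, t_{n+1}) (half-open so no sample is counted twice); the n-th RESP is
the respiration sample nearest to t_n (no interpolation — at 400 Hz the
difference is negligible).

HP values outside a configurable validity range (default 300–2000 ms,
covering 30–200 beats/min) mark missed detections or ectopic beats.  The
flagged beats of all three channels are repaired by linear interpolation
*in the beat domain* (beat index as abscissa) between the nearest in-range
neighbours; leading/trailing flagged beats take the nearest in-range value.
Repair preserves series length and is idempotent.  An interpolated fraction
above 5% raises a warning flag rather than an error: in clean recordings
that fraction is an observed property, not a validity rule.

Analysis segments are 256 consecutive beats drawn uniformly at random
(seeded) from the repaired series; 256 is power-of-two friendly for the FFT
work in the surrogate stage.  No stationarity screening is applied to the
drawn segment.

## Univariate spectral markers

Each series is linearly detrended (the same pre-processing the bivariate
stage uses, applied uniformly) and modelled as an AR(p) process.  The
coefficients come from the Levinson–Durbin recursion on the *biased*
(divide-by-n) autocorrelation estimate, which guarantees a stable model;
consistently, "variance" everywhere uses the population (divide-by-n)
convention so that lag-0 autocorrelation and variance agree.  The order
minimises AIC, n·ln(σ²_w) + 2p, over 8–14.

All AR mathematics lives on the dimensionless beat-frequency axis
(cycles/beat).  Band edges are physiological frequencies in Hz — LF
0.04–0.15 Hz, HF 0.15–0.4 Hz, membership closed-open [lo, hi) — so the
axis is converted through the segment's mean heart period:
f_Hz = f_cpb / μ_HP[s].

The AR power spectral density is factorised into one component per real
pole and per complex-conjugate pole pair.  The power of the component of
pole p_k is the residue of S(z)/z at p_k,

    g_k = σ²_w · p_k^{p-1} / ( Π_{j≠k}(p_k − p_j) · Π_j(1 − p̄_j p_k) ),

taken as Re(g_k) for a real pole and 2·Re(g_k) for a pair; the central
frequency is the pole angle /2π.  Signed residues sum to the process
variance *exactly* (verified against dense PSD integration to 1e-6
relative error); individual residues of near-cancelling poles can be
legitimately negative, so each component carries both the signed residue
(`raw_power`, used for conservation) and a value rectified at zero
(`power`, used for band markers).  Real poles map to 0 cycles/beat
(negative real poles to 0.5) and therefore fall in neither LF nor HF.

Markers: μ and σ² of HP and SAP; HF power of HP (HF_HP, ms², vagal
modulation); LF power of SAP (LF_SAP, mmHg², vascular sympathetic
modulation); respiratory rate f_RESP (breaths/min) as 60× the central
frequency of the largest-power HF component of RESP — ties break toward
the lower frequency.

## Bivariate causal squared coherence

A series pair is z-scored after linear detrending (population SD; this
makes every K²/CK² marker scale-invariant) and described by a bivariate AR
model with a direction-specific latency structure: within each loop the
fast pathway acts within the same beat (lag 0) and the slow one with one
beat of delay — RESP→HP at lag 0 / HP→RESP at lag 1, and SAP→HP at lag 0 /
HP→SAP at lag 1.  Only one pathway may be instantaneous; the structural
model is then recursive, the zero-lag coefficient absorbs the instantaneous
cross-correlation, and the innovation covariance can be taken diagonal.

Each equation is an ordinary least-squares problem solved via Cholesky
factorisation of its normal equations (fallback to a pivoted SVD solve,
with a warning, when the Cholesky diagonal indicates a condition number
above 1e12; a genuinely rank-deficient design raises an identification
error).  The common order of the pair minimises the multivariate Akaike
figure of merit, n·ln(λ₁λ₂) + 2·(#coefficients), over 5–14 on a common
estimation sample (rows start at the range maximum so the criterion is
comparable across orders).  One order serves both directions of a pair,
since both CK² functions derive from the single fitted model.  Stability is
checked on the companion matrix of the reduced form; an unstable fit is
flagged and spectral operations refuse it.

The cross-spectral matrix on a uniform 1025-point grid over [0, 0.5]
cycles/beat is S(f) = H(f) Λ H(f)ᴴ with H = [I − A(f)]⁻¹ and A(f) the
polynomial transform including the lag-0 cross term.  Squared coherence is
K²(f) = |S12|²/(S11·S22) — symmetric under channel swap.  Causal squared
coherence toward the effect channel zeroes every coefficient of the
*reverse* (effect→cause) pathway, leaving all other coefficients and Λ
unchanged, and recomputes the coherence of the modified model.  The
pathway-zeroed model need not be dynamically stable; CK² only evaluates
its transfer function on the unit circle, and since the modified spectral
matrix is still of the form H̃ΛH̃ᴴ (positive semidefinite), CK² stays in
[0, 1] by Cauchy–Schwarz regardless.  Band markers are arithmetic means of
these functions over the Hz-converted grid points inside LF or HF; the
grid resolution and the arithmetic (rather than power-weighted) mean are
documented choices, as the method itself fixes neither.

## Surrogate uncoupling test

Significance of each K²/CK² band marker is tested against the null of full
uncoupling using iteratively refined amplitude-adjusted Fourier-transform
(IAAFT) surrogates.  Initialisation replaces the Fourier phases with
i.i.d. uniform draws on [0, 2π) (conjugate-symmetric; DC and Nyquist kept
real); each of the 100 refinement iterations alternates a
spectrum-adjustment step (impose the original amplitude spectrum, keep
phases) and an amplitude-adjustment step (rank-order the original values
onto the surrogate).  The final step is the amplitude adjustment, so the
surrogate's sorted values equal the original's bit-exactly while the
amplitude spectrum is approximate.  The two channels of a surrogate pair
use different seeds, which destroys their cross-correlation.

The marker is recomputed on 100 surrogate pairs with the *full*
identification pipeline — detrend, z-score, order selection re-run per pair
(a conservative reading; freezing the original order is available as an
option).  The threshold is the nearest-rank 95th percentile of the null
values, and the null is rejected iff the original marker is *strictly*
above it.  If more than 20% of surrogate fits are unstable the null is
declared unreliable.  Rejecting when the original ranks strictly above the
r-th of m exchangeable null values has exact probability
(m + 1 − r)/(m + 1): the default procedure (m = 100, rank 95) operates at
exact level 6/101 ≈ 0.059, a property of the published rule itself.  When
the null set is scaled down for speed the percentile should be adjusted to
the nearest rank that keeps the intended level — with m = 40, rank 39
(the 97.5 nearest-rank percentile) gives 2/41 ≈ 0.049.  The empirical size
measured over 500 replicate tests on independent channels matches these
exact levels, and power at strong coupling exceeds 90%.  The per-cohort
rejection percentage (%K², %CK²) is the fraction of subjects rejecting.

A known mild conservativeness of the null's *location*: surrogates of
strongly coupled pairs keep each channel's realised amplitude spectrum,
and those envelopes are correlated across channels, which elevates the
estimated null coherence by roughly 0.05 relative to truly independent
realisations.  This shifts the null slightly toward the alternative
(costing a little power) without affecting the size of the test under
true uncoupling.

## Synthetic generators

The generators provide the ground truth no clinical recording can.  The
trivariate subject model places the analysed pathways explicitly:

* RESP — autonomous AR(2) resonance (pole modulus 0.94) at the breathing
  frequency, default 0.268 Hz ≈ 16.1 breaths/min;
* HP — mild own dynamics (coefficient 0.2) + gain·RESP at lag 0
  (respiratory sinus arrhythmia) + gain·SAP at lag 0 (cardiac baroreflex);
* SAP — AR(2) Mayer-wave resonance (modulus 0.8) at 0.1 Hz + gain·HP at
  lag 1 (mechanical feedforward); an optional HP→RESP lag-1 pathway is off
  by default.

Frequencies are specified in Hz and mapped to cycles/beat through the mean
heart period, mirroring the analysis convention.  Channels are rescaled by
sample standardisation to the configured means/SDs — defaults follow
resting supine values typical of a lightly affected post-COVID cohort
(μ_HP 884 ms, σ²_HP ≈ 750 ms², μ_SAP 138 mmHg, σ²_SAP ≈ 28 mmHg²) — so the
time-domain targets hold exactly and the spectral shape carries the
physiology.  Small additive white measurement noise (10% SD) is applied to
RESP only.  Stability of every configuration is verified on the companion
matrix at construction.  The feedforward gain default (0.1) keeps the
SAP↔HP loop stable (spectral radius ≤ 0.94) across the whole preset range.

Presets encode the orthostatic physiology being probed: `HEALTHY_STAND`
lowers the RESP→HP gain (1.5 → 0.25) and raises the SAP→HP gain
(0.25 → 1.5) relative to `HEALTHY_REST`, with the expected mild
tachycardia (μ_HP 884 → 798 ms); the `COVID_*` presets keep both gains
fixed (0.8) under standing — the blunted-response contrast.  `UNCOUPLED`
zeroes every pathway.  A bivariate generator (narrow-band cause channel,
one tunable coupling direction) exports a five-point gain ladder
(0.25…2.0) shared by the recovery and power benches; at n = 256 its
estimated coupled-direction CK²(HF) medians rise monotonically
(≈0.45/0.69/0.88/0.94/0.96) while the reverse direction stays below 0.02.

What the generators do *not* emulate: non-Gaussian and nonstationary
dynamics, ectopy and artefacts beyond optional out-of-range beats,
amplitude-frequency coupling of real respiration, measurement noise on HP
and SAP, or any waveform realism beyond what the extraction stage needs
(Gaussian QRS templates, raised-sine pressure pulses, spline respiration).
Passing tests therefore demonstrate correctness of the estimators under
the stated linear closed-loop model, not robustness to every pathology of
clinical data.

## Problem sizes and numerical notes

The statistical benches run at the study's native segment length
(n = 256): 200 seeds for directional recovery, 500 replicate uncoupling
tests with 40 surrogate pairs each for the empirical size (nearest-rank
adjusted null rate 2/41), 200 tests for power, 50 seeds × 64 beats for the
raw-signal round trip, and 40 paired subjects per cohort for the
orthostatic contrast.  Exact/algebraic checks use tolerances 1e-6
(power conservation), 1e-8 (Levinson vs normal equations) and 1e-10
(coherence bounds, swap symmetry, causal identity).

Degenerate inputs raise typed errors rather than propagating NaNs:
constant/zero-variance series, all-out-of-range beat series, too-short
segments, rank-deficient designs, unstable fits, empty bands, absent HF
respiratory components.  Coherence values are clipped to [0, 1] only
within 1e-9 of the boundary; a larger overshoot raises a spectral
singularity error instead of being masked.
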