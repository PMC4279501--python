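# Methods

## Signal model and conventions

The input is specific force from a chest-worn triaxial accelerometer: x
lateral, y vertical, z horizontal, in m/s² with gravity included on the
vertical axis (raw phone accelerometers report the gravity-inclusive signal,
and no orientation fusion is attempted — classification does not require it).
Timestamps are seconds from an arbitrary origin; only relative timing enters
any computation, so classifier output is invariant to a uniform time shift.
Sampling is nominally ~80 Hz but may be irregular, which drives the central
numerical choice below.

## Kernel smoothing under irregular sampling

All smoothing is a normalized time-domain Gaussian kernel estimate
(Nadaraya–Watson): the value at query time q is Σᵢ wᵢ sᵢ / Σᵢ wᵢ with
wᵢ = exp(−(tᵢ−q)²/2σ²) over sample times tᵢ. Unlike an FIR convolution this
is exact for irregular sample spacing, can be queried at arbitrary times (so
it doubles as the resampler), reproduces constants exactly at every query
point, and is linear in the signal. The kernel is truncated at ±5σ (lost
weight mass < 1e-6); weights renormalize over whatever samples exist, which
handles stream edges; a query whose truncated window is empty (a data gap
wider than 10σ) falls back to the nearest sample rather than failing.

## Cycle segmentation

The segmentation channel (default: the vertical axis, whose once-per-cycle
oscillation is present in every skating gear; `magnitude` √(ax²+ay²+az²) is
available as an alternative) is smoothed with σ_segment = 370 ms, wide enough
that only the fundamental cycle frequency survives. Cycle boundaries are
local minima of this very-low-frequency signal — minima rather than zero
crossings because minima need no baseline parameter under a gravity offset.
Two gates reject spurious minima: prominence ≥ 10% of the smoothed signal's
interquartile range, and a minimum boundary spacing of `min_cycle_duration`
(deeper minimum wins). Consecutive boundary pairs with spacing in
[0.5 s, 3.0 s] — bracketing reported skating cycle rates — become cycle
segments; leading/trailing partial cycles are discarded, so only whole cycles
are ever classified.

Two boundary-region corrections matter in practice. The truncated kernel's
estimate near the recording edges is biased toward the local average, which
can swallow a genuine minimum lying within a few σ of the edge; the
segmentation channel is therefore reflection-padded across both edges before
smoothing. Reflection itself can merge an edge-adjacent minimum into the
boundary (mirroring a rising edge builds a W whose narrow center peak the
wide kernel flattens), so any detected boundary within 2σ_segment of an edge
is re-localized as the minimum of the narrow feature-bandwidth smoothing over
a ±2σ_segment window. On a pure sinusoid these corrections recover every
analytic minimum to within one sample period.

## Time-normalization

Each segment is evaluated at 100 uniformly spaced query times in one kernel
regression pass and flattened to a 300-vector (100 steps × 3 axes), making
the representation independent of sampling rate and cycle duration. The
feature bandwidth is σ_feature scaled by cycle duration:
σ = 0.090 s · d / 1.4 s for a cycle of duration d. A bandwidth fixed in
seconds would attenuate the harmonics of a 0.9 s cycle noticeably more than
those of a 1.5 s cycle (the k-th harmonic is scaled by exp(−2π²k²σ²/d²)),
so the same movement pattern executed at different tempos would map to
different trajectories; tying the bandwidth to the cycle keeps the
normalized representation tempo-invariant while equaling a 90 ms smoothing
at the nominal 1.4 s cycle. Samples just outside the segment (within the
kernel support) are used when available, so interior cycle boundaries incur
no edge bias.

## The Markov-Gaussian classifier

Each gear g is modeled generatively over the normalized trajectory
v₁…v₁₀₀ (vₜ ∈ ℝ³):

- v₁ ~ N(μ₁, S₁),
- vₜ | vₜ₋₁ ~ N(Aₜ vₜ₋₁ + bₜ, Qₜ) for t = 2…100,

a first-order linear-Gaussian Markov chain — the minimal model that captures
sequential correlation along the trajectory without the ~45k free parameters
of a full 300×300 covariance (which cannot be estimated from ~50 cycles per
gear) and without discretizing the observations. Per class: 9 first-step
parameters plus 18 per transition, 1791 in total.

**Estimation** is conditional least squares: μ₁/S₁ are the first-step sample
mean and (unbiased) covariance; (Aₜ, bₜ) is the least-squares linear map from
step t−1 to step t across training cycles (minimum-norm solution when the
system is underdetermined); Qₜ is the mean squared residual. Every covariance
gets ridge·I added (default ridge = 1e-3 (m/s²)², i.e. a 0.03 m/s² noise
floor per axis), guaranteeing positive definiteness even for degenerate
training sets — with ~50 cycles, unregularized 3×3 residual covariances are
occasionally near-singular. Training is deterministic; fitted classifiers
serialize to JSON bit-reproducibly.

**Classification** evaluates the chain log-likelihood (computed in the log
domain via per-step Cholesky factors; for small chains it equals the density
of the implied joint Gaussian to better than 1e-8, which the tests verify
against an independent joint-covariance construction) under all five gear
models and takes the argmax. Class priors are equal; exact ties resolve to
the earlier gear in canonical order (G2L, G2R, G3, G4L, G4R). Cycles are
classified independently — no temporal label smoothing — so per-cycle output
can be compared directly against a reference timeline and errors attributed
to specific cycles.

Two training regimes are distinguished only as a provenance tag: `collective`
(pooled multi-source corpus) vs `individual` (one skier's calibration trial);
the estimator is identical.

## Evaluation layer

Reference labels are gear intervals over time; each cycle receives the gear
with the largest duration overlap (ties to the earlier interval; cycles with
zero overlap are excluded from scoring rather than counted as errors, since
a complete reference labels every cycle and gaps only arise from user data).
Scoring produces the 5×5 confusion matrix (reference rows, predicted
columns; row percentages; text cells formatted `n (%)`), overall and
per-gear accuracy, and an error breakdown with precedence startup >
transition > other: a misclassified cycle at index j is *startup* if j < k
(default k = 3), else *transition* if within w cycles of a reference gear
change (default w = 1: the last cycle of the old gear and the first of the
new), else *other*. The windows are configurable since no canonical
definition exists. `paired_t_test` operates on differences b − a with n−1
degrees of freedom (all-zero differences return t = 0, p = 1; identical
nonzero differences are rejected as degenerate); `pearson_r` is the standard
product-moment coefficient. Both delegate p-value computation to scipy.

## Synthetic data generator

Each gear's template is a low-order Fourier series per axis (harmonics ≤ 4)
of cycle phase, hand-designed to echo the qualitative plane shapes of chest
acceleration during skating (G2's lateral–horizontal "half-moon" coupling,
G3's near-symmetric "butterfly") — they are not fits to measured data, which
are not available in tabulated form. Structural invariants are built in:
G2R/G4R are exact lateral mirrors (ax → −ax) of G2L/G4L; G3's lateral axis
uses odd harmonics only, giving ax(φ) = −ax(φ+½); every template's dominant
vertical minimum sits at phase 0 so constructed boundaries coincide with
detected ones; pairwise template RMS separation on a 100-point phase grid
exceeds 1 m/s² (minimum ≈ 2.0, smallest for G3 vs G4L).

A session is rendered by concatenating cycles with per-cycle duration
N(1.4 s, 0.1 s) (clipped to ±4 SD) and amplitude scale N(1.0, 0.05), sampled
at 80 Hz with timestamp jitter N(0, 1 ms) (clipped to ±40% of the sample
period so timestamps stay strictly increasing), plus independent per-axis
Gaussian noise (default SD 0.3 m/s²). All draws flow from one seeded
generator, so fixtures are bit-reproducible. Fixed-gear trials emulate the
~50-cycle calibration runs; the variable protocol draws 1+Poisson(23) blocks
with lengths 1+Poisson(140/24 − 1) and gear probabilities proportional to
target shares 30/27/30/26/26 (excluding immediate repeats), calibrating
expected totals to ~140 cycles and ~23 transitions. Transitions are
instantaneous at block boundaries; no morphing cycle is synthesized.

**What passing synthetic tests do and do not show.** The generator produces
exactly the cyclic structure the pipeline assumes: stationary templates,
well-separated class means, stationary noise, and transitions aligned with
cycle boundaries. Perfect fixed-gear accuracy on this data demonstrates the
pipeline's internal consistency — segmentation, normalization, estimation
and scoring compose correctly — not field performance. Real recordings add
inter-skier template variability, postural drift of the sensor frame,
terrain-driven amplitude changes and blurred transitions, none of which are
modeled. The one qualitative field finding the synthetic setup does
reproduce is the error geography: when noise is elevated (2.5 m/s²), the
rare misclassifications concentrate in cycles straddling gear transitions,
because only there does an extracted cycle mix two movement patterns.

## Problem sizes and defaults used in the checks

The automated checks run the full pipeline at the study's natural scale —
50 cycles per gear for training and evaluation trials, ~140-cycle variable
sessions — since a complete run takes on the order of a second. Monte-Carlo
checks (parameter recovery, noise-degradation, transition concentration) use
20 seeds; chain-vs-joint equivalence uses 3–4 steps where the joint
covariance is cheap to assemble; recovery checks use 40-step chains, which
exercise the same per-step estimator as the 100-step default.

## Known limitations

- The chain's exact original parameterization (state tying, covariance
  structure) is not fully specified in public sources; the first-order
  linear-Gaussian form here is the minimal model matching the published
  description and may differ in detail from the original implementation.
- No on-line classification, no transition-type modeling, no gyroscope or
  magnetometer fusion, no gravity removal.
- The segmentation axis and boundary criterion (vertical-axis minima) are
  documented defaults; signals whose vertical oscillation is not dominant
  may need `segmentation_channel="magnitude"`.
- Table-style confusion matrices averaged over many subjects cannot be
  reproduced without the original raw data; the evaluation layer computes
  per-run matrices and the statistics needed to aggregate them.
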