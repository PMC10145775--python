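# Methods

This note records the models, conventions and numerical choices behind
`gaitring`, in the order the pipeline applies them, together with what the
synthetic protocol does and does not emulate.

## Signals and preprocessing

A recording is six synchronized channels from a single lower-back (L5) IMU
at 100 Hz: accelerations (g) and angular velocities (deg/s) mapped onto the
craniocaudal (CC), mediolateral (ML) and anteroposterior (AP) anatomical
axes. The device-to-anatomy mapping, including signs, is explicit metadata
(`axis_map`, e.g. `{"cc": "-y", "ml": "x", "ap": "z"}`) so recordings from
differently mounted sensors normalize to the same frame.

All six channels are band-pass filtered to 0.5–5 Hz with a 4th-order
Butterworth filter before anything else; segmentation features,
classification features and gait criteria all consume the filtered
recording. The filter is applied forward–backward (zero phase, effective
magnitude order 8): the autocorrelation peak *lags* used by the symmetry
and steadiness criteria must not be phase-distorted, which a causal
application would not guarantee. The trade-off is a ~1 s edge transient at
each end of the recording and a symmetric smear of sharp events; both are
recording-boundary effects, not regime properties.

The segmentation stage sees only gCC (turns, posture changes) and aAP
(gait onsets/offsets). Each is standardized over the whole recording —
per-recording rather than per-regime, since no segmentation exists yet —
and transformed by a magnitude STFT with a 3 s window and 0.1 s hop. The
hop is read in seconds (10 samples at 100 Hz). A Hann window is used: the
bin count below is window-shape independent and Hann limits leakage across
the narrow band of interest. With a 300-sample window the bin spacing is
1/3 Hz; keeping bins with 0 < f < 5 Hz strictly yields exactly 14 bins per
channel, 28 per frame (inclusive bounds would give 16). A frame's time
stamp is its window center, so frame i covers samples [10·i, 10·i + 300)
and maps to 0.1·i + 1.5 seconds.

## Change-point model and solver

Regime boundaries are modeled as mean shifts of the frame sequence. A
segmentation with interior breakpoints 0 < t₁ < … < t_K < n (0-based,
half-open segments) is scored by the quadratic risk — the total squared
deviation of frames from their segment means — plus a linear penalty βK.
The solver returns the exact global minimizer with K free.

Implementation choices:

* **Cost in O(1).** Segment costs come from cumulative sums of y and ‖y‖²;
  tiny negative rounding residues are clipped to zero.
* **Minimum segment length** of 2 frames (0.2 s) excludes degenerate
  one-frame regimes. The 3.5 s evaluation margin is an evaluation constant
  and plays no role in the solver.
* **Delayed pruning.** PELT's dominance test (discard candidate s at end t
  when F(s) + C(s,t) > F(t)) licenses removal only for end points
  ≥ t + min_size when a minimum segment length is enforced: for ends
  inside (t, t + min_size) the dominating breakpoint at t is itself
  inadmissible. The implementation therefore evaluates the test at
  t₀ = t + 1 − min_size, which reduces to the classic test at min_size = 1.
  The solver is certified risk-exact against an exhaustive O(n²) dynamic
  program (naive two-pass costs, no pruning) on hundreds of random
  instances spanning four orders of penalty magnitude and min_size 1–3.
* **Ties** are broken toward the candidate with the smallest previous
  breakpoint (fewer, earlier breaks), deterministically.
* The inner loop is compiled with numba; an equivalent vectorized numpy
  path exists and is tested against it.

## Penalty calibration

Given annotated recordings (signal i, expert breakpoints {t_k(i)}), the
penalty is chosen to minimize the mean excess penalized risk of the
annotation over the β-optimal segmentation. The excess is non-negative by
solver optimality and zero exactly where the solver reproduces the
annotation, so the minimizer is the penalty at which the solver behaves
like the expert. Annotated times are snapped to the nearest frame index
before evaluation.

The objective is piecewise-constant in stretches, so a pure scalar search
can stall on flat steps. The search therefore runs on log₁₀ β over
[−4, +4], scaled by the mean per-frame variance of the training signals
(making the bracket dimensionless), seeds with a 25-point grid, and lets a
bounded Brent refinement polish the best bracket. Joint minimization of the
*mean* gap across signals is the default; a per-signal mode (one β per
signal, aggregated by the median) is available behind a flag.

## Regime classification

Classification is regime-level, not sliding-window: segmentation guarantees
within-regime stationarity, and regimes are longer than typical HAR frames,
so features are computed on more data. Each regime yields 129 features: for
each of the six channels, 21 statistics (mean, unbiased SD, variance, min,
max, periodogram dominant-peak power/frequency and second-peak
power/frequency, coefficient of variation, nearest-rank percentiles
75/25/85/15/95/5, the 75/25/85/15 percentiles of the central two-thirds of
the regime, RMS), plus the two craniocaudal autocorrelation peaks and the
mean acceleration vector magnitude.

Conventions that needed fixing:

* Percentiles use the nearest-rank rule (R = ⌈q·n/100⌉-th sorted value).
* "Middle of the signal" is the central two-thirds window [n/6, 5n/6).
* The periodogram is |FFT|²/N with the DC bin dropped; the second dominant
  peak is the largest *local* maximum outside a ±0.2 Hz guard band around
  the first (the adjacent bin of the main peak would otherwise always win)
  and must carry more than 10⁻¹² of the main peak's power, else 0 is
  recorded.
* The coefficient of variation is ill-conditioned on band-passed signals,
  whose mean is at rounding level; it is imputed as 0 when
  |mean| < 10⁻⁹·SD, extending the zero-variance imputation.
* Features are standardized, then projected onto the smallest number of
  principal components reaching 99 % cumulative explained variance.
* Both cascade stages are linear soft-margin SVMs with C = 1 (no tuning);
  stage 1 sees all regimes (walking vs rest), stage 2 only the non-walking
  training regimes (sedentary vs non-sedentary). A stage-1 walking
  prediction is final and never reaches stage 2.

The documented feature enumeration totals 129; the count is configuration
metadata, not an assertion, and the vector's names and order are fixed and
serialized with the model.

## Gait criteria

Four unitless criteria per walking regime, all on filtered accelerations:

* **RMSR_ML (stability, lower is better)** and **RMSR_AP (sturdiness)**:
  per-axis RMS divided by the three-axis RMS magnitude
  RMS_A = √(RMS_ML² + RMS_CC² + RMS_AP²). The three ratios satisfy a
  Pythagorean identity (∑ ratio² = 1), checked to 10⁻¹².
* **P1CC (symmetry)** and **P2CC (steadiness)**: peaks of the unbiased
  autocorrelation of the craniocaudal acceleration at one- and two-step
  lags. The autocovariance is computed by FFT (Wiener–Khinchin) with
  zero-padding to ≥ 2n so the circular convolution never wraps, each lag
  divided by (n − lag), normalized to ACF[0] = 1.

Peak extraction is windowed by cadence rather than "first two local
maxima": P1 is the ACF maximum over lags in [0.5, 1.5] step periods, P2
over [1.5, 2.5], with the step period taken from the periodogram dominant
frequency of the regime's craniocaudal channel. Without the windows, noise
lobes below the step lag would capture P1. When the discrete maximum is
interior to its window a 3-point parabolic fit refines the peak value,
because the true step lag rarely falls on an integer sample and the
quantization otherwise adds ~0.002 of spurious jitter to the peak height.
A single shared implementation serves both the scoring criteria and the
P1/P2 classification features.

Criteria are defined only on regimes long enough to support the two-step
lag window; the pipeline scores walking regimes of at least 4 s and leaves
shorter fragments (typically turn slivers from over-segmentation) labeled
but unscored.

## Healthy model and display bins

From all healthy walking regimes, each criterion gets a mean μ and SD σ
(ddof = 1); new regimes are z-scored as z = (x − μ)/σ. Display bounds
[x_min, x_max] are the 10th and 90th percentiles of the *z-scored* healthy
values — distribution-dependent constants, not the Gaussian ∓1.28, since
normality is not assumed. By construction ~80 % of healthy regimes fall in
the band, up to nearest-rank rounding.

For display, scores are oriented so larger always means better (RMSR_ML is
negated). The five bins are: within the oriented band; "slightly"
below/above when within half the healthy inter-percentile range beyond a
bound — the chosen quantification of a category the display needs but no
closed-form rule defines; "well" below/above beyond that.

## Evaluation machinery

* **Change-point metrics.** A predicted breakpoint is a true positive if it
  pairs one-to-one with an annotated one within 3.5 s; matching is greedy
  over increasing |Δt|, which coincides with optimal assignment whenever
  the margin does not exceed the minimum true inter-break spacing (the
  margin's own admissibility condition). Precision = TP/K, recall = TP/K*,
  F1 their harmonic mean; an empty prediction with non-empty truth scores
  precision 0, not NaN.
* **Joint sample-scale confusion.** Each 100 Hz sample inherits the label
  of the regime containing it (truth from annotation, prediction from the
  segment + classify chain); the matrix is row-normalized to percentages.
  No boundary samples are excluded.
* **Cross-validation** is subject-wise and balanced on the healthy flag,
  deterministic under a seed.
* **Degraded-window robustness.** Each criterion is recomputed on 10
  sub-windows of a regime (full; first 3/3.5/4/5 s; first 40 %; 40 %
  starting at 20/30/40 %; last 40 %), summarized per regime by median and
  IQR, with healthy cohort overlays (mean, 25th/75th percentiles).

## The synthetic protocol

The generator emulates a six-minute semi-controlled lap protocol:
W1 (60 s), A1 door + 90° turn (15 s), W2 (45 s), W3 (45 s), A2 stairs
(25 s), A3 leaning (20 s), A4 standing (20 s), A5 sitting (30 s), W4
(50 s), W5 (50 s). A1/A2 are non-sedentary (moving, not walking), A3–A5
sedentary (still) — the regime-type assignment follows the protocol's
transition table.

The gait waveform is a harmonic series (fundamental + 2 harmonics) at the
step frequency plus a stride-frequency (half-cadence) admixture of relative
amplitude `asymmetry_delta`; the stride phase advances π per step with
Gaussian step-period jitter. This keeps the spectrum analytically
checkable and gives each knob a monotone link to exactly one criterion:
`amp_ml` → RMSR_ML, `amp_ap` → RMSR_AP, `asymmetry_delta` → P1CC (down,
with P2CC nearly unchanged), `timing_jitter_sd` → P2CC (down). Healthy
defaults: cadence 1.9 Hz, amplitudes (CC, AP, ML) = (0.30, 0.20, 0.12) g,
asymmetry 0.05, jitter 10 ms, sensor noise 0.02 g — typical adult
free-walking values. Each walking bout carries a small per-bout cadence
(±0.25 Hz) and amplitude (±15 %) variation: subjects do not walk
identically on every lap, and walk-to-walk boundaries would otherwise be
statistically invisible.

Transitions are what make the protocol segmentable, so the generator
models them explicitly: blocks join with 0.1 s linear cross-fades (ground
truth at the fade midpoint); lap corners between consecutive walking bouts
are 1 s Gaussian gCC turn pulses; every activity block opens with a
smoothly decaying posture-change burst (strong trunk rotation, moderate
acceleration) — sitting down or leaning in *is* a movement, and it is what
makes activity-to-activity transitions annotatable at all. Sedentary
content is low-variance noise over slow drift; non-sedentary content is
broadband bursts under random smooth envelopes, overlapping the gait band
without sustained periodicity. The default noise and transition scales
were chosen so that segmentation at the calibrated penalty is clearly
solvable but not degenerate (held-out F1 around 0.8, matching the regime
the method is designed for).

Cohorts draw healthy knobs near the defaults (asymmetry ≤ 0.1, jitter
5–15 ms) and cycle pathological subjects through four subtypes, each
degrading the knob of one criterion anchored on the healthy population
mean (e.g. stability subjects draw amp_ml at 2.5–3.5× the healthy mean).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: biomechanical waveform realism (no
double-support timing, no inverse dynamics), stair-specific morphology,
fall events, sensor drift or saturation, and real annotation noise (ground
truth here is exact by construction). Real cohorts also show wider
between-subject spreads of the autocorrelation criteria than the clean
harmonic waveform produces.

## Known limitations

* The steadiness/symmetry criteria on 3–5 s windows inherit a
  partial-period edge bias of the unbiased short-window ACF on the order
  of 0.002; relative to the synthetic healthy cohort's tight P1CC spread
  this is visible in the degraded-window study (it would be negligible
  against realistic between-subject spreads).
* The penalty transfers across recordings only insofar as their spectral
  scale matches the calibration set; recordings from different sensors
  should be recalibrated.
* Sample-scale confusion near regime boundaries is bounded by the 0.1 s
  hop and the 3 s window smear of the spectral representation; boundary
  placement below ~1 s is outside the method's resolution by design.
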