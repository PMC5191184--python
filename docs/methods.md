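# Methods

This note documents the models implemented in `gaitvel`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Signal model and frames

All streams share one axis convention: X antero-posterior (positive
forward), Y medio-lateral (positive right), Z vertical (positive **down**,
aligned with gravity).  Accelerometers report specific force in the sensor
frame, so a sensor at rest with axes aligned to the global frame reads
(0, 0, −g).  Strap-down rotation maps specific force through the supplied
orientation quaternion (sensor → gravity-aligned global frame) and adds
g_vec = (0, 0, +9.80665) m/s², leaving linear acceleration.  Orientation
estimation itself is an input: the package neither filters gyroscopes into
attitude nor uses magnetometers.

During steady-state walking, segment accelerations are treated as
quasi-periodic: within stride *k* of duration *T_k*, each axis is a
truncated Fourier series with fundamental period *T_k*.  Six harmonics
capture pelvis acceleration; two are enough for the shank features.

## Per-stride Fourier fitting and integration

`fit_fourier` projects one stride of samples onto
{1, sin(i·2πt/T), cos(i·2πt/T)}, i = 1..M:

* when the samples form a uniform grid tiling exactly one period, the
  discrete basis is orthogonal and the projection is computed directly —
  exact to machine precision for band-limited signals, and the coefficients
  of low orders are unchanged when the order is raised;
* otherwise (stride durations that are not a whole number of samples,
  non-uniform timestamps) the coefficients come from ordinary least squares
  on the basis evaluated at the sample times.  No resampling or
  interpolation is performed anywhere: interpolating 100 Hz samples onto a
  projection grid was measured to leave ~1e-4 m/s² coefficient error, which
  is the dominant error term in otherwise noise-free processing.

No roughness penalty or basis smoothing is applied: reproducibility and
exact orthogonality were preferred over unspecified smoothing, so numerical
equality with functional-data-analysis toolboxes that smooth is not
claimed.  Strides with fewer than 2M + 1 samples are skipped with a
warning.

Analytic integration maps (a_i, b_i) → (T b_i / 2πi, −T a_i / 2πi) with the
DC term removed; the result is the zero-mean cyclical velocity.  Removing
the DC before integration is what makes the estimate immune to constant
acceleration offsets (gravity residuals) and integration drift.

The phase-angle form uses c_i = √(a_i² + b_i²), φ_i = atan2(b_i, a_i), with
the branch fixed to (−π, π] (the conversion formula does not fix a branch
by itself; this one is asserted by the validators).

## Gait-phase HMM

Four states correspond to the phases opened by foot strike (FS), flat foot
(FF), heel off (HO) and toe off (TO).  Observations are 2-D: the shank ML
angular velocity and its backward first difference (per sample, not divided
by Δt — the scale is absorbed by the learned covariances; documented for
reproducibility).  The transition topology is circular left-right: states
may persist or advance to the next phase, TO-phase wraps to FS-phase so
consecutive strides chain; forbidden transitions are structural zeros, not
small probabilities.

Supervised training: transition probabilities from labeled transition
counts; per-state emission mixtures (3 components, full covariances) by EM
with k-means initialization, a 200-iteration cap, 1e-6 tolerance and a
fixed seed; initial distribution from first-label frequencies, floored at
1e-12 so a sequence starting in an unseen phase still decodes.  A state
with fewer than 3 × (components) samples aborts training with a message.

Decoding is Viterbi, with ties broken toward the lower state index.
Per-sample posterior maximization would be the alternative; Viterbi was
chosen because it is deterministic, respects the topology by construction,
and is directly testable against exhaustive path search (the test suite
verifies equality on all 4^N paths for N ≤ 8).

Event times are the first sample of each new phase occurrence; phase
intervals are half-open, so a sample exactly at an event belongs to the
later phase.  Temporal gait parameters per cycle are the stride time
T_FS(k) = t_FS(k+1) − t_FS(k) and the FS→FF, FS→HO, FS→TO durations.

## ARD Bayesian linear regression

Linear-Gaussian model with a bias term (the input is augmented with a
constant 1) and an independent zero-mean Gaussian prior of precision β_i on
every weight.  Features are standardized internally and the moments stored
for prediction; without this, the comparison of β_i across features with
units as different as seconds and m/s² would be meaningless.  For fixed
hyperparameters the posterior is Gaussian with μ = αΣΦᵀv,
Σ = (B + αΦᵀΦ)⁻¹, solved by Cholesky factorization; the log evidence is
evaluated through the same factorization
(ln|C| = −N ln α − Σ ln β_i + ln|A|, vᵀC⁻¹v = α‖v − Φμ‖² + μᵀBμ) rather
than the N×N covariance.

Evidence maximization uses the fixed-point updates γ_i = 1 − β_iΣ_ii,
β_i = γ_i/μ_i², 1/α = ‖v − Φμ‖²/(N − Σγ_i), initialized at β_i = 1,
α = 1/var(v), iterated to a 1e-6 relative tolerance (cap 1000 cycles).  The
optimizer contains no randomness.  Numerical guards: β clipped to
[1e-12, 1e16], α capped at 1e12 (reached only for exactly noise-free
targets), a weight whose posterior mean is exactly zero is marked
irrelevant, and the α update is skipped with a warning if the effective
degrees of freedom N − Σγ are non-positive.

**Pruning.**  After each update cycle, features whose β_i exceeds 200 times
the noise precision are removed from the active set and never re-enter; the
bias is exempt (pruning it would force a zero-mean speed model).  The
threshold is compared against the noise precision **that produced the
current posterior** — the pre-update α of the cycle — not the value just
re-estimated.  This applies the rule along the hyperparameter trajectory:
the precisions of irrelevant weights diverge within the first cycles while
α is still rising from its conservative start at 1/var(v), so irrelevant
features are removed reliably.  Comparing against the converged α instead
lets a pure-noise feature survive whenever its chance sample correlation is
modest (roughly a 1-in-16 event per feature), which destroys the
all-noise-features-pruned behaviour the method is meant to exhibit; the
package's acceptance checks measure a 100/100 success rate under the
trajectory comparison versus ~68/100 under the converged-α comparison.
A corollary of the trajectory rule: a feature is kept only if its
standardized weight is large enough relative to the total target spread
(|w_std| ≳ sd(v)/√200).  Features below that relevance scale are treated as
irrelevant even if their true weight is nonzero; their contribution to the
prediction is below sd(v)/14 by construction.

Prediction returns a Gaussian with mean μᵀφ(x) and variance
1/α + φ(x)ᵀΣφ(x) ≥ 1/α.

## Pipeline and LOSO protocol

Per trial: HMM segmentation of the shank stream → strap-down rotation of
the pelvis stream → per-stride cyclical velocity (M = 6) → shank feature
vector (M = 2, d = 16) → ARD prediction of the APV → composition.  The APV
is added to the AP axis of the gravity-aligned frame; this assumes
straight-heading walking, and heading tracking for curved paths is out of
scope.  A configurable initial window (default 30 s) can be discarded as a
speed-up transient; the synthetic trials are steady-state from the first
stride, so the leave-one-subject-out driver runs with the window off.

Leave-one-subject-out validation trains the HMM on the ground-truth phase
labels and the ARD regression on features extracted at the ground-truth
events of the training subjects, then processes each held-out subject with
the full pipeline (detected events included).  Estimated strides are
matched to reference strides by nearest foot strike within half a median
stride; unmatched estimated strides count as insertions, unmatched
reference strides as deletions.

## Agreement statistics

* **Reference progression speed** from a marker trajectory: X/Y coordinates
  low-pass filtered with a forward-backward 2nd-order Butterworth filter
  (3 Hz cut-off), differentiated by first central differences, combined
  into the horizontal-plane norm and averaged per gait cycle.
* **Two-stage errors**: per-subject means m_n (and RMS values e_n) first,
  then MBE = mean(m_n), RMSE = √mean(m_n²), ARMSE = mean(e_n).  The
  two-stage ordering is intrinsic — it prevents subjects with many strides
  from dominating — and ARMSE, unlike RMSE, retains intra-subject
  variability.
* **Regression-based limits of agreement**: with D = est − ref and
  A = (est + ref)/2, OLS of D on A gives the bias line; OLS of |D − bias
  line| on A gives the residual line (absolute residuals about the fitted
  bias line — the standard regression variant; residual-SD-within-bins
  would be the alternative and is not implemented); limits are
  bias ± 2.46 × residual line.  The multiplier 2.46 is stored as a named
  constant as conventionally printed, not recomputed from 1.96·√(π/2), so
  reports match the convention digit for digit.  The summary half-width
  averages the (floored-at-zero) half-width over the central 95% of A,
  defined by symmetric 2.5/97.5 percentile trimming.  Classical constant
  limits (MD ± 1.96 SD) are always reported alongside, and are the
  fallback when A has zero variance.

## Synthetic-gait generator

The generator defines the benchmark conditions; defaults describe healthy
adults at a comfortable speed:

| parameter | default | meaning |
|---|---|---|
| n_subjects × n_strides | 10 × 100 | cohort size |
| sampling_rate | 100 Hz | both IMUs |
| mean_stride_time / CV | 1.1 s / 4% | stride-to-stride timing variability |
| event_fractions | 0.12, 0.40, 0.62 | FF/HO/TO as fractions of the stride |
| event_fraction_jitter_sd | 0.008 | per-stride event-timing jitter |
| pelvis harmonics | ≈0.8–1.5 m/s² in c1, decaying to c6 | per-axis amplitudes |
| shank accel harmonics | ≈0.4–2.5 m/s² (M = 2) | feature carriers |
| subject / stride amplitude CV | 15% / 5% | between- and within-subject spread |
| accel / gyro noise SD | 0.05 m/s² / 0.02 rad/s | white sensor noise |
| APV target noise | 0.05 m/s | unexplained speed variability |
| swing peak | 4.0 rad/s | shank ML template maximum |

Pelvis acceleration is exactly the harmonic model per stride (with phases
drawn once per subject, so features carry subject-level structure and LOSO
is meaningfully stressed), which makes the cyclical-velocity truth
available in closed form.  The APV is a linear function of the stride time
(−1.5 s⁻¹), the stance duration (−0.6 s⁻¹) and the six shank acceleration
amplitudes (0.12–0.5 per m/s²), intercept 1.95, giving ≈1.35 ± 0.10 m/s;
weights were chosen once so that every informative feature sits comfortably
above the ARD relevance scale discussed above, with gyroscope amplitudes
and the FF/HO durations deliberately carrying no signal.  The shank ML
angular-velocity template is piecewise smooth with four non-overlapping
phase levels (deep post-FS excursion, near-zero flat-foot plateau, moderate
HO dip, large swing bump); it is an implementation constant chosen for
qualitative similarity to shank gait signals — no quantitative waveform
description exists to match, so its realism is not asserted.  Each trial is
generated ~0.3 stride past the last reported foot strike so that a decoder
can observe the closing foot strike of the final cycle.

**What the benchmark does not show.**  The generator draws accelerations
from the same model family the estimator fits, so the cyclical-velocity
results demonstrate correctness of the machinery, not robustness to
out-of-model signal content (soft-tissue artifact, sensor bias drift,
asymmetric gait).  The shank template is idealized, so event-detection
accuracies transfer to real data only qualitatively.  The APV truth is
linear in the extracted features by construction; real walking speed is
not, and real-data errors will be correspondingly larger.

## Numerical choices and degenerate inputs

* Stride-boundary classification uses half-open intervals with a 1 ns
  tolerance absorbing float representation error of accumulated event
  times.
* Zero-variance feature columns are retained unscaled with a warning.
* Cycles violating the event ordering, and strides too short for the
  harmonic basis, are skipped with warnings rather than failing the trial.
* Decoded paths that never complete a cycle produce an empty, warned
  result; an empty stride set propagates as an empty estimate with a
  diagnostic.
* Exact ties in Viterbi scores resolve to the lower state index.

## Known limitations

Single straight-heading composition convention; no orientation estimation;
no online/streaming decoding; no Baum-Welch (unsupervised) HMM training;
no subject-specific calibration or personalization of the speed model; the
agreement module reports point estimates of the limits of agreement
without confidence intervals.
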