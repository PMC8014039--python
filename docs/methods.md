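# Methods

`strideforge` estimates overground running speed from a foot-worn IMU
(triaxial accelerometer ±16 g and gyroscope ±2000 deg/s at 500 Hz, barometer
at 50 Hz, one unit per foot) validated against a GNSS speed reference
(10 Hz).  Three estimators share a common signal chain; a synthetic gait
generator provides exact ground truth so every stage is testable without
recordings.

## Reference speed (GNSS)

Raw receiver speed is cleaned by two filters — samples outside 5–20 km/h
and samples whose per-sample accuracy estimate exceeds 0.15 m/s are
discarded — then smoothed with a 0.5-s moving average on the surviving
(uneven) samples, linearly interpolated onto a uniform 10-Hz grid, and
low-pass filtered with a zero-phase 4th-order Butterworth at 0.25 Hz.
Zero-phase filtering is a deliberate choice: estimates and reference are
compared per step, and a causal filter's group delay would bias that
alignment.  Gaps longer than 5 s (a configurable guard against receiver
dropouts) are flagged invalid rather than interpolated.  The final output
rate is configurable (`out_rate`); the default keeps 10 Hz.  The per-step
reference label is the mean of `v_ref` over the step window [IC_i, IC_i+1).

## Signal chain

1. **Filtering.** Zero-phase 4th-order Butterworth, 50 Hz cut-off, on
   acceleration and angular velocity.
2. **Frame alignment.** Data are expressed in the foot *functional frame*
   (x longitudinal, y vertical up, z mediolateral right).  The rotation may
   be supplied from an external calibration, or estimated from a level
   segment: vertical axis from the mean specific force over the most static
   window; mediolateral axis from the first principal component of the gyro
   samples during movement, signed so the sustained mid-swing pitch lobe is
   positive (the brief contact dips can be deeper, so sign selection
   compares time-beyond-threshold, not extremes); the longitudinal axis
   completes the right-handed triad.  This is a simplified functional
   calibration; published multi-posture calibration procedures are
   deliberately out of scope and can be substituted through the same
   rotation interface.
3. **Slope.** Barometric pressure → altitude via the standard-atmosphere
   hypsometric formula `h = 44330 (1 − (p/p0)^0.1903)` (p0 = 1013.25 hPa,
   configurable; a temperature-corrected variant is not implemented), 4-s
   moving average, 1-Hz down-sampling.  Slope `s(t)` is the altitude
   difference across a 5-s span, kept in its native unit (metres per 5 s).
   The differencing is *centered* (±2.5 s) so the slope series carries no
   lag relative to the stride labels; edge samples fall back to one-sided
   differences and are flagged.
4. **Gait events.** The run is segmented into mid-swing cycles: positive
   peaks of the pitch-rate (gyro z) with a minimum spacing of κ·T (κ = 0.5)
   where the period T comes from a YIN estimator (cumulative-mean-normalized
   difference function over 10-s windows with 5-s overlap, absolute
   threshold 0.15, parabolic lag refinement).  Within each cycle, initial
   contact (IC) and terminal contact (TC) are the two most prominent
   pitch-rate minima in time order; MinRot is the argmin of ‖ω‖ within
   [IC, TC] (earliest sample on ties).  Temporal parameters per step over
   the merged two-foot IC sequence: CT = TC−IC, FLT = IC₊₁−TC,
   SWT = IC₊₂−TC, STP = IC₊₁−IC, STR = IC₊₂−IC.  Strides with STR outside
   [0.37, 2.5] s (inclusive) or FLT ≤ 0 are discarded.
5. **Strapdown.** Orientation is anchored at each MinRot, where the foot is
   closest to static: tilt from the mean specific force over a 20-ms window
   (anchors whose specific-force norm deviates from 9.81 m/s² by more than
   20 % are excluded), propagated between anchors by body-rate quaternion
   integration.  Heading is left unresolved — pitch and speed magnitudes,
   the only quantities used downstream, are heading-invariant.  Gravity
   ([0, 0, 9.81] m/s², global z up) is removed, acceleration integrated by
   the trapezoidal rule from each anchor with v(MinRot) := 0, and the
   residual at the next anchor removed by a correction linear in time (the
   standard zero-velocity-update de-drift; a literal stance clamp between
   MinRot and TC is available behind `mode="clamp"`).  The corrected
   velocity is reported in both frames; `v_foot` is the functional-frame
   series.  Pitch at IC is the arcsin of the vertical component of the
   rotated longitudinal axis (positive = rear-foot landing).

## Direct estimator

Per step, the default estimate is the mean of ‖v_foot‖ over the stride
window [IC_i, IC_i+2).  On ideal signals this overestimates slightly —
the foot's path (with its vertical arc) is longer than its displacement —
while any loss of flight-phase observability biases it low; the
forward-component mean (`mode="forward"`) is exact on clean signals and is
what the exactness tests assert.  The collapse rule from the continuous
velocity to a per-step number is an interpretation (it matches the
`mean_vfoot_norm` feature); both variants are exposed.

## Feature table

Per stride (window [IC_i, IC_i+2)): 11 statistics — mean, sample std
(ddof = 1), median, IQR (linear-interpolation quantiles), max, RMS,
kurtosis (Pearson, non-excess, biased), skewness (biased), and the three
AR(3) Yule–Walker coefficients (MLE autocovariance normalization, solved
directly per channel) — for 13 channels (acceleration, angular velocity
and v_foot × {x, y, z, norm}, plus slope), slope statistics using the 1-Hz
samples overlapping the stride (nearest sample if none).  With the five
temporal parameters and the pitch at IC this gives 149 base features,
each augmented by f1(p) = p², f2(p) = p³, f3(p) = 1/p (f3 of a zero is
masked NaN for that row), plus height, weight, gender ∈ {0, 1} and age:
600 candidate columns.  Each step carries the features of the stride its
foot initiated; the label is the mean reference speed over the step.
Normalization is a robust z-score — subtract the mean, divide by the
unscaled median absolute deviation — with training-set statistics applied
unchanged to held-out subjects.

## Generic linear model

Forward stepwise selection runs on a development subject set disjoint from
the train/test pool: candidates (each base feature and each transform
separately) are added greedily by the mean ordinary-least-squares MSE over
leave-one-subject-out folds, stopping when the relative gain drops below
1 %.  Final training uses the LASSO on inputs scaled to zero mean and unit
variance; along the regularization path the sparsest model is kept unless
the next denser one improves the *training* MSE by ≥ 2 % (the MSE source
is configurable; validation-fold MSE is the alternative).  Training rows
are rebalanced by random under-sampling over five speed bins
(1.4–2.2–3.0–3.8–4.6–5.4 m/s) down to the least-populated bin, repeated
ten times by default with independent draws; each repetition yields one
model per held-out subject.  Input averaging over k ∈ {2, 4, 6, 8, 10}
consecutive steps (non-overlapping blocks, before under-sampling) and a
centered moving average on the output are both supported.  The presets
`P_MANUAL` (comprehensive set), `P_AUTO_BEST` and `P_MANUAL_BEST` ship as
named feature lists usable without re-running selection.

## Personalized model (RLS)

Stride length `sl = v_ref · STR` (dimensional analysis fixes this reading:
length = speed × time, and speed is recovered as stride length × stride
frequency) is modelled linearly in the stride features with an online
recursive-least-squares update per stride: K = pᵀDp,
D ← D(I − p(I + K)⁻¹pᵀD), β ← β + Dp(sl − pᵀβ).  The recursion is
implemented in matrix form (mini-batches work; for one stride (I + K)⁻¹ is
1/(1 + K)) and is algebraically the Sherman–Morrison update of the
ridge-initialized normal equations — the test suite asserts equality with
the batch solution to 1e-8.  Ten strides initialize β₀ and
D₀ = (PᵀP + 10⁻⁶I)⁻¹; D is symmetrized each update.  No forgetting factor
is used by default (`forgetting < 1` enables one).  Per-subject features
that are constant within the subject (anthropometrics) are absorbed into
the intercept.  Cross-validation splits each subject's strides into
consecutive 10-stride bouts, randomly half training / half testing; the
test RMSE is recomputed after every update stride by default
(`score_every` relaxes this).

## Evaluation

Per subject: bias (mean error), precision (sample STD, ddof = 1), RMSE,
Pearson r; inter-subject aggregates are mean/STD/min/max of these.  Both
the mean of per-subject biases and the pooled-over-steps bias are
reported; they differ on unbalanced data.  A Lilliefors test (KS against a
normal with estimated parameters, Monte-Carlo null with 2000 resamples at
α = 0.05; the null depends only on n and is cached) switches mean/STD to
median/IQR for non-normal error distributions.  Bland–Altman summaries
report the mean difference, ±1.96·STD limits and the least-squares trend
of difference versus mean; the empirical CDF of absolute step errors is
queryable per subject and pooled.

## Synthetic gait generator

The generator produces the statistical structure the estimators assume,
with exact ground truth:

* **Trajectory.** Per stride: stance with the foot exactly stationary at
  ground level (the zero-velocity windows the ZUPT correction needs, each
  ≥ 10 ms by construction); swing as a minimum-jerk forward arc reaching
  the next stance point, with a C²-continuous vertical lift bump (apex
  0.10 m) so the planted acceleration is continuous and trapezoid
  integration of the noise-free signals recovers the ground-truth velocity
  to < 0.1 % relative error at 500 Hz.
* **Pitch.** The sagittal rate is a sum of analytic cos² lobes: a fixed
  −10 rad/s impact dip centered exactly at IC, a recovery lobe settling
  the pitch by mid-stance, a push-off lobe reaching the toe-off angle at
  TC (default −20°), and a positive mid-swing lobe closing the loop — so
  the event detector's landmarks (positive mid-swing peak, two stance-edge
  minima, a quiet MinRot window) exist by construction, for rear-foot
  (default +10° at IC) and forefoot (negative) strikers alike.
* **Speed and schedule.** A commanded speed profile drives an IC schedule
  through a cadence map (default stride frequency 1.2 + 0.06·v Hz) and a
  duty-factor map (contact fraction 0.42 − 0.04·(v − 3), clipped below
  0.5 so flight always exists); the per-stride speed label is exactly the
  stance-to-stance displacement over the stride duration.  The right
  foot's ICs interleave at the midpoints of the left foot's.
* **Subject heterogeneity.** `speed_offset` (cohort STD 0.15 m/s) shifts
  the speed at which the cadence/duty maps are evaluated, so subjects
  trade stride frequency against stride length differently — the
  inter-subject structure a generic model cannot absorb and
  personalization can.
* **Flight-phase observability.** Optionally, a per-stride fraction of the
  swing translational acceleration (mean 0.05, STD 0.03 in cohort
  generation; zero by default) is withheld from the accelerometer output.
  This emulates the physical fact that a foot-mounted accelerometer does
  not fully capture translational motion during flight: it biases the
  strapdown foot speed low, stride-to-stride, making foot-speed features
  informative but imperfect proxies.  Without it, ideal sensing makes
  `mean_vfoot_norm` an essentially exact speed proxy and no generic-model
  bias can arise — a regime real recordings do not exhibit.
* **Sensors.** Accelerometer output is the exact specific force (second
  derivative of the trajectory plus gravity) rotated into the foot frame;
  gyro carries the planted pitch rate; the barometer encodes the foot's
  altitude through the inverse hypsometric formula; GNSS samples the
  commanded speed at 10 Hz with optional noise and injected outliers
  guaranteed to fail the reference filters.  Noise densities default to
  0.02 m/s²/√Hz (accelerometer), 0.005 rad/s/√Hz (gyro), 0.03 hPa
  (barometer) and 0.1 m/s (GNSS speed).  All randomness flows from the
  scenario seed; outputs are bit-identical under a fixed seed.

**What the generator does not emulate:** soft-tissue and mounting
vibration, turning and curved paths, treadmill mechanics, magnetometer or
temperature effects, GNSS multipath structure, and the true biomechanical
coupling between slope and gait.  Tests passing on synthetic cohorts
demonstrate algorithmic correctness and the claimed statistical behaviors
(bias structure, personalization, averaging trends) under the stated
assumptions — not field accuracy on real runners.

## Problem sizes and numerical choices

Cohort experiments use 12 subjects × 120 s sessions (≈ 330 steps each) for
the personalization study and 4 × 90 s cohorts over 10 seeds for the
averaging trend; these sizes give stable Monte-Carlo estimates of the
properties of interest while keeping the whole suite quick to run.
Tolerances: rotations validated to 1e-6 orthonormality; RLS↔batch
equality asserted at 1e-8; LASSO path solved to coordinate-descent
tolerance 1e-6 (tightened to 1e-12 where the OLS limit is checked);
drift-corrected velocity is exactly zero at anchors by construction.
Degenerate inputs: constant feature windows flag their shape statistics
and are set to 0; constant columns are excluded from normalization and
selection; rank-deficient RLS initializations raise.

## Known limitations

The orientation estimator is a tilt-anchored stand-in, adequate for speed
magnitudes but not for heading-dependent quantities.  The direct
estimator's norm-mean variant carries a small geometric positive bias on
clean data.  The stepwise selector is greedy and order-dependent, as
expected of forward selection with correlated candidates.  The synthetic
cohort's "668 available features" cannot be matched exactly — the audited
candidate count here is 600 and is reported as such.
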