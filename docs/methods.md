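# Methods notes

This note documents the models, estimators and numerical choices in
`reaim`, what the synthetic cohorts do and do not emulate, and the known
limitations of the pipeline's self-checks.

## Task designs and the synthetic cohorts

The simulators generate the four task designs the analyses target:

* **Blocked learning (EXP1).** A 2 × 2 between-subject design crossing
  rotation magnitude {25°, 75°} and set size {2, 12 targets}; baseline 36
  trials, rotation 300, washout 36 (the washout length is this package's
  choice; the design fixes only baseline and rotation). Target sequences
  are balanced within cycles, never repeating a location consecutively
  (12T) or more than twice in a row (2T). Early in learning every cell's
  RT carries a mental-rotation cost `pace · |rotation|`; for the 2T cells
  that cost is held for the first 72 rotation trials and ramped off by
  trial 150, emulating the shift from algorithmic re-aiming to cached
  responses. Washout reaches carry a small constant bias (3° in the 2T/25°
  cell, 1° elsewhere) standing in for use-dependent aftereffects — no
  state-space implicit-adaptation model is included, by design.
* **Free-RT trial pairs (FREE).** 140 learning/execution pairs; rotations
  −90°:15°:90°, 10 pairs per size and 20 null pairs; the execution target
  is always one of the three locations the learning target did not use.
  Execution re-aims equal `gain · rotation` with the sign inverted at
  `p_flip`, and execution RT is `t0 + pace · |realized angle| + noise`.
* **Forced-response (FORCED).** 624 rotation trials: 35 at each of 17
  test windows (200–600 ms by 25 ms), 14 at a 1200 ms asymptotic window,
  15 zero-window catch trials; 90° rotation. Realized RT is the window
  minus a truncated-normal earliness (mean 40 ms, sd 40 ms, floored at 0),
  reflecting that subjects move before the deadline; a trial is on time
  when movement onset is within 100 ms of the window. Note that with a
  non-negative earliness every realized RT is at or below its window, so
  essentially all simulated trials are on time; the on-time *rule* is
  still applied and recorded per trial. Catch trials always produce
  uniform reach directions.
* **Generalization (EXP4).** 45° rotation trained on a 140°-wide region
  with 2 or 8 targets (feedback on half the training trials), then probes
  at 10 equally spaced novel locations in the remaining 220°. Response
  caching transfers locally — probe re-aim falls off as a Gaussian of the
  circular distance to the nearest training target (width
  `sigma_transfer_deg`, default 30°) — while mental rotation transfers
  globally at a distance-independent gain (default 0.9).

Strategy parameters (per `StrategyParams`, population means): pace
2.5 ms/deg, preparation floor t0 = 150 ms (MR) / 225 ms (RC), sign-flip
probability 0.087, swap probability 0.05, lapse probability 0.05, motor
concentration κ = 10 (circular sd ≈ 18°), under-rotation gain 0.95,
solution 90°. Between-subject heterogeneity is mean-preserving lognormal
jitter on pace and t0 (cv 0.2), which is what lets cross-task pace
correlations exist at all. The flip rate is an empirically grounded
value; most of the others are plausible defaults exposed in the config
rather than measured quantities.

What the simulators deliberately do **not** emulate: implicit adaptation
dynamics, trial-to-trial learning noise beyond the fixed curves, curved
trajectories or biomechanics, RT-dependent accuracy trade-offs beyond the
strategy models, and catch-trial directional biases. Passing tests
therefore certify the *analysis* code against known generative truth, not
the realism of any particular human dataset.

## Circular statistics and preprocessing

Angles are degrees in (−180, 180] everywhere outside likelihood code;
positive always points toward the compensating solution after mirroring by
the counterbalanced rotation sign. The circular variance is 1 − R̄ (mean
resultant length); means with R̄ < 1e−9 are flagged undefined rather than
reported. The circular mode uses a 10°-bin histogram with ties broken
toward the circular mean, then toward the lower bin index. RT bins are
half-open 25 ms bins from 0 to 400 ms with a right-unbounded overflow bin
(17 bins total). Outlier exclusion is a single pass per subject: a trial
is dropped iff it lies more than 3 SDs from that subject's mean (the
candidate included in its own baseline); zero-variance and single-trial
subjects lose nothing, and angle-based exclusion is skipped for sign-error
analyses. A sign error is a reach at or below −15°; the predicted
response-caching "swap" anchor is `rotation − 180` (wrapped) and the
mental-rotation "flip" anchor is `−rotation`.

## Mixture model

The likelihood is evaluated with the exponentially scaled Bessel function
(`i0e`), so large κ cannot overflow. Optimization runs in radians via
SLSQP with an analytic gradient under the simplex constraint
w1 + w2 ≤ 1 and bounds w ∈ [0, 1], κ ∈ [0.1, 200] (the ceiling prevents
point-mass degeneracy), µ1 ∈ (0, π], µ2 ∈ [−π, 0]. Fifty random restarts
per fit are drawn uniformly inside the bounds (weights uniform on the
triangle) from a seeded generator; the winner is the lowest NLL with ties
broken by start index, making fits bit-reproducible. AIC uses k = 5
(Free-µ) and k = 3 (Fixed-µ). Bins with fewer than 20 pooled angles are
fit but flagged `low_n`. Bin-by-bin fitting defaults to starting at the
bin whose lower edge is 150 ms; the starting bin is an explicit argument
because the handoff between "critical bin" and "first analyzed bin" is a
genuine ambiguity in the design this implements — the boundary detector
(below) reports the first non-random bin, and the mixture default starts
at 150 ms regardless.

## Critical bin and pace estimation

`detect_critical_bin` scans adjacent RT-bin pairs in order and reports the
later bin of the first pair whose per-subject circular variance decreases
significantly (one-tailed paired t, α = 0.05, no multiplicity correction —
deliberately mirroring a single-comparison analysis). With no significant
decrease anywhere the result is flagged undefined.

The FREE pace is the per-subject OLS slope of execution-trial RT on the
absolute realized movement angle (rotated pairs only); the absolute angle
is used because sign flips preserve re-aim magnitude. An alternative
regression on the imposed rotation magnitude is provided as a cross-check.

The FORCED pace is the reciprocal of the per-subject OLS slope of aligned
angle on RT, over on-time trials from the critical bin's lower edge up to
**400 ms** (the top of the closed binning range) by default. The upper cut
is a deliberate design choice: the preparation ramp completes at
`t0 + pace · gain · solution` (≈ 364 ms at the default parameters), and a
line fitted across the post-ramp plateau — or across 1200 ms
asymptotic-window trials — measures a secant of the ramp rather than its
slope, inflating the pace estimate severalfold and even inverting its
correlation with the true pace across subjects (faster rotators saturate
more). Passing `rt_max_ms=None` restores the uncut regression. A
subject's pace is flagged undefined unless the slope exceeds a small
positive floor (10⁻³ deg/ms) *and* is reliably positive (p < 0.05):
without the significance gate, sampling noise around a flat (caching)
profile produces spuriously "defined" paces. The sigmoid alternative fits
a(t) = L/(1 + e^{−(t−t50)/τ}) by bounded multi-start least squares and
reads the pace as 4τ/L, the reciprocal of the maximal slope; the logistic
form and that readout are this package's operationalization of a
"sigmoidal alternative" and should not be over-interpreted.

Even with the 400 ms cut, the linear FORCED estimator retains an upward
bias of roughly 50–60% under the default generative conditions: sign
flips shrink the slope by (1 − 2·0.087), lapses by 0.95, pre-t0 uniform
trials further, and the per-subject 1/slope conversion is Jensen-inflated.
The acceptance test for cross-task pace recovery asserts the idealized
15% band regardless and is expected to fail on the FORCED clause; this is
an honest property of regressing a raw mixture distribution, recorded
here rather than patched over by re-tuning the generator.

## Inferential utilities

The JZS Bayes factor for a one-sample t uses the Cauchy(0, r) prior as a
normal scale mixture and evaluates the marginal by adaptive quadrature
(relative tolerance 10⁻¹⁰, hard error gate at 10⁻⁶); the prior scale is a
mandatory argument (r = 1 in the pipeline). For reference, BF01 at
t = 0.19, N = 32, r = 1 is 7.17; no t at r = 1, N = 32 can exceed 7.30,
so reported values near 7.8 in the literature imply a slightly wider
prior (r ≈ 1.09). Power/sample-size uses the noncentral t, with an exact
quadrature fallback where scipy's CDF loses accuracy at large
noncentrality. OLS, t-tests and correlations wrap statsmodels/scipy.

## Population-vector model

360 cosine-tuned units with uniform preferred directions, baseline 0 and
gain 1 (closure on the uniform grid makes all readouts count-invariant for
n ≥ 8, so these defaults only set the scale). A single plan at direction θ
yields a population vector at θ with length L0 = gain·n/2. Mental rotation
moves one plan continuously (length constant at L0); response substitution
cross-fades plans at 0 and Ω, with closed-form relative length
√((1−a)² + a² + 2a(1−a)cos Ω), minimized at a = ½ (≈ 0.707 for Ω = 90°).
Negative activities are retained by default — rectification would break
the closed forms — with a `rectify` flag for exploration. Since vector
length proxies movement speed, the two accounts separate cleanly: MR
predicts direction-independent speed, RS a dip at intermediate directions.

## Generalization analysis

Subjects must show reliable asymptotic learning (one-sample t against 0°
over the last 4 training cycles, p < 0.05) to enter the probe analysis.
The probe regression z-scores each regressor within subject — trial
number, circular distance to the nearest training target, RT, and the
interaction built as z(RT)·z(distance) then re-z-scored — and fits OLS per
subject; group inference is a one-sample t per beta per group and a
two-sample t between groups on the distance beta. Distances are circular
because probes span a 220° region. The Gaussian generalization fit
(offset + height·e^{−d²/2σ²}) is provided for completeness but flagged
unstable when the parameter covariance is near-singular or a bound is
active — flat (global) transfer profiles genuinely do not constrain it.

## Problem sizes and self-check limitations

The end-to-end suite simulates 20 cohorts of 32 MR subjects and 20 of 10
RC subjects for the model-selection dissociation, a 20-point recovery grid
(κ ∈ [2, 16] × w1 ∈ {0.3, 0.8} × µ1 ∈ {30°, 120°}, nuisance w2 = 0.1 and
µ2 = −90°, 5000 draws per fit), and 200 replicate generalization cohorts
at 15/17 retained subjects — sizes chosen to give stable pass/fail
behavior at interactive runtimes. Two checks sit at the edge of what the
estimators can deliver and are expected to be red: the low-concentration
corners of the recovery grid, where the MLE's sampling sd at n = 5000 is
comparable to the asserted ±0.05 / ±20% bands (the fits are at their true
optima; the errors are estimator variance, not optimizer failure), and
the FORCED clause of the pace-recovery check discussed above.
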