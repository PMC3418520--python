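# Methods

## The question the pipeline addresses

When a reaching movement is perturbed by a viscous curl field whose
amplitude grows trial by trial in a simple linear series (1, 2, 3,
4 Ns/m), does the motor system's next-trial expectation reflect the
*average* of the recent perturbations (2.5 Ns/m) or the *next* term of
the series (5 Ns/m)?  `reachadapt` implements the full in-silico
version of that experiment: it generates the three-phase protocol,
simulates synthetic subjects embodying each hypothesis, measures their
expressed forces on error-clamp probe trials, and runs the statistical
contrast that dissociates the hypotheses.  A companion module carries
the same averaging-vs-extrapolation question into object lifting,
with two two-parameter trial-by-trial grip-force models.

## Protocol model

A session is 780 trials: 100 null-field baseline trials, 200
random-perturbation trials, and 480 constant-perturbation trials.
Random-phase field amplitudes are drawn uniformly from
{1.0, 1.5, ..., 4.0} Ns/m; ten increasing sequences (1, 2, 3, 4 Ns/m,
each followed immediately by an error-clamp probe) are embedded at
random non-overlapping, non-adjacent positions.  The random phase
contains 20 clamps in total (10%): the 10 sequence-trailing probes
plus 10 placed uniformly among background positions, never adjacent to
a sequence block.  The constant phase is 12 blocks of 40 trials — six
amplitudes {1, 2, 2.5, 3, 4, 5} Ns/m, two blocks each, order drawn
once per seed (shared by all subjects, overridable in the config) —
with 5 randomly placed clamps per block (12.5%), never at a block's
first trial, giving 10 clamps per condition.  Clamp counts are
`round(fraction x phase length)` exactly; generation is deterministic
given `(config, seed)`; trial indices are 0-based everywhere.

## Reach and channel simulation

Each reach is a minimum-jerk point-to-point movement sampled at 200 Hz
(speed `v(t) = 30 D/T tau^2 (1-tau)^2`), with defaults D = 0.13 m,
T = 0.45 s chosen so peak speed is ~0.54 m/s, inside the observed
53-58 cm/s range.  Reach amplitude and arm dynamics are stand-ins —
no trajectory model is implied by the experimental setup itself — and
are fully configurable.  The sampled speed series is rescaled (an
O(dt^2) correction) so its trapezoidal integral equals the reach
distance to machine precision.

The lateral plant is a point mass (1 kg) with a linear arm impedance
(50 N/m, 10 Ns/m), a deliberately simple documented stand-in.  On
field trials it is driven by the compensation mismatch
`(B - B_hat) v(t)`, where `B_hat` is the learner's feedforward gain;
perfect compensation yields a straight reach, and movement error
(lateral displacement at peak speed) grows linearly with the mismatch.
On error-clamp trials the drive is the expressed force `B_hat v(t)`
against the arm impedance plus the standard channel spring-damper
(1000 N/m, 50 Ns/m); the recorded force is the force transmitted to
the channel wall, `k_ch x + c_ch x'`.  Integration is fixed-step RK4
at 1/200 s with sub-stepping for the stiff channel and an explicit
stability check that raises rather than integrating garbage.

Two consequences of this physical readout matter for interpretation:
the wall transmits `k_ch/(k_ch + k_arm)` ~ 98% of the expressed force
(so a perfect learner scores an adaptation coefficient of ~0.98, not
1.0), and clamp-trial movement errors are ~1 mm at typical gains, the
same order as real channel trials.  Motor noise is an optional
zero-mean Gaussian scaling of the expressed gain per trial (default
sd 5%).

Because the plant is linear and time-invariant and every drive is a
scalar multiple of the one speed profile, the session driver computes
one unit response per plant and scales it per trial; this is exactly
the superposition property, which the test suite verifies against
direct integration to 1e-8.

## Learners

Two hypothesis instantiations are shipped; neither is a claim about
how subjects actually compute.

* **Averager.**  Either a sliding-window (FIR) mean of the last
  k = 4 experienced amplitudes, or a single-rate update
  `B_hat <- A B_hat + eta (B_exp - B_hat)` (eta = 0.3 default).  After
  the 1-2-3-4 sequence the FIR-4 averager expects 2.5 Ns/m.
* **Extrapolator.**  Ordinary least squares on the last k
  (trial, amplitude) pairs, evaluated one step ahead: after 1-2-3-4 it
  expects 5 Ns/m.

Null-field trials count as experiencing amplitude 0; the FIR window is
pre-seeded with zeros by default (configurable), which lets the
baseline drag the early average down, mirroring the reported
under-prediction of the sequence mean.  Error-clamp trials present
essentially no error and leave the state frozen by default; an
optional retention multiplier < 1 decays the gain instead.

## Force analysis

All adaptation measures live on clamp trials, against the perfect
(full-compensatory) force `F_FC(t) = B v(t)`:

* adaptation coefficient `a`: regression through the origin of the
  exerted onto the perfect force, `a = <F, F_FC>/<F_FC, F_FC>`.  The
  model as written has no intercept, and the intercept-free reading is
  adopted (flagged as an interpretation); `a` is invariant to any
  residual orthogonal to `F_FC`.
* Pearson correlation `r` between exerted and perfect force.
* force at maximum speed (ties broken by earliest sample) — for
  velocity-proportional compensation it coincides with peak force,
  and both are reported so the robustness claim can be checked.
* movement error: lateral displacement at maximum speed.

Per-condition summaries average per-clamp coefficients over each
condition's 10 clamps (default); pooling all clamp profiles of a
condition into one regression is available behind a flag.  No baseline
force subtraction is applied.

## The average-vs-next contrast

Post-sequence probe forces are compared against the constant-phase
clamp forces of the 2.5 Ns/m ("average") and 5 Ns/m ("next")
conditions.  `avg_diff` and `next_diff` are benchmark minus
post-sequence means; the decisive test compares the per-observation
absolute deviations from each benchmark (two-tailed t).  Pooling is
observation-level by default (10 subjects x 10 clamps -> ~t(198) for
the independent test), with subject-level pooling behind a flag;
whether the original comparisons were paired is not derivable, so both
are provided (default independent, flagged).  A one-way ANOVA across
the 10 sequence repetitions (one group per repetition, one observation
per subject) probes implicit learning of the series; a stationary
learner satisfies the null, and the suite checks the p-value is > 0.05
in >= 90% of 100 seeded cohort replicates and that the null p-value
distribution is uniform (KS test).  No multiple-testing correction is
applied anywhere in the contrast.

Expected behaviour, verified in the tests: an averaging cohort sits on
the 2.5 benchmark (`|avg_diff|` small, `next_diff` ~ 2.5 Ns/m x peak
speed) and an extrapolating cohort reverses the ordering.  Two honest
deviations from the idealized values arise from the protocol itself:
benchmark clamps early in a block are measured before the learner's
window has converged, and the extrapolator overshoots at rising block
transitions — so the tests assert the ordering and ~15-20% tolerances
rather than exact asymptotes.

## Grip-force models

For a lifting series with object weights `W[n]` and grip forces
`GF[n]`, both models predict trial n from a 3-trial history:

* regression model: `w1 * mean(GF[n-3:n]) + w2 * extrap(GF[n-3:n])`,
  where `extrap` is the OLS line through the three previous grip
  forces evaluated at trial n (one-step extrapolation — the reading
  adopted for "regression of the previous grip forces");
* variance model: `w1 * mean(GF[n-3:n]) + w2 * std(W[n-3:n])`, sample
  (n-1) standard deviation by default, switchable.

`(w1, w2)` are fitted by OLS over all trials with a full history
(the first three are excluded), with no intercept (optional for
sensitivity analysis); collinear designs raise rather than returning
an arbitrary solution.  Fit quality is VAF
(`1 - var(resid)/var(obs)`) and Pearson r; with two parameters each
the models compare directly.  Weight units are arbitrary and absorbed
into `w2`.

The synthetic generator produces weight schedules (random over
{1..4} levels, repeated 1-2-3-4 ramps, or ramps embedded in a random
background) and grip forces from either model's own law (or a
model-free weight averager) plus Gaussian noise (default sd 0.05 N,
the condition used for parameter recovery: noiseless fits recover
(w1, w2) to 1e-10, and at n = 200 the mean recovered w1 over 500 seeds
is within 0.02 of truth).  Because the generator lacks human execution
variability, synthetic VAF (~0.97 at default noise) is well above the
~0.6 reported for real lifting data; the generator supports parameter
recovery and model comparison, not quantitative reproduction of human
fit quality.

## What the synthetic subjects do and do not show

Passing tests demonstrate that the protocol, measures and statistics
behave as designed and that the contrast machinery *can* dissociate
the two hypotheses when the data are generated by either one.  They
do not reproduce human effect sizes (e.g. absolute forces or the
0.12 N vs 0.69 N differences), which depend on unavailable subject
data; human values serve only as qualitative ordering references.
Known limitations: one-dimensional lateral plant (no two-joint
biomechanics, muscle dynamics or gravity), identical speed profiles
across trials, no savings/interference or two-rate dynamics, and no
visual-feedback modelling.

## Problem sizes and numerics

Default test-suite scales: cohorts of 10 subjects x 780 trials,
100-replicate ANOVA calibrations, 200-500-seed recovery studies —
each cohort simulates in ~0.2 s thanks to the unit-response scaling.
Tie-breaks (earliest sample at speed maxima), degenerate inputs
(zero-norm perfect force, zero-variance series, collinear designs,
all-identical ANOVA groups) and integrator stability all have defined,
tested behaviour.
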