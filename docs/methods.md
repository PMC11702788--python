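# Methods

This note documents the models, conventions, and numerical choices behind
`aspursuit`, in the order the pipeline runs.

## Scientific background

When the kinematics of a forthcoming moving target are predictable, humans
launch *anticipatory smooth pursuit* (aSP): the eyes start drifting in the
expected motion direction before the ~100 ms visual latency makes a
stimulus-driven response possible. The quantity of interest throughout this
package is **aSPv**, the anticipatory eye velocity reached at the end of
the anticipatory phase, trial by trial. The package asks three questions of
(synthetic) experiments: how aSPv scales with the *probability* of a
kinematic condition within a block, how it depends on the previous trial's
speed (N−1 history), and whether, for accelerating targets, it is driven by
the mean target speed over a finite *temporal window of integration* (TWI)
after motion onset.

## Synthetic experiment generator (`synth`)

Because no raw gaze data ship with the package, a generator produces the
study conditions every downstream stage assumes, at 1 kHz with known ground
truth.

**Designs.** Five presets mirror the block structures the analyses expect:

* `exp1a`: horizontal motion, constant speeds 5.5 / 16.5 °/s, 500 ms
  duration, seven blocks with P(high speed) ∈ {0, .1, .25, .5, .75, .9, 1}
  (500 trials per mixture block, 250 for the pure blocks);
* `exp1b`: oblique (45°) motion, constant speeds 11 / 33 °/s with durations
  1 s / 0.52 s (equated displacement), P(v33c) ∈ {0, .3, .7, 1}
  (100/200/200/100 trials);
* `exp2a` / `exp2b`: oblique accelerating v11a (+22 °/s²) vs decelerating
  v33d (−22 °/s²) mixtures, with equated displacement (0.87 / 0.72 s) or
  fixed 600 ms duration respectively;
* `exp3`: fully-crossed 3 × 3 (v0 ∈ {11, 22, 33} °/s × a ∈ {+22, 0, −22}
  °/s²), fully predictable 500 ms blocks, 100 trials each (120 for v33).

Each trial has a fixation epoch, a 300 ms gap, then target motion; `time 0`
is target motion onset everywhere.

**Latent aSPv.** In probability designs the per-trial latent value follows
the same hierarchical linear model the analysis fits:
`aSPv = β0 + b0_p + (β1 + b1_p)·P + γ·1[N−1 was the reference condition] + ε`,
with participant effects `b0, b1 ~ N(0, sd²)` and residual
`ε ~ N(0, trial_sd²)`. In fully-predictable kinematic designs the latent
mean is `β0 + b0_p + slope·TSE`, where TSE is the mean target speed over
the generative window `[0, twi_end]` (for constant speed, simply v0).
Defaults: β0 = 2.5 °/s and β1 = 5 °/s (aSPv rising from 2.5 to 7.5 °/s
across the probability range), γ = 0.5 °/s, participant sds 0.4,
trial sd 1 °/s, speed slope 0.2 per °/s, twi_end 0.2 s.

**Trace model.** The along-motion eye velocity is zero until the
anticipation onset `t_a` (−0.1 s, inside the gap), then a *normalized
convex exponential* `aSPv·(e^{ρ(t−t_a)} − 1)/(e^{ρ(t_lat−t_a)} − 1)` with
curvature ρ = 15 s⁻¹, reaching the latent aSPv exactly at the visual
latency `t_lat` (+0.1 s); from `t_lat` a normalized logistic (rate
40 s⁻¹, midpoint 70 ms past `t_lat`) carries velocity toward
`gain × target_velocity(t)`. Steady-state gain is 1.0 up to 11 °/s, 0.9 at
22 °/s, and 0.8 at 33 °/s, reflecting the sub-unity gain of fast pursuit.
Velocity is integrated (trapezoid) to position; white position noise
(sd 0.05° per raw sample) yields ~1 °/s velocity noise after the 30 Hz
filter, the scale assumed in the recovery analyses. Catch-up saccades are
30 ms raised-cosine velocity pulses (peak 80–200 °/s) at Poisson times
(rate 1.5 per trial) during pursuit. Anticipation-onset jitter is exposed
(`onset_jitter_sd`) but off by default; no published value constrains it.

**What the generator does not emulate:** blinks, pupil artifacts,
calibration drift, main-sequence saccade dynamics, direction errors of
anticipation, and any nonlinearity between probability and aSPv. Passing
recovery tests therefore demonstrate that the chain is consistent and
unbiased *under its own assumptions*, not that real data meet them.

## Preprocessing (`preprocess`)

Positions are low-pass filtered with a zero-phase (forward–backward)
second-order Butterworth at 30 Hz and differentiated by central differences
(one-sided at endpoints). Saccades are detected by the union of an absolute
2-D speed threshold (30 °/s) and a relative, median-based ellipse
criterion (λ = 5 robust spreads per axis). Because raw pursuit velocity is
legitimately far from zero, the relative criterion operates on the residual
after subtracting a 50 ms running-median smooth component; the robust
spread has a floor of 0.3 °/s so the threshold cannot collapse on clean
traces. Flagged runs ≥ 6 ms become intervals, intervals closer than 20 ms
merge, and each is padded ±5 ms — padding/merging values are declared
defaults, not published facts. Velocity inside intervals becomes NaN.

Trial exclusion uses strict ("more than") thresholds on missing-data
fractions, with denominators equal to the number of *expected* samples:
profile `exp1a` excludes > 40 % missing in the [−100, 200] ms onset
window, the other profiles > 70 % missing in [−100, 100] ms; all profiles
exclude > 60 % missing overall.

## Single-trial model fit (`trialfit`)

The desaccaded along-motion velocity inside the fit window (−300 to
+350 ms for `exp1a`, −300 to +300 ms otherwise) is fitted with a
continuous three-phase curve: flat baseline → normalized convex
exponential → normalized logistic toward an asymptote, sharing the
generator's parameterization so that **aSPv is the fitted curve's value at
the anticipation offset `t_lat`** (the exponential's maximum). Continuity
is enforced at both joins. Bounds: `t_a ∈ [−0.3, 0.12]` s,
`t_lat ∈ [t_a + 0.02, 0.2]` s, ρ ∈ [0.5, 60] s⁻¹, asymptote ∈
[0, 1.2 × max target speed] when the target speed is known. Estimation is
trust-region nonlinear least squares on non-missing samples, with an
8-point multi-start grid over (t_a, t_lat) (cheap exploration pass, tight
polish of the winner).

**Latency regularization.** The phase boundary `t_lat` is weakly
identified from one noisy trial: the likelihood has a flat ridge along
which `t_lat` slides into the sigmoid rise and aSPv reads high or low by
>1 °/s. A single pseudo-residual `(t_lat − 0.1)/0.015` pulls the boundary
toward the ~100 ms physiological pursuit latency (sd 15 ms, the order of
single-trial latency variability); it is excluded from RMSE/AIC/BIC and
can be disabled (`latency_prior=None`). Under the default noise level this
brings single-trial aSPv recovery to bias ≈ 0.03 °/s and RMSE ≈ 0.28 °/s.

Model adequacy is scored against a continuous piecewise *linear*
alternative (baseline / ramp / pursuit, 5 free parameters vs 8) via AIC,
BIC, and RMSE computed from a Gaussian likelihood with plug-in variance,
`n` = non-missing window samples. Manual inspection of fits is replaced by
an automated flag queue: non-convergence, |aSPv| > 15 °/s, or RMSE above
the session's 99th percentile.

## Hierarchical regressions (`stats`)

The first 10 trials of each block are dropped before probability analyses
(50 in the stricter control mode); the N−1 speed class comes from the
presented sequence, not from retention. Models are fitted by maximum
likelihood (not REML) so nested-model BIC comparisons are coherent:

1. probability: `aSPv ~ 1 + P`, random intercept + P slope per
   participant; for oblique experiments the axis (horizontal/vertical)
   enters as main effect and interaction, with each trial contributing one
   row per axis component;
2. history: `aSPv ~ 1 + P * TvN1` (low coded against the high-speed
   reference), random intercept + P + TvN1;
3. kinematics: `aSPv ~ 1 + v0 * accel` in raw units (°/s, °/s²), random
   intercept + v0 + accel, compared with the v0-only model through
   `BF = exp((BIC_reduced − BIC_full)/2)`;
4. categorical contrasts: `aSPv ~ 0 + C(condition)` marginal means, all 36
   pairwise differences z-tested and Benjamini–Hochberg adjusted.

Instead of an automatic maximal-model search, non-convergence walks a
deterministic **fallback ladder**: correlated random intercept + slopes →
uncorrelated variance components → random intercept only → OLS with
participant-clustered errors. The ladder never changes the fixed-effect
design matrix, and the selected rung is recorded in every summary. Two
statsmodels-specific choices: optimizers are tried bfgs-first because
lbfgs can report convergence with a collapsed variance (infinite
log-likelihood), and the categorical contrast model uses the
random-intercept rung directly — a random slope over nine categorical
levels (45 covariance parameters) is not estimable at the problem sizes
this package targets. Significance language in reports uses α = 0.01.

For mixtures of accelerating targets the N−1 class follows the
initial-speed convention (v33d = "high", v11a = "low"), and aSPv entering
the kinematic analyses is the along-motion resultant (per-axis components
remain available).

## Temporal window of integration (`twi`)

For constant-speed conditions, trial-level aSPv is regressed on target
speed by OLS, pooling participants (`aSPv = slope·Tk + intercept`). For
each accelerating condition the regression is inverted to a target speed
estimate `TSE = (aSPv − intercept)/slope`, and equating TSE with the mean
of `v0 + a·t` over `[0, T]` (closed form `v0 + aT/2`, verified against
quadrature) gives `TWI_end = (2/a)(TSE − v0)`. Negative or
longer-than-motion values are retained in distributions and only flagged —
they are evidence about the model, not errors.

Uncertainty comes from a bootstrap (default n = 1000) that resamples
*trials with replacement within each condition*, refits the regression,
recomputes condition means, and re-inverts; the 95 % CI is the 2.5/97.5
percentile interval. Trial-level resampling matches the pooled-regression
logic; a participant-level (cluster) mode is provided
(`unit="participant"`). Replicates with non-positive slope are recorded as
missing, with a warning above 10 %.

## Reproducibility and problem sizes

A single master seed drives everything: per-stage seeds are derived
through `numpy.random.SeedSequence` spawning, recorded in the run
manifest, and identical configs reproduce byte-identical tables. All
intermediates are flat text (TSV/JSON).

Default verification sizes are deliberately reduced: single-trial recovery
uses 200 trials; slope-recovery coverage uses 20 replicates of 10
participants × ~500 trials (with the matched generative model, i.e. no
history effect, since otherwise the marginal probability slope is β1 + γ);
TWI coverage uses 200 replicates of a half-size 3 × 3 experiment with 300
bootstrap resamples; the end-to-end pipeline demo runs 2–3 participants at
3–20 % of the full trial counts. These sizes give stable pass/fail
behavior for the properties tested while keeping a full run in minutes.

## Known limitations

* The exponential/sigmoid functional forms and the free-vs-fixed status of
  `t_a`/`t_lat` are declared conventions; other toolboxes may differ, and
  aSPv values are comparable across pipelines only up to such conventions.
* The latency prior trades a small bias for a large variance reduction; on
  traces whose true pursuit latency is far from 100 ms it will shrink
  `t_lat` toward the prior unless the data clearly resist.
* The absolute 30 °/s saccade criterion intersects legitimate pursuit
  velocity for the fastest (33 °/s) targets; such trials lose more samples
  and are excluded more often — a property of the criterion, not a bug.
* Wald CIs from the mixed models can undercover slightly with few
  participants; the bootstrap TWI CIs are percentile-based and make no
  normality assumption.
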