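# Methods

This note documents the models, algorithms and numerical choices behind
`flowparse`. It is the package's own account of its science; every
quantitative claim below is one the test suite or `scripts/acceptance.py`
recomputes.

## The paradigm being modelled

An observer in a virtual environment watches a ball travel laterally at
4, 5 or 6 m/s, 8 m away, visible for 0.5 s. In the **prediction task** the
ball then disappears and the observer presses a button when it would have
reached a target placed `occlusion duration x ball speed` metres past the
disappearance point (occlusions 0.5/0.6/0.7 s in the full factorial design,
plus 0.1–0.4 and 0.8–1.0 s with a static observer only). In the **speed
estimation task** the observer compares the ball's speed against a ball
cloud in a second interval (2IFC) whose speed follows an adaptive
staircase. In both tasks the observer may simultaneously experience
visually simulated lateral self-motion in the ball's direction ("same"),
against it ("opposite"), or none ("static").

### Self-motion profile

Self-motion ramps on over 50 ms, holds 4 m/s for 400 ms, and ramps off
over 50 ms. The ramp is a Gaussian-CDF-shaped speed profile, renormalised
over ±3σ so it reaches exactly 0 and 4 m/s at the ramp edges. Because the
renormalised shape is point-symmetric about the ramp midpoint, each ramp
averages exactly half the plateau speed, which pins the total displacement
to 4·(0.4 + 0.05) = 1.8 m and the time-averaged speed to 3.6 m/s. A linear
ramp (same symmetry, same displacement) is available for sensitivity
checks. Displacements integrate the piecewise speed with adaptive
quadrature; retinal traces use a uniform grid (default dt = 1 ms, central
differences for angular speed).

The package's retinal-speed table is derived from this clean geometry: the
ball's visible path spans ±(v·T/2) around the observer's initial
straight-ahead, the observer translates along the same axis, and
eccentricity is `arctan(lateral offset / 8 m)`. For a static observer and
a 4 m/s ball this gives a mean absolute retinal speed of
2·arctan(1/8)/0.5 s = 28.5 deg/s (and 52.8 / 2.8 deg/s for
opposite / same self-motion). Published tables derived from external
scripts for the same stimulus differ in absolute values; the ordering
(opposite > static > same) and the closed-form check above are the
contract here.

## Generative observer model

Incomplete flow parsing is modelled as additive misattribution of
self-motion to the ball. For a participant with bias fraction `a` and
precision effect `p` in a given profile:

    v_perceived ~ N(v_ball + a · v_self,  w_s · mean · (1 + p))
    d_perceived ~ N(d_occluded,           w_d · d_occluded)
    t_button    = d_perceived / v_perceived

with `v_self = 3.6 m/s` (the time-averaged self-motion speed — this
convention makes a bias of 0.2 shift a PSE by 0.72 m/s), speed Weber
fraction `w_s` and distance Weber fraction `w_d`. Percepts are resampled
until they exceed 0.1 m/s (speed) / 0.01 m (distance): the ratio model
would otherwise blow up on the (practically never-occurring) non-positive
draws, about which the perceptual model itself says nothing.

Population defaults (all configurable in `PopulationSpec`):

| parameter | mean | between-participant SD |
|---|---|---|
| bias, opposite direction | 0.20 | 0.30 |
| precision effect, opposite | 0.20 | 0.30 |
| bias / precision, same direction | 0 | 0 |
| speed Weber fraction `w_s` | 0.10 | 0.015 (truncated > 0.01) |
| distance Weber fraction `w_d` | 0.05 | 0 (common to all) |

Precision effects are truncated above −0.9. The static profile is always
unbiased; same-direction effects default to zero but the fitting machinery
estimates them freely. One percept sample per interval (no within-trial
integration) and no motor-noise term beyond the perceptual noise: the
model operates at the trial level.

In the 2IFC task the cloud interval carries no self-motion, so the cloud
percept is unbiased with the same Weber fraction; the response is
`cloud percept > ball percept` with a fair coin on exact ties. The
implied psychometric function of a bias-0.2 observer at 4 m/s crosses 50%
at 4.72 m/s.

What the generator does **not** emulate: motor/timing jitter in the button
press, lapses and attention failures (the 3× occlusion outlier rule fires
on essentially no synthetic trials), head rotation, learning or fatigue
across the session, and any Aubert–Fleischl-type dependence on gaze.
Passing tests therefore certify the pipeline's behaviour under the stated
perceptual model, not under every nuisance process in real data.

## PEST staircase

The comparison speed follows Parameter Estimation by Sequential Testing
with the classic Taylor–Creelman step heuristics (halve on reversal; keep
the second same-direction step; double the third and later ones, with the
standard delay-to-the-fourth exception after a run that ended in a
doubling), targeting the 50% point: "cloud faster" steps the cloud down.
Modifications matching the task design: the applied step is fixed at
1.2 m/s (twice the 0.6 m/s initial step) for the first ten trials; levels
are clipped to [reference/3, 3·reference]; a track ends after 37 trials or
once ≥ 30 trials are done and the adapted step is below 0.03 m/s. Two
tracks per condition start 30% above and below the reference, giving
2 × 3 speeds × 3 profiles = 18 tracks and 540–666 trials per participant.

Decisions where the classic recipe leaves room:

* Each response moves the track (no Wald run criterion); the rule set
  lives in one function (`pest._apply_rules`) so a different PEST variant
  can be substituted.
* During the ten fixed-step trials the adapted step is left untouched (it
  enters trial 11 still at 0.6 m/s); run direction is tracked throughout.
* The adapted step is capped at the early-phase step (1.2 m/s), the
  conventional maximum-step safeguard.
* Levels are continuous; no quantisation.
* "At the limits" in the staircase exclusion rule means exactly equal to a
  bound — levels are clipped, so bound contact is exact.

A vectorised lockstep runner (`run_staircases_batch`) advances whole
cohorts of tracks at once; a property test pins it trial-for-trial to the
scalar reference engine.

## Psychometric fitting

Choice probabilities are `Φ((x − PSE)/JND)`: a two-parameter
cumulative-Gaussian fit by direct Bernoulli likelihood maximisation, no
lapse or guess rate. The two tracks of a condition are pooled into one fit
per participant × speed × profile. The optimizer is bounded L-BFGS-B with
analytic gradients from four deterministic starts (mean ± SD of the
levels for the PSE; 0.5× and 1.5× the level SD for the JND); the JND is
constrained to [10⁻³, 3 × level range]. Complete separation drives the
JND to its lower bound and is reported as `converged=False` with a
diagnostic rather than an exception. A batched damped-Newton variant
solves the same MLE for hundreds of cells at once inside simulation loops;
tests pin it to the scalar fitter to 10⁻³.

## Confirmatory statistics

The six confirmatory analyses, with "static" as the reference level
throughout:

* **H1a** timing error ~ motion profile, random intercept and ball-speed
  slope per participant (trial level).
* **H1b** log condition-SD of the extrapolated time ~ condition mean +
  profile, same random effects; likelihood-ratio test of the profile term
  against the null without it, separately per direction.
* **H2a/H2b** the same pair on PSEs and log JNDs.
* **H3a** per-participant (opposite − static) mean-extrapolation
  difference regressed on the PSE difference (expected negative slope).
* **H3b** the SD difference regressed on the mean difference with/without
  the JND difference; these are ordinary linear models, so the nested
  comparison uses the exact partial F-test — a monotone transform of the
  likelihood ratio that keeps its nominal size at small cohorts, where the
  asymptotic chi-square rejects too often (the null-calibration suite
  checks this).

Exclusions, applied first: prediction trials with responses above 3× the
occlusion duration (strict inequality); staircases with more than 20% of
levels at a bound (per staircase); condition cells with SD ≤ 0.01 s for
all precision analyses (their logs would dominate the fit).

The mixed-model backend (statsmodels `MixedLM`) supports one grouping
factor, so the crossed occlusion-duration random intercept of the
trial-level models enters as a fixed factor instead; every result carries
a formula tag recording this. All LRT model pairs are fitted by full
maximum likelihood (not REML), df = difference in fixed-effect count; for
these pairs every optimizer is tried and the best log-likelihood wins, so
an under-converged null fit cannot inflate the statistic.
One-off confirmatory analyses can attach parametric-bootstrap percentile
CIs (simulate from the fitted model, refit; default 500 replicates, with
a warning if more than 10% of refits fail); simulation loops use the
asymptotic Wald p-values for fixed effects, which the null-calibration
test shows to be accurate at the design sizes used.

## Simulation-based parameter fitting

Per participant × task × direction, two steps: the precision parameter is
pinned at 0 while the accuracy parameter is fitted, then accuracy is fixed
and precision fitted. The objective is the median across simulated
datasets (50 for the prediction task, 25 for the speed task) of
`sqrt(median over condition cells of squared error)` between observed and
simulated difference summaries — mean-error/SD differences per
speed × occlusion for prediction, PSE/JND differences per speed for speed
estimation. Search: bounded scalar minimisation (SciPy's Brent-style
`minimize_scalar(method="bounded")`), accuracy over [−1, 1] (fractions of
the 3.6 m/s nominal self-motion speed), precision over (−0.9, 3],
tolerance 10⁻³ — below the Monte Carlo resolution of the objective.

Each optimisation pre-draws its noise once and reuses it across candidate
values (common random numbers): the objective becomes a deterministic,
near-smooth function of the parameter, which a bracketing search requires;
the estimand is unchanged. The simulators use the population-mean Weber
fractions, since a real participant's internal noise is not observable;
the accuracy objective is insensitive to this choice. In the noise-free
limit the simulator satisfies the scaling identities exactly: an accuracy
parameter `a` shifts the PSE by `a·3.6` m/s and the timing error by
`occ·(v/(v + a·3.6) − 1)`.

Cohort-level summaries: an intercept-only regression (one-sample t-test)
per task × direction × domain, and an OLS regression of prediction-task on
speed-task parameters per domain and direction — a shared underlying
effect predicts a slope near 1 because both parameters are scaled as
fractions of the same self-motion speed.

## Power analysis

Power and false-positive rates come from Monte Carlo simulation of the
full pipeline: draw a cohort, simulate both tasks, run the confirmatory
battery, record rejections at α = 0.05, aggregate with exact
Clopper–Pearson intervals. Failed simulations are logged and excluded,
with the count reported. The default is 250 simulations per design cell
with a documented desk-scale preset of 100; the false-positive runs use
200 simulations at a 20-participant / 5-repetition design (the null
calibration of a test statistic does not depend on the design size, and
the suite verifies all six tests sit inside the exact binomial band
there). The power criterion — every accuracy test ≥ 0.85 at 40
participants, 13 repetitions and ~70 trials per speed condition — is
checked at 100 simulations.

## Numerical and degenerate-input policy

* Deterministic seeds everywhere (`numpy.random.SeedSequence` spawning);
  end-to-end byte-identical CSVs under a fixed seed.
* Zero-variance responses short-circuit the precision LRTs to a null
  result instead of a backend failure; constant regressors and cohorts
  below five participants are refused with diagnostics.
* Mixed-model fits fall back through lbfgs/bfgs/cg optimizers; singular
  random-effect covariances are flagged on the result.
* All tolerances asserted in tests are stated there, next to the check.

## Known limitations

* No crossed random effects (see above); with three occlusion levels the
  fixed-factor substitute is close but not identical to the intended
  variance component.
* The two-step fit ignores accuracy-precision covariance within a
  participant; a joint 2-D fit is out of scope.
* The precision parameter of the speed task is weakly identified at
  staircase-length data (JND estimates from ~70 trials are noisy); its
  per-participant recovery error is correspondingly large.
* Real-data nuisance processes listed under the generator's non-goals are
  not modelled, so empirical effect sizes from human cohorts need not
  match the generative defaults.
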