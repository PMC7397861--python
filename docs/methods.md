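# Methods

This note documents the models, the synthetic-data generator, the
estimation machinery, and the numerical conventions used throughout
`actionprior`, together with the design choices that were genuinely open
and how they were resolved.

## Task model

All geometry is continuous pixels on a 0-based horizontal axis of a
1280-px screen. The ball starts at 128 px; the close and far targets sit
at 512 and 896 px, corresponding to nominal forces of 35% and 65% of the
participant's maximum voluntary force. A force response f (fraction of
maximum force) maps to an initial velocity

v = (0.5·f / 0.25) · 0.30 · screen_width  [px/s]

and the ball decelerates uniformly to a stop, so the final position is
start + v²/(2a). The deceleration a is calibrated **per effort level** so
that the nominal force lands exactly on the corresponding target centre.
A single shared deceleration cannot satisfy both anchor points: the two
target distances stand in ratio 2 while the squared nominal velocities
stand in ratio (0.65/0.35)² ≈ 3.45. Per-effort calibration honours the
"nominal force ↔ target centre" correspondence exactly and keeps the map
strictly monotone and invertible within each effort level; positions are
clipped to the screen.

Schedules contain 40 blocks of 27 trials (19 basic, 8 estimation), 10
blocks per effort × reward cell in a seeded shuffled order. Within a
block the trial-type order is drawn by rejection sampling under the two
constraints (first three trials basic; no two adjacent estimation
trials); infeasible configurations raise instead of looping. The force
response is the mean of the 60-Hz force trace over the half-open window
[2.0 s, 2.5 s) (30 samples). Maximum force is calibrated from three 10-s
presses: per trace, the mean of the minimum-variance 5-s window; the
maximum across traces. Reward is £1 at zero error, decreasing linearly to
£0 at 15% (close target) or 30% (far target) of the screen width, never
negative.

## Observer models

On an estimation trial the reported position estimate is modelled as the
precision-weighted combination of a Gaussian prior over the outcome and
Gaussian sensory evidence centred on the true final position, optionally
shifted by s:

* **M1** – prior centred on the target; free σ_prior, σ_evidence per
  participant × condition.
* **M2** – M1 plus the evidence shift s (free per participant ×
  condition; a config flag restricts it to one value per participant).
* **M3** – "observational" prior: mean and SD fixed at the participant's
  empirical basic-trial performance distribution in that condition; only
  σ_evidence is free. M3 deliberately has no free prior parameters — it
  asks whether estimates simply reflect what performance actually looked
  like.

**Trial-level likelihood.** The generative story is a single sensory
sample x_s ~ Normal(x_true + s, σ_evidence) passed through the combination
rule, so an observed estimate is Gaussian with mean
w·μ_prior + (1 − w)·(x_true + s) and SD **(1 − w)·σ_evidence**. This is
the default (`likelihood="sensory"`). The alternative reading — the
estimate as a draw from the Bayes posterior over positions, with SD
√(σ²_p σ²_e/(σ²_p + σ²_e)) — is implemented behind the same switch
(`likelihood="posterior"`); the two differ by a factor √w in the
predictive SD and the choice is isolated in one function
(`observer.predictive_moments`).

**Hierarchy.** Each free parameter follows a three-level Gaussian
hierarchy, on the log scale for the SDs: condition-level values ~
Normal(participant mean, κ); participant means ~ Normal(group mean μ, τ).
Hyperpriors are weakly informative in pixel units: group means of log SDs
~ Normal(log 50, 1.5) (a few px to several hundred px at ±2 SD), the
shift's group mean ~ Normal(0, 50); κ and τ get half-Normal(1) priors on
the log-SD scale and half-Normal(20 px) for the shift.

## Estimation

No probabilistic-programming stack is assumed: the posterior is sampled
by a purpose-built Gibbs sampler whose scans combine

1. exact conjugate Gaussian draws for every location parameter (the
   per-cell shift, participant means, group means);
2. vectorized univariate slice sampling (stepping-out + shrinkage) for
   the per-cell log SDs and all scale hyperparameters — all
   participant × condition cells are updated in one vectorized pass since
   their conditionals are independent;
3. a joint per-cell diagonal move of (log σ_prior, log σ_evidence),
   which travels the common-scale ridge (w held fixed) that
   coordinate-wise updates traverse slowly;
4. interleaved non-centred ("ancillarity–sufficiency") re-draws of each
   scale hyperparameter with the standardized effects held fixed,
   breaking the funnel coupling between scales and effects; and
5. whole-hierarchy and per-participant block translations, which move a
   hierarchy's cells and means rigidly against the likelihood — essential
   when κ is small and cells are almost pinned to their participant mean.

A **centred** parameterization is used throughout (rather than a
non-centred one): with ≥ 10 trials per cell the likelihood is informative
enough that centred conditionals are the well-identified ones, and
centring makes every location update exactly conjugate; the interleaved
moves (4–5) supply the mixing benefits non-centring would otherwise
provide.

Chains are independent with seeds spawned from the user seed. Default
desk-scale settings are 4 chains × 500 stored draws after 500 warm-up
scans, with 10 scans per stored draw (thinning decorrelates the stored
sample; the full-scale setting of 8 chains × 2,000/1,000 is available via
the same arguments). Convergence is summarized by the split-chain
potential scale reduction factor computed for every stored quantity;
values below 1.01 are treated as converged. Note that the *maximum* R̂
across several hundred parameters has a sampling floor of about 1.005
even for perfectly independent draws at this chain length.

Model comparison uses WAIC on the pointwise log-likelihood matrix
(log-sum-exp stabilized; penalty = per-point posterior variance with the
sample-variance convention, ddof = 1). Pairwise ΔWAIC standard errors are
sd(pointwise differences)·√n. Posterior predictive checks simulate
replicate estimates per posterior draw and report central-interval
coverage, pooled and per condition.

## Synthetic cohorts

The generator draws ground-truth observer parameters from the same
two-level hierarchy the models assume and simulates force production
through the task physics. Defaults describe the study conditions the
package targets:

* log σ_prior ~ Normal(log 45, 0.4) between participants, σ_evidence
  ~ Normal(log 70, 0.4), condition-level jitter 0.15 — giving a
  group-mean prior weight w ≈ 0.7 and participant weights spanning
  roughly 0.35–0.9;
* evidence shift ~ Normal(−15, 8) px between participants (a leftward
  bias, condition jitter 4 px);
* force bias −1% (low effort) and −4% (high effort) of maximum force
  (undershoot grows with effort), force SD 5% and 8% (variability grows
  with effort), with reward improving both slightly; these map through
  the force→position slope (~22–24 px per % max force) to performance
  SDs of roughly 110–190 px, so prior SDs are well below performance SDs
  for most participants;
* AMI subscales on the 0–4 item scale (means 1.2–1.5, SD 0.7), with the
  behavioral-activation score constructed so that its partial correlation
  with participant-mean prior SD given performance variability targets
  ρ = 0.37 by construction (residualize, mix with orthogonalized noise,
  rescale; clipping to [0, 4] attenuates the realized correlation only
  marginally).

What the generator does **not** emulate: learning or adaptation across
trials, fatigue, response/pointing noise beyond the single sensory
sample, item-level AMI responses, or heavy-tailed force errors. Passing
recovery tests on these cohorts therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to the
mis-specification real data would add.

## Preprocessing conventions

Scaled MAD uses the 1.4826 Gaussian-consistency constant. Participant
exclusion applies the ≥ 3 scaled-MAD rule to each participant's **mean
absolute force error** across all trials (the natural reading of "average
task performance"; the signed mean would let large symmetric errors
cancel). Cell-level trial filtering removes force errors more than 3
scaled MADs from the participant × condition median; a degenerate
zero-MAD cell disables that cell's filter rather than deleting every
off-median trial. IQRs use linear-interpolation (type-7) quantiles.
First-trial removal drops within-block trial 1 only.

## Weighting regression and conditional AIC

The estimation-error ~ performance-error relation is fitted with Gaussian
linear mixed models by maximum likelihood (not REML, so information
criteria are comparable across random-effect structures with identical
fixed effects). The candidate family has exactly ten members: random
intercept + slope by participant (baseline), plus within-participant
adjustments of the intercept, the slope, or both, by effort, reward, or
both — condition adjustments are nested within participant as
variance-component terms. Conditional AIC is −2 × conditional
log-likelihood + 2 × effective degrees of freedom, with the effective dof
taken as the trace of the mixed-model hat matrix from Henderson's
equations plus one for the residual variance; when the random-effect
covariance collapses to zero this reduces to the ordinary AIC of the
fixed model. Several bias-corrected conditional-AIC variants exist; the
hat-trace form is used because it is exact in the known-variance case,
cheap, and testable against an explicit linear-algebra oracle.
Non-converging candidates are dropped from the selection with a warning.
Data with exactly zero residual variance (the degenerate endpoints slope
= −1 and slope = 0) are detected and returned as exact least-squares
fits, flagged singular.

## Association statistics

Partial correlations use the correlation-matrix formula with df = n − 3
and the t transform for p-values (identical to the residual-regression
route, which serves as a cross-check). Holm–Bonferroni is applied over
the four-scale AMI family. The correlation Bayes factor is Jeffreys's
default test: the marginal likelihood of the observed r under a uniform
stretched-beta prior on ρ divided by its likelihood under ρ = 0,
computed by one-dimensional integration of the exact sampling density of
r; for partial correlations the effective sample size is n minus the
number of covariates. (The alternative g-prior integrand of Wetzels &
Wagenmakers yields systematically smaller values and does not reproduce
standard reference outputs; the Jeffreys default matches the analytic
closed form in pingouin/JASP to four decimals.) Power analysis for a
two-sided Pearson test integrates the same exact r density over the
rejection region and returns the smallest n reaching the target power;
the Fisher-z approximation (which returns 47 where the exact method
returns 46 at ρ = 0.4, α = .05, power .80) is exposed as an alternative.

## Problem sizes

Desk-scale defaults keep every stage runnable on a single CPU in
minutes: cohorts of 8–30 participants, shortened sessions of 8–16 blocks
of 15 trials (10 basic + 5 estimation), sampler settings of 2–4 chains ×
150–500 stored draws, and 12 replicates for the WAIC model-recovery
check. These sizes are the package's test conditions; the full-scale
study design (47 participants × 1,080 trials, 8 chains × 2,000 draws) is
reachable through the same configuration surface.

## Known limitations

* The likelihood SD convention ((1 − w)·σ_evidence) is one defensible
  reading of the generative story; fits under the posterior-SD
  alternative are supported but not routinely tested.
* The evidence shift is free per condition by default; if the underlying
  process is a single perceptual bias, the per-participant restriction
  (`shared_shift=True`) is the better-specified model.
* The exclusion statistic ("mean absolute force error") and the
  condition-level grain of the observational prior are documented
  conventions, not uniquely determined by the task description.
* Recovery of the shift parameter is noticeably weaker than that of the
  SDs at desk scale (cell-level shift posteriors shrink strongly toward
  the participant mean); participant-level shift recovery is the
  meaningful target.
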