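# actionprior

Precision-weighted Bayesian observer modelling of how people perceive
their own action outcomes, with a visuomotor-task simulator, hierarchical
MCMC estimation, and trait-association statistics.

## The problem

In a ballistic aiming task, a participant presses a force sensor to launch
a ball at a target; on a minority of trials the trajectory is hidden and
the participant reports where they believe the ball stopped. Reported
estimates are systematically biased toward the target, consistent with the
percept being a precision-weighted combination of a prior belief about the
outcome ("I hit the target") and noisy sensory evidence about the true
final position:

```
x_estimate = w·μ_prior + (1 − w)·μ_evidence,
w = σ²_evidence / (σ²_evidence + σ²_prior),
μ_evidence = x_true + s
```

where σ_prior and σ_evidence are the standard deviations of the prior and
the sensory evidence, and s is a directional shift of the evidence mean
(e.g. from the ball's rightward motion). The same identity can be read as
a regression: estimation error = −w · performance error + (1 − w)·s, so
the slope of estimation error on performance error identifies the prior
weight w (−1 = full reliance on the prior, 0 = prior disregarded).

The scientific question this pipeline supports is whether the *precision*
(1/σ²_prior) of those priors varies meaningfully across people — in
particular, whether trait apathy (Apathy Motivation Index, AMI) is
associated with less precise priors about action outcomes, after adjusting
for each person's actual performance variability.

This package is aimed at computational-psychiatry researchers who want a
tested, reusable implementation of the full analysis chain, exercised
end-to-end on synthetic cohorts with known ground truth, so that every
estimator can be validated by parameter recovery before being pointed at
real data.

## What's inside

| module | contents |
| --- | --- |
| `actionprior.task` | task geometry and physics (force → final position), trial scheduling with its constraints, maximum-force calibration, reward rule |
| `actionprior.cohort` | synthetic cohorts: known observer parameters per participant × condition, simulated trials, AMI scores with a controllable partial correlation to prior width |
| `actionprior.preprocess` | participant exclusion and trial filtering by scaled-MAD rules, performance summaries |
| `actionprior.behavior` | 2×2 repeated-measures ANOVA with generalized eta-squared, repeated-measures ANCOVA with a continuous covariate |
| `actionprior.weighting` | estimation-error ~ performance-error linear mixed models (10 random-effect structures), conditional-AIC selection |
| `actionprior.observer` | the three hierarchical Bayesian observer models (target prior / target prior + evidence shift / observational prior), Gibbs-sampler estimation, split-R̂ diagnostics, WAIC comparison, posterior predictive checks, parameter recovery scoring |
| `actionprior.association` | partial correlations, Holm–Bonferroni correction, default-prior correlation Bayes factors, exact power analysis for correlations |
| `actionprior.pipeline` / `actionprior.cli` | end-to-end orchestration with a config file, seeded reproducibility and a machine-readable report |

## Worked example

Run the whole pipeline on a simulated cohort (12 participants, a shortened
session of 12 blocks, reduced sampler settings):

```python
from actionprior.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, outdir="demo", n_participants=12,
                chains=2, samples=250, warmup=250,
                task=dict(n_blocks=12, trials_per_block=15,
                          basic_per_block=10, estimation_per_block=5,
                          blocks_per_condition=3))
run_pipeline(cfg)
print(open("demo/report.txt").read())
```

which prints:

```
actionprior pipeline report (config d2c2ff27ed3f, seed 7)
simulated trials: 2160
preprocessing: 144 first trials removed, 23 outlier trials removed, 0 participants excluded
weighting LMM: best spec int:both|slope:both, group slope -0.615
best observer model by WAIC: m2
posterior predictive 95% coverage: 0.955
parameter recovery: corr(true, fitted prior SD) = 0.942 (pass at 0.7)
  ami_total: partial r = 0.342, p = 0.3032, Holm p = 1.0000, BF10 = 0.60
  ami_behavioral_activation: partial r = 0.263, p = 0.4344, Holm p = 1.0000, BF10 = 0.49
  ami_emotional_sensitivity: partial r = -0.035, p = 0.9177, Holm p = 1.0000, BF10 = 0.37
  ami_social_motivation: partial r = 0.374, p = 0.2575, Holm p = 1.0000, BF10 = 0.66
```

Reading the report: each simulated participant's estimates were generated
from the shifted-evidence observer, and the analysis recovers that
structure — the mixed-model slope of −0.615 estimates the group-mean prior
weight w ≈ 0.62 (the generative mean is ~0.7, shrunk slightly by
between-participant spread); WAIC correctly selects the shifted-evidence
variant (`m2`) over the unshifted and observational-prior alternatives;
the fitted prior SDs correlate 0.94 with the generating values; and the
95% posterior predictive interval covers 95.5% of the held-in estimates.
The AMI partial correlations carry the planted positive link with
behavioral activation, but a cohort of 12 is (correctly) far below the
n = 46 the power analysis demands, so none is significant.

The same run is available from the shell:

```bash
actionprior run --seed 7 --out demo --config cfg.yaml
```

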