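# psplasmode

Plasmode simulation benchmark of propensity-score estimation methods for
1:1 caliper matching in observational studies of a binary exposure and a
binary outcome, with a TMLE comparator.

## The problem

When treatment is not randomized, the propensity score
e(W) = P(A = 1 | W) is the workhorse for confounder adjustment, and 1:1
nearest-neighbour caliper matching on it is one of the most common study
designs in pharmacoepidemiology. The propensity score itself, however, can
be estimated many ways: plain logistic regression, multivariate adaptive
regression splines (MARS), a supervised feed-forward classifier, or an
autoencoder whose low-dimensional bottleneck feeds a downstream logistic
model. Whether the extra flexibility of the machine-learning estimators
helps or hurts the *downstream treatment-effect estimate* is an empirical
question, and answering it fairly requires simulated data whose covariate
structure is as messy as a real ICU cohort.

`psplasmode` answers it with a **plasmode simulation**: covariate/exposure
rows are resampled *unmodified* from a base cohort (a synthetic stand-in
for the Right Heart Catheterization / SUPPORT cohort: 5,735 subjects, 50
mixed-type correlated covariates), and only the outcome is simulated from
a known logistic model

    logit P(Y=1 | A, W) = b0 + bA·A + f(W)

where f(W) contains main effects of all covariates plus deliberately
awkward terms: age polynomials up to degree 3, a PaO2/FiO2 polynomial up
to degree 2, a heart-rate × mean-BP interaction, a GCS × hematocrit ×
sodium triple interaction, exp(weight) and cos(APACHE). The treatment
coefficient bA is set to log(true OR) and the intercept b0 is calibrated
so the simulated outcome prevalence hits its target. Every propensity
model sees *main effects only* — flexibility has to be earned from data.

Each replicate then runs the full analysis pipeline:

1. estimate the propensity score (PS, MARS, DL, DL.n, AE, AE.o);
2. match 1:1 without replacement, caliper = 0.2 × SD of the logit PS;
3. check balance via standardized mean differences (|SMD| > 0.25 flags
   imbalance);
4. fit a *doubly adjusted* logistic outcome model (treatment + all
   covariate main effects) on the matched rows.

Replicate estimates are aggregated into bias, empirical SE, MSE, average
model SE, 95% coverage and bias-eliminated coverage, each with its Monte
Carlo SE, plus zip-plot data. A TMLE estimator (super learner outcome
model: logistic regression + MARS, 5-fold CV; influence-curve variance)
uses the same propensity scores as a matching-free comparator.

## Scenario grid

| scenario | exposure | outcome | true OR | n |
|---|---|---|---|---|
| i (base) | 30% | 30% | 0.7 | 3,500 |
| ii rare exposure | 5% | 30% | 0.7 | 3,500 |
| iii rare outcome | 30% | 5% | 0.7 | 3,500 |
| iv large sample | 30% | 30% | 0.7 | 5,000 |
| v null effect | 30% | 30% | 1.0 | 3,500 |

## Worked example

```python
import numpy as np
from psplasmode import (
    RunConfig, ScenarioConfig, build_dgm, generate_cohort,
    preprocess, run_scenario,
)

base = preprocess(generate_cohort(5735, seed=11))          # synthetic RHC-like cohort
sc = ScenarioConfig("i", 0.30, 0.30, 0.7, 3500, n_sims=200, base_seed=201)
spec = build_dgm(base, sc)                                  # refit + calibrate the true model
perf, results = run_scenario(RunConfig(methods=("PS",)), sc, base=base, spec=spec)
row = perf[0]
print(f"bias {row.bias:+.4f} ({row.bias_mcse:.4f})  empSE {row.emp_se:.4f}  "
      f"modSE {row.mod_se:.4f}  coverage {row.coverage:.3f}  "
      f"mean OR {np.exp(row.bias + sc.true_log_or):.4f}")
```

prints (one CPU, ~30 s):

```
bias +0.0074 (0.0077)  empSE 0.1094  modSE 0.1057  coverage 0.930  mean OR 0.7052
```

i.e. over 200 plasmode replicates of the base scenario, the matched,
doubly adjusted logistic-PS estimator recovers the injected odds ratio of
0.7 essentially without bias (the bias is well within its Monte Carlo
noise), its model-based SE agrees with the empirical SE, and the 95%
interval covers at the nominal rate.

There is also a CLI: `psplasmode simulate`, `psplasmode analyze
--cohort data.csv --exposure swang1 --outcome death`, and
`psplasmode report results/performance.csv`.

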