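# Methods

## Plasmode design

The package evaluates propensity-score (PS) estimation methods by their
downstream treatment-effect estimates, not by prediction accuracy. A
plasmode simulation keeps the empirical joint distribution of covariates
and exposure — replicates are drawn by resampling rows of a base cohort
with replacement — and simulates only the outcome from a fixed, known
logistic model. This preserves realistic covariate correlation and
exposure confounding while giving the simulation a known estimand.

**True outcome model.** The data-generating model contains main effects
of all covariates plus: age polynomials to degree 3, a PaO2/FiO2
polynomial to degree 2, heart rate × mean blood pressure, a GCS ×
hematocrit × sodium triple interaction, exp(weight) and cos(APACHE), all
on standardized covariates (so "raw powers" are powers of z-scores and
the exp/cos arguments are O(1)). Its coefficients are obtained by
refitting this specification on the base cohort by maximum likelihood;
the treatment coefficient is then overwritten with log(true OR) and the
intercept recalibrated. The injected conditional log-OR is therefore the
exact truth for bias and coverage.

**Prevalence control.** Replicates of size n are resampled stratified by
exposure with an exact treated count of round(n × exposure prevalence);
the treated fraction is deterministic, not merely expected. The outcome
intercept is calibrated once, on the base cohort, by monotone
root-finding (Brent, |gap| < 1e-8) — but the calibration mean weights the
base rows by the scenario's resampling design (total treated weight =
scenario exposure prevalence). Without that weighting the replicate-level
outcome prevalence would be pulled away from its target whenever the base
cohort's own exposure prevalence (~0.39 under the default generator)
differs from the scenario's, because the treatment effect applies to a
different fraction of subjects. Per-replicate seeds are base_seed +
replicate index; the outcome draw uses a separate stream from the
resampling draw so the two are independent given the seed.

## Synthetic base cohort

The generator emulates an ICU cohort of 5,735 subjects and 50 covariates:
22 continuous (including the nine the outcome model treats specially), 22
binary, and 6 three-level categoricals. Continuous covariates come from
an exchangeable-correlation Gaussian block (ρ = 0.2 by default, a
moderate clinical-covariate correlation) mapped onto plausible clinical
units; binaries and categoricals are generated through logistic and
multinomial-logit links on the continuous block, which induces
cross-type correlation. Exposure follows a logistic model on 12
covariates (5 of them special-term variables) with slopes ±0.2 ×
confounding strength and a root-found intercept hitting the target
prevalence (default 0.38, near the RHC treated fraction). A baseline
outcome (30% prevalence) with modest main effects and mild versions of
the special non-linearities is included so the true-model refit has
genuine signal in every term.

What the generator does *not* emulate: the real SUPPORT missingness and
measurement pathologies, heavy-tailed labs, the exact 50-covariate coding,
and the empirical dependence between exposure and the full covariate set.
Passing tests therefore demonstrate correctness of the machinery and
calibration under a realistic-but-clean covariate structure; they do not
certify behaviour on the real RHC data, which can be supplied as a CSV
through `load_cohort`.

## Estimators

All six PS methods consume the same main-effects design matrix
(standardized continuous columns, 0/1 binaries, reference-coded
categorical indicators) and return probabilities clipped to
[1e-6, 1 − 1e-6] so logits stay finite.

- **PS** — maximum-likelihood logistic regression.
- **MARS** — least-squares MARS: reflected hinge pairs added greedily
  (knots at deciles of the active rows, interactions to degree 2, no
  variable repeated in a term), then backward deletion scored by GCV with
  effective parameters m + penalty(m−1)/2, penalty 3 (2 when additive).
  No cross-validation. Raw predictions may leave (0,1); they are
  truncated and the count reported. Defaults: 15 max terms, 5 candidate
  knots — enough for the low-signal exposure surfaces here while keeping
  a per-fit cost of ~1-2 s at n = 3,500.
- **DL / DL.n** — feed-forward classifier, hidden layers (64, 32, 16),
  ReLU, sigmoid output, binary cross-entropy, Adam 1e-3, batch 64, 50
  epochs. DL uses dropout 0.3, L2 0.01, batch normalization and He-normal
  initialization; DL.n disables all four (Glorot-uniform init).
- **AE / AE.o** — autoencoder with encoder (32, 16), bottleneck 10,
  symmetric decoder, MSE loss, 100 epochs; the PS is a logistic
  regression of exposure on the (standardized) bottleneck activations.
  AE.o adds the same four design features as DL. The bottleneck→logistic
  construction is one of several possible readouts of an autoencoder PS;
  it is the standard choice when the autoencoder is used as a
  dimension-reduction front end.

The network engine is a small deterministic numpy implementation (one
seeded generator drives initialization, shuffling and dropout), so every
estimator is bit-reproducible for a given seed and machine. There is no
early stopping; epochs are fixed for determinism. Batch-norm inference
uses running statistics with momentum 0.9.

Convergence screens: iteration caps plus a |coefficient| < 15 bound on
standardized inputs (a cheap separation detector); screened-out
replicates are excluded from performance aggregation and counted.

## Matching and effect estimation

Caliper = 0.2 × SD(logit PS) with the n−1 denominator, computed on the
full pre-matching sample. Greedy nearest-neighbour matching without
replacement processes treated units in data order on the logit scale;
ties break to the lower control index. (The processing order of the
original analyses is unknown; a fixed deterministic rule is required for
reproducibility.) Unmatched treated units are dropped. SMDs use the
pooled SD sqrt((s_t² + s_c²)/2) from the pre-matching sample for both the
before and after columns, so the two are comparable; |SMD| > 0.25 flags
imbalance.

The treatment effect is the conditional log-OR from a logistic regression
of outcome on treatment plus all covariate main effects, fitted on
matched rows, with the model-based (information-matrix) SE and a 95% Wald
interval. No pair-clustered variance is used — the benchmark evaluates
the plain model SE, and the empirical-vs-model-SE comparison is itself
one of the performance measures. Metrics are computed on the log-OR
scale.

## TMLE

The TMLE comparator targets the marginal odds ratio
logit(ψ1) − logit(ψ0), ψa = E[Q*(a, W)]. The initial Q is a super
learner over logistic regression and MARS with 5-fold CV; weights solve
a non-negative least-squares problem on the CV predictions, normalized
to the simplex (a learner failing a fold gets weight 0). Targeting uses
two clever covariates H1 = A/g, H0 = −(1−A)/(1−g) in a no-intercept
logistic fluctuation with offset logit Q. The SE comes from the
efficient influence curves of (ψ1, ψ0) and the delta method. Propensity
scores are bounded to [0.001, 0.999] inside TMLE only (positivity
guard); Q is bounded to [1e-4, 1 − 1e-4] before the logit offset. In the
scenario runner TMLE sits behind a flag; it is primarily a
single-dataset comparator.

## Performance measures

bias, empirical SE (n−1 SD), MSE, average model SE (the arithmetic mean
of reported SEs; a root-mean-square-of-variances alternative sits behind
`mod_se_rms=True`), 95% coverage and bias-eliminated coverage, each with
the standard simulation-study Monte Carlo SE. With these conventions
mse = bias² + empSE²(n−1)/n holds exactly and is asserted to 1e-12.
Non-converged or empty-match replicates are excluded listwise per method
and counted. Zip-plot data ranks replicates by the fractional centile of
|z| = |(estimate − truth)/SE|.

## Problem sizes and numerical choices

The shipped study conditions are the scenario grid above with a
base cohort of n = 5,735. The test suite and the acceptance script run
the base and null scenarios at 200 replicates and the four-method
qualitative comparison at 100 replicates with reduced network epochs
(DL 15, AE 20) — sizes chosen so a full run completes on a single CPU in
minutes; the full 1,000-iteration grid is available through
`ScenarioConfig.n_sims` and the CLI. Root-finding tolerances are 1e-10
(intercepts); GLM fits cap at 100 iterations; zero-variance continuous
columns are rejected at preprocessing; constant propensity scores yield
a zero caliper with a warning; degenerate (single-arm) inputs raise.

## Known limitations

- The strong autoencoder under-coverage reported on the real RHC-based
  study does not reproduce on this synthetic cohort with the declared
  default architectures: at 100 replicates all four headline methods
  show comparable bias, SEs and coverage. The package reports the
  empirical-vs-model-SE pattern rather than asserting it; reproducing
  the original pattern likely requires the real covariate structure and
  the original (unpublished) network configurations.
- MARS forward selection uses decile knots and a term cap rather than an
  exhaustive knot search; this is the usual speed/fidelity trade-off.
- The doubly adjusted SE ignores matched-pair correlation by design (see
  above).
- The synthetic generator's exposure model is logistic-linear, so the
  "true" PS is learnable by plain logistic regression; machine-learning
  estimators can only lose efficiency here, which is the conservative
  setting for comparing them.
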