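"""Plasmode simulation machinery.

Plasmode simulation resamples observed covariate/exposure rows without
modification and simulates only the outcome from a known ("true") model,
so that the covariate structure stays realistic while the treatment effect
is controlled.  The true outcome model here is a logistic regression with
main effects of all covariates plus special terms: age polynomial up to
degree 3, PaO2/FiO2 polynomial up to degree 2, a heart-rate x mean-BP
interaction, a GCS x hematocrit x sodium triple interaction, exp(weight)
and cos(APACHE).  Its coefficients are refit on the base cohort, the
treatment coefficient is then overwritten with the target log odds ratio,
and the intercept is calibrated to the target outcome prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .calibration import solve_logit_intercept
from .cohort import CohortTable

# ---------------------------------------------------------------------------
# term descriptors


@dataclass(frozen=True)
class Term:
    """One column of the expanded true-model design.

    kind: main | polynomial | interaction | transform
    """

    kind: str
    variables: tuple[str, ...]
    degree: int = 1
    fn: str | None = None  # exp | cos, transform only

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.variables[0]
        if self.kind == "polynomial":
            return f"{self.variables[0]}^{self.degree}"
        if self.kind == "interaction":
            return ":".join(self.variables)
        return f"{self.fn}({self.variables[0]})"


def default_terms(cohort: CohortTable) -> tuple[Term, ...]:
    """Main effects of every covariate column plus the special terms."""
    cohort.schema.require_dgm_specials()
    _, names = cohort.model_matrix()
    terms = [Term("main", (n,)) for n in names]
    terms += [
        Term("polynomial", ("age",), degree=2),
        Term("polynomial", ("age",), degree=3),
        Term("polynomial", ("pafi",), degree=2),
        Term("interaction", ("heart_rate", "mean_bp")),
        Term("interaction", ("gcs", "hematocrit", "sodium")),
        Term("transform", ("weight",), fn="exp"),
        Term("transform", ("apache",), fn="cos"),
    ]
    return tuple(terms)


@dataclass(frozen=True)
class DGMSpec:
    """The true outcome model of the plasmode simulation."""

    terms: tuple[Term, ...]
    beta: np.ndarray  # aligned to terms
    beta_treatment: float
    intercept: float | None = None
    source: str = "user"

    @property
    def calibrated(self) -> bool:
        return self.intercept is not None


@dataclass(frozen=True)
class ScenarioConfig:
    id: str
    exposure_prevalence: float
    outcome_prevalence: float
    true_or: float
    sample_size: int
    n_sims: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.exposure_prevalence < 1:
            raise ValueError("exposure_prevalence must be in (0,1)")
        if not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must be in (0,1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")

    @property
    def true_log_or(self) -> float:
        return float(np.log(self.true_or))


#: the pre-registered scenario grid of the simulation study
PAPER_SCENARIOS: dict[str, ScenarioConfig] = {
    s.id: s
    for s in (
        ScenarioConfig("i", 0.30, 0.30, 0.7, 3500),
        ScenarioConfig("ii", 0.05, 0.30, 0.7, 3500),
        ScenarioConfig("iii", 0.30, 0.05, 0.7, 3500),
        ScenarioConfig("iv", 0.30, 0.30, 0.7, 5000),
        ScenarioConfig("v", 0.30, 0.30, 1.0, 3500),
    )
}


@dataclass(frozen=True)
class PlasmodeReplicate:
    data: CohortTable  # X, A resampled from the base; Y simulated
    scenario_id: str
    replicate_index: int
    seed: int


# ---------------------------------------------------------------------------
# operations


def build_design_matrix(cohort: CohortTable, terms: tuple[Term, ...]) -> np.ndarray:
    """Expand the term list on a preprocessed cohort, columns in term order.

    Polynomial terms are raw powers of the (scaled) variable, interactions
    elementwise products, transforms elementwise exp/cos.
    """
    base, names = cohort.model_matrix()
    col = {n: base[:, j] for j, n in enumerate(names)}
    out = np.empty((cohort.n, len(terms)))
    for j, t in enumerate(terms):
        for v in t.variables:
            if v not in col:
                raise ValueError(f"term {t.label!r} references missing covariate {v!r}")
        if t.kind == "main":
            out[:, j] = col[t.variables[0]]
        elif t.kind == "polynomial":
            out[:, j] = col[t.variables[0]] ** t.degree
        elif t.kind == "interaction":
            prod = col[t.variables[0]].copy()
            for v in t.variables[1:]:
                prod *= col[v]
            out[:, j] = prod
        elif t.kind == "transform":
            fn = {"exp": np.exp, "cos": np.cos}[t.fn]
            out[:, j] = fn(col[t.variables[0]])
        else:
            raise ValueError(f"unknown term kind {t.kind!r}")
    return out


def fit_true_outcome_model(
    base: CohortTable,
    terms: tuple[Term, ...] | None = None,
    true_or: float = 0.7,
) -> DGMSpec:
    """Fit the true-model logistic regression of Y on [A, design] by ML and
    overwrite the treatment coefficient with log(true_or)."""
    if base.Y is None:
        raise ValueError("base cohort has no outcome to fit the DGM on")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    terms = terms if terms is not None else default_terms(base)
    D = build_design_matrix(base, terms)
    Xd = np.column_stack([np.ones(base.n), np.asarray(base.A, dtype=float), D])
    try:
        fit = sm.GLM(np.asarray(base.Y, dtype=float), Xd, family=sm.families.Binomial()).fit(
            maxiter=100
        )
    except Exception as exc:  # pragma: no cover - separation is data-dependent
        raise RuntimeError(f"true outcome model failed to converge: {exc}") from exc
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        bad = [terms[j - 2].label for j in np.where(np.abs(params) > 50)[0] if j >= 2]
        raise RuntimeError(f"true outcome model unstable; offending terms: {bad}")
    return DGMSpec(
        terms=terms,
        beta=params[2:].copy(),
        beta_treatment=float(np.log(true_or)),
        intercept=None,
        source="fitted",
    )


def linear_predictor(spec: DGMSpec, cohort: CohortTable) -> np.ndarray:
    """beta_treatment * A + design @ beta (no intercept)."""
    D = build_design_matrix(cohort, spec.terms)
    return spec.beta_treatment * np.asarray(cohort.A, dtype=float) + D @ spec.beta


def calibrate_intercept(
    spec: DGMSpec,
    cohort: CohortTable,
    target: float,
    exposure_prevalence: float | None = None,
) -> DGMSpec:
    """Set the intercept so mean outcome probability over the cohort hits
    ``target`` (monotone root-finding, |gap| < 1e-8).

    When ``exposure_prevalence`` is given, base rows are weighted by the
    stratified-resampling design (treated rows carry total weight
    ``exposure_prevalence``), so the calibrated prevalence matches the
    expectation over scenario replicates rather than over the base cohort,
    whose own exposure prevalence generally differs.
    """
    lp = linear_predictor(spec, cohort)
    weights = None
    if exposure_prevalence is not None:
        a = np.asarray(cohort.A, dtype=float)
        n1 = a.sum()
        n0 = len(a) - n1
        if n1 == 0 or n0 == 0:
            raise ValueError("weighted calibration needs both exposure strata")
        weights = np.where(a == 1, exposure_prevalence / n1, (1 - exposure_prevalence) / n0)
    b0 = solve_logit_intercept(lp, target, weights=weights)
    return replace(spec, intercept=b0)


def resample_base(
    base: CohortTable, sample_size: int, exposure_prevalence: float, seed: int
) -> CohortTable:
    """Stratified with-replacement resampling with an exact treated count of
    round(sample_size * exposure_prevalence)."""
    A = np.asarray(base.A)
    treated = np.flatnonzero(A == 1)
    control = np.flatnonzero(A == 0)
    if treated.size == 0 or control.size == 0:
        raise ValueError("base cohort needs both treated and untreated rows")
    n1 = int(round(sample_size * exposure_prevalence))
    n0 = sample_size - n1
    if n1 <= 0 or n0 <= 0:
        raise ValueError("prevalence leaves an empty stratum at this sample size")
    rng = np.random.default_rng(seed)
    idx = np.concatenate([rng.choice(treated, n1, replace=True), rng.choice(control, n0, replace=True)])
    return base.take(idx)


def simulate_outcomes(spec: DGMSpec, data: CohortTable, seed: int,
                      scenario_id: str = "", replicate_index: int = 0) -> PlasmodeReplicate:
    """Draw Y_i ~ Bernoulli(expit(intercept + lp_i)) on a resampled table."""
    if not spec.calibrated:
        raise ValueError("DGMSpec intercept is not calibrated")
    # distinct stream from the resampling rng that shares the replicate seed
    rng = np.random.default_rng((seed, 1))
    p = expit(spec.intercept + linear_predictor(spec, data))
    y = (rng.random(data.n) < p).astype(np.int8)
    return PlasmodeReplicate(
        data=data.with_outcome(y),
        scenario_id=scenario_id,
        replicate_index=replicate_index,
        seed=seed,
    )


def make_replicate(
    base: CohortTable, spec: DGMSpec, scenario: ScenarioConfig, replicate_index: int
) -> PlasmodeReplicate:
    """Resample + simulate one replicate; seed = base_seed + replicate_index."""
    seed = scenario.base_seed + replicate_index
    data = resample_base(base, scenario.sample_size, scenario.exposure_prevalence, seed)
    return simulate_outcomes(
        spec, data, seed, scenario_id=scenario.id, replicate_index=replicate_index
    )
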