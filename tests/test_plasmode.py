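import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from psplasmode import (
    CohortTable,
    Covariate,
    CovariateSchema,
    PAPER_SCENARIOS,
    build_design_matrix,
    calibrate_intercept,
    default_terms,
    fit_true_outcome_model,
    make_replicate,
    resample_base,
    simulate_outcomes,
)
from psplasmode.plasmode import DGMSpec, Term, linear_predictor
from psplasmode.schema import DGM_SPECIAL


def special_cohort(n=12, seed=0, with_values=None):
    """Tiny cohort holding only the nine special continuous covariates."""
    rng = np.random.default_rng(seed)
    schema = CovariateSchema(
        tuple(Covariate(name, "continuous", role="dgm_special") for name in DGM_SPECIAL)
    )
    X = pd.DataFrame(rng.standard_normal((n, 9)), columns=list(DGM_SPECIAL))
    if with_values:
        for k, v in with_values.items():
            X[k] = v
    A = np.array([0, 1] * (n // 2))
    return CohortTable(schema=schema, X=X, A=A, scaled=True)


class TestDesignMatrix:
    def test_polynomials_are_raw_powers(self):
        cohort = special_cohort(with_values={"age": 2.0})
        terms = (
            Term("main", ("age",)),
            Term("polynomial", ("age",), degree=2),
            Term("polynomial", ("age",), degree=3),
        )
        D = build_design_matrix(cohort, terms)
        np.testing.assert_allclose(D[0], [2.0, 4.0, 8.0])

    def test_interaction_is_product(self):
        cohort = special_cohort(with_values={"heart_rate": 3.0, "mean_bp": -1.0})
        D = build_design_matrix(cohort, (Term("interaction", ("heart_rate", "mean_bp")),))
        np.testing.assert_allclose(D[:, 0], -3.0)

    def test_transforms_at_zero(self):
        cohort = special_cohort(with_values={"apache": 0.0, "weight": 0.0})
        D = build_design_matrix(
            cohort,
            (Term("transform", ("apache",), fn="cos"), Term("transform", ("weight",), fn="exp")),
        )
        np.testing.assert_allclose(D[0], [1.0, 1.0])

    def test_missing_special_covariate_errors(self, linear_cohort):
        cohort, _ = linear_cohort
        with pytest.raises(ValueError, match="missing covariate"):
            build_design_matrix(cohort, (Term("main", ("age",)),))

    def test_term_list_contains_required_specials(self, base_small):
        labels = {t.label for t in default_terms(base_small)}
        assert {
            "age^2", "age^3", "pafi^2",
            "heart_rate:mean_bp", "gcs:hematocrit:sodium",
            "exp(weight)", "cos(apache)",
        } <= labels


class TestFitTrueOutcomeModel:
    def test_null_base_gives_null_coefficients_and_overwrite(self):
        cohort = special_cohort(n=4000, seed=5)
        rng = np.random.default_rng(6)
        cohort = cohort.with_outcome((rng.random(4000) < 0.4).astype(int))  # Y indep of (A, X)
        spec = fit_true_outcome_model(cohort, true_or=0.7)
        assert spec.source == "fitted"
        assert np.abs(spec.beta).max() < 0.15
        assert spec.beta_treatment == pytest.approx(np.log(0.7), abs=1e-12)

    def test_true_or_values(self, base_full):
        spec = fit_true_outcome_model(base_full, true_or=0.7)
        assert spec.beta_treatment == pytest.approx(-0.356675, abs=1e-6)
        spec1 = fit_true_outcome_model(base_full, true_or=1.0)
        assert spec1.beta_treatment == 0.0

    def test_requires_outcome(self, linear_cohort):
        cohort, _ = linear_cohort
        cohort_no_y = special_cohort()
        with pytest.raises(ValueError, match="outcome"):
            fit_true_outcome_model(cohort_no_y)


class TestCalibrateIntercept:
    def test_zero_predictor_half_target(self):
        cohort = special_cohort(n=10)
        spec = DGMSpec(terms=(), beta=np.empty(0), beta_treatment=0.0)
        out = calibrate_intercept(spec, cohort, 0.5)
        assert out.intercept == pytest.approx(0.0, abs=1e-8)

    def test_bisection_oracle(self):
        # lp = {0, 0, 2}, target 0.7; frozen value from a bisection oracle on
        # (2 expit(b) + expit(b+2)) / 3 = 0.7
        schema = CovariateSchema((Covariate("x", "continuous"),))
        cohort = CohortTable(
            schema=schema,
            X=pd.DataFrame({"x": [0.0, 0.0, 2.0]}),
            A=np.array([0, 0, 1]),
            scaled=True,
        )
        spec = DGMSpec(terms=(Term("main", ("x",)),), beta=np.array([1.0]), beta_treatment=0.0)
        out = calibrate_intercept(spec, cohort, 0.7)
        assert out.intercept == pytest.approx(0.3745823995602485, abs=1e-7)

    def test_calibrated_prevalence_hits_target(self, base_full, dgm_base):
        # the design-weighted mean (treated stratum weighted to the scenario's
        # 30% exposure prevalence) hits the 30% outcome target exactly
        from scipy.special import expit

        p = expit(dgm_base.intercept + linear_predictor(dgm_base, base_full))
        a = base_full.A.astype(float)
        w = np.where(a == 1, 0.30 / a.sum(), 0.70 / (len(a) - a.sum()))
        assert w @ p == pytest.approx(0.30, abs=1e-8)


class TestResample:
    @pytest.mark.parametrize(
        "size,prev,expected", [(3500, 0.30, 1050), (3500, 0.05, 175), (5000, 0.30, 1500)]
    )
    def test_exact_treated_counts(self, base_small, size, prev, expected):
        out = resample_base(base_small, size, prev, seed=1)
        assert int(out.A.sum()) == expected
        assert out.n == size

    def test_rows_carried_unmodified(self, base_small):
        out = resample_base(base_small, 500, 0.3, seed=2)
        base_rows = {tuple(r) for r in base_small.X.itertuples(index=False)}
        assert all(tuple(r) in base_rows for r in out.X.itertuples(index=False))

    def test_degenerate_stratum_errors(self, base_small):
        with pytest.raises(ValueError):
            resample_base(base_small, 100, 1.0 - 1e-9, seed=0)


class TestSimulateOutcomes:
    def test_determinism(self, base_small, dgm_base):
        data = resample_base(base_small, 800, 0.3, seed=3)
        r1 = simulate_outcomes(dgm_base, data, seed=9)
        r2 = simulate_outcomes(dgm_base, data, seed=9)
        assert np.array_equal(r1.data.Y, r2.data.Y)
        r3 = simulate_outcomes(dgm_base, data, seed=10)
        assert not np.array_equal(r1.data.Y, r3.data.Y)

    def test_uncalibrated_spec_rejected(self, base_small):
        spec = DGMSpec(terms=(), beta=np.empty(0), beta_treatment=0.0)
        data = resample_base(base_small, 100, 0.3, seed=0)
        with pytest.raises(ValueError, match="calibrated"):
            simulate_outcomes(spec, data, seed=0)

    def test_prevalence_conservation(self, base_full, dgm_base):
        sc = PAPER_SCENARIOS["i"]
        means, treated = [], []
        for i in range(200):
            rep = make_replicate(base_full, dgm_base, sc, i)
            means.append(rep.data.Y.mean())
            treated.append(rep.data.A.mean())
        assert set(treated) == {0.30}
        mc_se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.30) < 2 * mc_se + 2e-3

    def test_effect_injection_recovered_by_correct_refit(self, base_full, dgm_base):
        # refit the correctly specified outcome model on one very large
        # replicate; the injected treatment log-OR is recovered within 2 SEs
        sc = PAPER_SCENARIOS["i"]
        data = resample_base(base_full, 60000, 0.30, seed=123)
        rep = simulate_outcomes(dgm_base, data, seed=123)
        D = build_design_matrix(rep.data, dgm_base.terms)
        X = np.column_stack([np.ones(rep.data.n), rep.data.A.astype(float), D])
        fit = sm.GLM(rep.data.Y.astype(float), X, family=sm.families.Binomial()).fit()
        assert abs(fit.params[1] - dgm_base.beta_treatment) < 2 * fit.bse[1]
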