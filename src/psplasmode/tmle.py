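"""Targeted maximum likelihood estimation of the marginal odds ratio.

The initial outcome regression Q(A, W) is a super learner: a convex
combination of a main-effects logistic regression and MARS, weighted by
5-fold cross-validated squared-error risk (non-negative least squares
projected onto the simplex).  Given externally estimated propensity
scores g(W) (any of the six PS methods), the targeting step fluctuates
logit Q with two clever covariates

    H1 = A / g(W),        H0 = -(1 - A) / (1 - g(W)),

fitted as a no-intercept logistic regression with offset logit Q(A, W).
The targeted counterfactual means psi1 = mean Q*(1, W) and
psi0 = mean Q*(0, W) give log OR = logit(psi1) - logit(psi0); the SE comes
from the efficient influence curve of (psi1, psi0) with a delta-method map
onto the log-OR scale.  Propensity scores are bounded into [0.001, 0.999]
inside TMLE as a positivity guard, with the number of changed values
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import nnls
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .cohort import CohortTable
from .mars import MarsRegressor

_Z975 = 1.959963984540054
_Q_BOUND = 1e-4
PS_BOUND = (0.001, 0.999)


# ---------------------------------------------------------------------------
# candidate learners


class LogisticLearner:
    name = "logistic"

    def fit(self, X, y):
        self._m = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500, tol=1e-8)
        self._m.fit(X, y)
        return self

    def predict(self, X):
        return self._m.predict_proba(X)[:, 1]


class MarsLearner:
    name = "mars"

    def __init__(self, max_degree: int = 2, max_terms: int = 15):
        self._kwargs = dict(max_degree=max_degree, max_terms=max_terms)

    def fit(self, X, y):
        self._m = MarsRegressor(**self._kwargs)
        self._m.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        return np.clip(self._m.predict(X), _Q_BOUND, 1 - _Q_BOUND)


class MeanLearner:
    """Intercept-only learner; used to exercise a deliberately misspecified
    outcome-model set in double-robustness checks."""

    name = "mean"

    def fit(self, X, y):
        self._p = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(X.shape[0], self._p)


def default_learners() -> list:
    return [LogisticLearner(), MarsLearner()]


@dataclass(frozen=True)
class SuperLearnerFit:
    learners: tuple
    names: tuple[str, ...]
    weights: np.ndarray
    cv_risk: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.column_stack([lr.predict(X) for lr in self.learners])
        return np.clip(preds @ self.weights, _Q_BOUND, 1 - _Q_BOUND)


def _outcome_design(cohort: CohortTable) -> np.ndarray:
    W, _ = cohort.model_matrix()
    return np.column_stack([np.asarray(cohort.A, dtype=float), W])


def fit_super_learner(
    cohort: CohortTable,
    learners: list | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> SuperLearnerFit:
    """Cross-validate the candidate learners on Q(A, W) and weight them by
    simplex-constrained non-negative least squares on the CV predictions."""
    if cohort.Y is None:
        raise ValueError("cohort has no outcome")
    if cohort.n < 50:
        raise ValueError("super learner needs n >= 50")
    learners = learners if learners is not None else default_learners()
    X = _outcome_design(cohort)
    y = np.asarray(cohort.Y, dtype=float)
    n, k = len(y), len(learners)
    Z = np.full((n, k), np.nan)
    failed = np.zeros(k, dtype=bool)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        for j, lr in enumerate(learners):
            if failed[j]:
                continue
            try:
                fit = type(lr)(**getattr(lr, "_kwargs", {})) if hasattr(lr, "_kwargs") else type(lr)()
                Z[test, j] = fit.fit(X[train], y[train]).predict(X[test])
            except Exception:
                failed[j] = True
    cv_risk = np.array(
        [np.inf if failed[j] else float(np.mean((y - Z[:, j]) ** 2)) for j in range(k)]
    )
    ok = ~failed
    if not ok.any():
        raise RuntimeError("all super-learner candidates failed")
    w_ok, _ = nnls(Z[:, ok], y)
    if w_ok.sum() <= 0:  # NNLS returned the zero vector: fall back to best single learner
        w_ok = np.zeros(ok.sum())
        w_ok[np.argmin(cv_risk[ok])] = 1.0
    weights = np.zeros(k)
    weights[ok] = w_ok / w_ok.sum()
    fitted = tuple(lr.fit(X, y) for lr in learners)
    return SuperLearnerFit(
        learners=fitted,
        names=tuple(lr.name for lr in learners),
        weights=weights,
        cv_risk=cv_risk,
    )


# ---------------------------------------------------------------------------
# targeting


@dataclass(frozen=True)
class TMLEEstimate:
    method: str
    psi1: float
    psi0: float
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    epsilon: tuple[float, float]
    n_ps_bounded: int


def tmle_estimate(
    cohort: CohortTable,
    ps: np.ndarray,
    sl: SuperLearnerFit | None = None,
    method: str = "PS",
    seed: int = 0,
) -> TMLEEstimate:
    if cohort.Y is None:
        raise ValueError("cohort has no outcome")
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("propensity scores must lie strictly inside (0,1)")
    g = np.clip(ps, *PS_BOUND)
    n_bounded = int(np.sum(g != ps))
    a = np.asarray(cohort.A, dtype=float)
    y = np.asarray(cohort.Y, dtype=float)
    n = cohort.n

    sl = sl if sl is not None else fit_super_learner(cohort, seed=seed)
    W, _ = cohort.model_matrix()
    X_obs = np.column_stack([a, W])
    X1 = np.column_stack([np.ones(n), W])
    X0 = np.column_stack([np.zeros(n), W])
    q_obs, q1, q0 = sl.predict(X_obs), sl.predict(X1), sl.predict(X0)

    h1 = a / g
    h0 = -(1.0 - a) / (1.0 - g)
    fluct = sm.GLM(
        y,
        np.column_stack([h1, h0]),
        family=sm.families.Binomial(),
        offset=logit(q_obs),
    ).fit(maxiter=100)
    eps1, eps2 = (float(v) for v in fluct.params)

    q1_star = expit(logit(q1) + eps1 / g)
    q0_star = expit(logit(q0) + eps2 * (-1.0 / (1.0 - g)))
    q_obs_star = np.where(a == 1, q1_star, q0_star)
    psi1, psi0 = float(q1_star.mean()), float(q0_star.mean())
    log_or = float(logit(psi1) - logit(psi0))

    ic1 = h1 * (y - q_obs_star) + q1_star - psi1
    ic0 = -h0 * (y - q_obs_star) + q0_star - psi0  # standard-sign clever covariate
    cov = np.cov(np.column_stack([ic1, ic0]), rowvar=False) / n
    grad = np.array([1.0 / (psi1 * (1 - psi1)), -1.0 / (psi0 * (1 - psi0))])
    se = float(np.sqrt(grad @ cov @ grad))
    return TMLEEstimate(
        method=method,
        psi1=psi1,
        psi0=psi0,
        log_or=log_or,
        se=se,
        ci_low=log_or - _Z975 * se,
        ci_high=log_or + _Z975 * se,
        epsilon=(eps1, eps2),
        n_ps_bounded=n_bounded,
    )


def eif_score_means(cohort: CohortTable, ps: np.ndarray, est: TMLEEstimate,
                    sl: SuperLearnerFit) -> tuple[float, float]:
    """Post-fluctuation score-equation residuals mean(H1 (Y - Q*)) and
    mean(H0 (Y - Q*)); both should be ~0 after targeting."""
    g = np.clip(np.asarray(ps, dtype=float), *PS_BOUND)
    a = np.asarray(cohort.A, dtype=float)
    y = np.asarray(cohort.Y, dtype=float)
    W, _ = cohort.model_matrix()
    n = cohort.n
    q1 = sl.predict(np.column_stack([np.ones(n), W]))
    q0 = sl.predict(np.column_stack([np.zeros(n), W]))
    q1_star = expit(logit(q1) + est.epsilon[0] / g)
    q0_star = expit(logit(q0) + est.epsilon[1] * (-1.0 / (1.0 - g)))
    q_star = np.where(a == 1, q1_star, q0_star)
    h1 = a / g
    h0 = -(1.0 - a) / (1.0 - g)
    return float(np.mean(h1 * (y - q_star))), float(np.mean(h0 * (y - q_star)))
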