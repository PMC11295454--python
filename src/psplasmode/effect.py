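"""Doubly adjusted treatment-effect estimation on the matched cohort.

The outcome model is a logistic regression of the (simulated or observed)
binary outcome on treatment plus all covariate main effects — the same
untransformed inputs the propensity-score models saw — fitted on matched
rows only.  The reported effect is the conditional log odds ratio with
the model-based (information-matrix) SE and a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import CohortTable
from .matching import MatchedCohort

_Z975 = 1.959963984540054
_MAX_ABS_COEF = 15.0  # separation screen on standardized inputs


@dataclass(frozen=True)
class EffectEstimate:
    method: str
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    converged: bool

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (np.exp(self.log_or), np.exp(self.ci_low), np.exp(self.ci_high))


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """(params, SEs, converged) for a binomial GLM with intercept prepended."""
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        k = X.shape[1]
        return np.full(k, np.nan), np.full(k, np.nan), False
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    ok = (
        bool(getattr(res, "converged", True))
        and np.all(np.isfinite(params))
        and np.all(np.isfinite(bse))
        and float(np.abs(params).max()) < _MAX_ABS_COEF
    )
    return params, bse, ok


def estimate_effect(
    cohort: CohortTable, matched: MatchedCohort, method: str = "PS"
) -> EffectEstimate:
    """Fit the doubly adjusted model on matched rows and return the
    treatment log-OR with 95% Wald CI."""
    if cohort.Y is None:
        raise ValueError("cohort has no outcome")
    if matched.n_pairs == 0:
        return EffectEstimate(method, np.nan, np.nan, np.nan, np.nan, 0, False)
    rows = matched.matched_rows
    Xcov, _ = cohort.model_matrix()
    y = np.asarray(cohort.Y, dtype=float)[rows]
    a = np.asarray(cohort.A, dtype=float)[rows]
    X = np.column_stack([np.ones(rows.size), a, Xcov[rows]])
    if rows.size <= X.shape[1] + 1:
        return EffectEstimate(method, np.nan, np.nan, np.nan, np.nan, matched.n_pairs, False)
    params, bse, ok = _fit_logistic(y, X)
    log_or, se = float(params[1]), float(bse[1])
    return EffectEstimate(
        method=method,
        log_or=log_or,
        se=se,
        ci_low=log_or - _Z975 * se,
        ci_high=log_or + _Z975 * se,
        n_pairs=matched.n_pairs,
        converged=ok,
    )
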