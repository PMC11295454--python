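"""Scalar intercept calibration for logistic models.

Given a fixed linear predictor ``lp`` the mean response
``mean(expit(b + lp))`` is continuous and strictly increasing in the
intercept ``b``, so the intercept hitting any target proportion is the
unique root of a monotone scalar equation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit


def solve_logit_intercept(
    lp: np.ndarray, target: float, weights: np.ndarray | None = None, tol: float = 1e-10
) -> float:
    """Intercept b with (weighted) mean(expit(b + lp)) = target, within ``tol``."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"target proportion must lie in (0,1), got {target}")
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values; target unreachable")
    if weights is None:
        w = np.full(lp.shape, 1.0 / lp.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()

    def gap(b: float) -> float:
        return float(w @ expit(b + lp) - target)

    lo, hi = -2.0, 2.0
    while gap(lo) > 0:
        lo *= 2.0
        if lo < -500:
            raise ValueError("target unreachable from below")
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 500:
            raise ValueError("target unreachable from above")
    return float(brentq(gap, lo, hi, xtol=tol))
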