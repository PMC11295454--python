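"""1:1 greedy nearest-neighbour caliper matching and balance diagnostics.

Matching operates on the logit of the propensity score with a caliper of
0.2 times the SD of the logit-transformed scores (computed on the full
pre-matching sample, n-1 denominator).  Treated units are processed in
data order, each taking the closest remaining control within the caliper;
ties go to the lower control index.  Balance is summarized by the
standardized mean difference, with the pooled SD taken from the
pre-matching sample so before/after values share a denominator; |SMD| above
0.25 flags imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .cohort import CohortTable

SMD_FLAG = 0.25


@dataclass(frozen=True)
class MatchedCohort:
    pairs: tuple[tuple[int, int], ...]  # (treated row, control row)
    caliper_logit: float
    n_unmatched_treated: int
    smd_table: pd.DataFrame | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def matched_rows(self) -> np.ndarray:
        if not self.pairs:
            return np.empty(0, dtype=int)
        return np.asarray(self.pairs, dtype=int).ravel()


def compute_caliper(ps: np.ndarray, multiplier: float = 0.2) -> float:
    """multiplier x SD of logit(ps) on the full pre-matching sample."""
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("propensity scores must lie strictly inside (0,1)")
    sd = float(np.std(logit(ps), ddof=1))
    if sd == 0.0:
        warnings.warn("constant propensity scores: caliper is 0", stacklevel=2)
    return multiplier * sd


def match(ps: np.ndarray, A: np.ndarray, caliper_logit: float) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement."""
    ps = np.asarray(ps, dtype=float)
    A = np.asarray(A)
    if ps.shape != A.shape:
        raise ValueError("ps and A lengths differ")
    lp = logit(ps)
    treated = np.flatnonzero(A == 1)
    control = np.flatnonzero(A == 0)
    if treated.size == 0 or control.size == 0:
        raise ValueError("matching needs at least one treated and one control unit")
    ctrl_lp = lp[control]
    available = np.ones(control.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for t in treated:  # data order
        d = np.abs(ctrl_lp - lp[t])
        d[~available] = np.inf
        j = int(np.argmin(d))  # argmin takes the first minimum -> lowest index
        if d[j] <= caliper_logit:
            pairs.append((int(t), int(control[j])))
            available[j] = False
    return MatchedCohort(
        pairs=tuple(pairs),
        caliper_logit=float(caliper_logit),
        n_unmatched_treated=treated.size - len(pairs),
    )


def smd(values: np.ndarray, A: np.ndarray, subset: np.ndarray | None = None) -> float:
    """(mean_t - mean_c) / pooled SD, pooled SD = sqrt((s_t^2 + s_c^2)/2)
    always computed on the PRE-matching sample; ``subset`` restricts the
    means (post-matching balance) but not the denominator."""
    values = np.asarray(values, dtype=float)
    A = np.asarray(A)
    t_all, c_all = values[A == 1], values[A == 0]
    if t_all.size < 2 or c_all.size < 2:
        return np.nan
    pooled = np.sqrt((t_all.var(ddof=1) + c_all.var(ddof=1)) / 2.0)
    if subset is not None:
        values, A = values[subset], A[subset]
        t, c = values[A == 1], values[A == 0]
        if t.size < 2 or c.size < 2:
            return np.nan
    else:
        t, c = t_all, c_all
    if pooled == 0.0:
        return 0.0 if t.mean() == c.mean() else np.inf
    return float((t.mean() - c.mean()) / pooled)


def smd_table(cohort: CohortTable, matched: MatchedCohort) -> pd.DataFrame:
    """Per-covariate SMD before and after matching (indicator columns of
    categoricals treated as numeric), with the 0.25 imbalance flag."""
    X, names = cohort.model_matrix()
    A = np.asarray(cohort.A)
    rows = []
    sub = matched.matched_rows if matched.n_pairs else None
    for j, name in enumerate(names):
        before = smd(X[:, j], A)
        after = smd(X[:, j], A, subset=sub) if sub is not None else np.nan
        rows.append(
            {
                "covariate": name,
                "smd_before": before,
                "smd_after": after,
                "imbalance_flag": bool(np.abs(after) > SMD_FLAG) if np.isfinite(after) else True,
            }
        )
    return pd.DataFrame(rows)


def match_cohort(cohort: CohortTable, ps: np.ndarray, with_balance: bool = True) -> MatchedCohort:
    """Caliper computation + matching (+ SMD table) in one call."""
    caliper = compute_caliper(ps)
    m = match(ps, cohort.A, caliper)
    if with_balance:
        m = MatchedCohort(m.pairs, m.caliper_logit, m.n_unmatched_treated, smd_table(cohort, m))
    return m
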