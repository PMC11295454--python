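"""Monte Carlo performance measures for simulation studies.

For a set of replicate estimates theta_hat_i with model SEs se_i and a
known truth theta:

    bias     = mean(theta_hat) - theta
    emp_se   = sd(theta_hat)                      (n-1 denominator)
    mse      = mean((theta_hat - theta)^2)
    mod_se   = mean(se_i)                         (arithmetic mean of SEs)
    coverage = fraction of 95% Wald CIs containing theta
    bias-eliminated coverage = fraction containing mean(theta_hat)

each with the standard simulation-study Monte Carlo SE: emp_se/sqrt(n) for
bias, emp_se/sqrt(2(n-1)) for emp_se, sd((theta_hat-theta)^2)/sqrt(n) for
MSE, sd(se_i)/sqrt(n) for mod_se and sqrt(p(1-p)/n) for the coverages.
With the n-1 SD convention the metrics obey the exact identity
mse = bias^2 + emp_se^2 * (n-1)/n.  Zip-plot data orders replicates by the
fractional centile of |z| = |(theta_hat - theta)/se|.

``mod_se`` averages reported SEs literally; a root-mean-square-of-variances
alternative is available via ``mod_se_rms=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .effect import EffectEstimate


@dataclass(frozen=True)
class PerformanceRow:
    scenario: str
    method: str
    truth: float
    bias: float
    bias_mcse: float
    emp_se: float
    emp_se_mcse: float
    mse: float
    mse_mcse: float
    mod_se: float
    mod_se_mcse: float
    coverage: float
    coverage_mcse: float
    be_coverage: float
    be_coverage_mcse: float
    n_used: int
    n_excluded: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    estimates: list[EffectEstimate],
    truth: float,
    scenario: str = "",
    method: str = "",
    n_excluded_extra: int = 0,
    mod_se_rms: bool = False,
) -> PerformanceRow:
    """Aggregate converged replicate estimates against the known truth."""
    used = [e for e in estimates if e.converged and np.isfinite(e.log_or) and np.isfinite(e.se)]
    n_excluded = len(estimates) - len(used) + n_excluded_extra
    n = len(used)
    if n < 2:
        raise ValueError("summarize needs at least 2 converged estimates")
    est = np.array([e.log_or for e in used])
    ses = np.array([e.se for e in used])
    lo = np.array([e.ci_low for e in used])
    hi = np.array([e.ci_high for e in used])

    bias = float(est.mean() - truth)
    emp_se = float(est.std(ddof=1))
    sq_err = (est - truth) ** 2
    mse = float(sq_err.mean())
    if mod_se_rms:
        mod_se = float(np.sqrt(np.mean(ses**2)))
    else:
        mod_se = float(ses.mean())
    covers = (lo <= truth) & (truth <= hi)
    coverage = float(covers.mean())
    be_covers = (lo <= est.mean()) & (est.mean() <= hi)
    be_coverage = float(be_covers.mean())
    return PerformanceRow(
        scenario=scenario,
        method=method,
        truth=float(truth),
        bias=bias,
        bias_mcse=emp_se / np.sqrt(n),
        emp_se=emp_se,
        emp_se_mcse=emp_se / np.sqrt(2.0 * (n - 1)),
        mse=mse,
        mse_mcse=float(sq_err.std(ddof=1) / np.sqrt(n)),
        mod_se=mod_se,
        mod_se_mcse=float(ses.std(ddof=1) / np.sqrt(n)),
        coverage=coverage,
        coverage_mcse=float(np.sqrt(coverage * (1 - coverage) / n)),
        be_coverage=be_coverage,
        be_coverage_mcse=float(np.sqrt(be_coverage * (1 - be_coverage) / n)),
        n_used=n,
        n_excluded=n_excluded,
    )


def zip_data(estimates: list[EffectEstimate], truth: float) -> pd.DataFrame:
    """Replicates sorted by |z| ascending with fractional centiles
    (i - 0.5)/n — the numeric basis of a zip plot."""
    used = [e for e in estimates if e.converged and np.isfinite(e.log_or)]
    if len(used) < 2:
        raise ValueError("zip_data needs at least 2 converged estimates")
    ses = np.array([e.se for e in used])
    if np.any(ses == 0):
        raise ValueError("zero model SE in a replicate")
    z = np.abs((np.array([e.log_or for e in used]) - truth) / ses)
    order = np.argsort(z, kind="stable")
    rows = []
    n = len(used)
    for rank, i in enumerate(order):
        e = used[i]
        rows.append(
            {
                "centile": (rank + 0.5) / n,
                "abs_z": z[i],
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "covers": bool(e.ci_low <= truth <= e.ci_high),
            }
        )
    return pd.DataFrame(rows)


_MEASURES = ("bias", "emp_se", "mse", "mod_se", "coverage", "be_coverage")


def compare_table(rows: list[PerformanceRow], baseline: str = "PS") -> pd.DataFrame:
    """Measures x methods with arrows marking the direction of change
    relative to the logistic-regression (PS) column."""
    methods = [r.method for r in rows]
    if baseline not in methods:
        raise ValueError(f"baseline method {baseline!r} missing")
    scenarios = {r.scenario for r in rows}
    if len(scenarios) > 1:
        raise ValueError("compare_table expects rows from a single scenario")
    base = next(r for r in rows if r.method == baseline)
    out = {}
    for r in rows:
        col = []
        for m in _MEASURES:
            val, mcse = getattr(r, m), getattr(r, f"{m}_mcse")
            cell = f"{val:.4f} ({mcse:.4f})"
            if r.method != baseline:
                ref = getattr(base, m)
                if val > ref:
                    cell += " ↑"
                elif val < ref:
                    cell += " ↓"
            col.append(cell)
        out[r.method] = col
    return pd.DataFrame(out, index=list(_MEASURES))
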