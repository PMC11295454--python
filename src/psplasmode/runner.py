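"""End-to-end scenario runner and single-dataset analysis driver.

Per replicate: resample covariates/exposure from the base cohort
(stratified, exact treated count) -> simulate outcomes from the calibrated
true model -> for each requested method: estimate the propensity score,
compute the caliper, match 1:1, check balance, fit the doubly adjusted
outcome model (optionally followed by TMLE).  Any stage failure on a
replicate is caught, logged and counted as an exclusion for that method
only.  All seeds derive deterministically from the scenario's base seed
(replicate seed = base_seed + index), so reruns reproduce the results CSV
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import CohortTable, generate_cohort, load_cohort, preprocess
from .effect import EffectEstimate, estimate_effect
from .matching import match_cohort, smd_table
from .performance import PerformanceRow, summarize
from .plasmode import (
    DGMSpec,
    PAPER_SCENARIOS,
    ScenarioConfig,
    calibrate_intercept,
    default_terms,
    fit_true_outcome_model,
    make_replicate,
)
from .ps_estimators import METHODS, NetConfig, estimate_ps
from .tmle import tmle_estimate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    scenarios: tuple[ScenarioConfig, ...] = tuple(PAPER_SCENARIOS.values())
    methods: tuple[str, ...] = ("PS", "MARS", "DL", "AE")
    run_tmle: bool = False
    base_cohort: str = "synthetic"  # "synthetic" or a CSV path
    base_n: int = 5735
    exposure_col: str = "A"
    outcome_col: str = "Y"
    output_dir: str | None = None
    n_workers: int = 1
    global_seed: int = 1
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def prepare_base(config: RunConfig) -> CohortTable:
    """Generate (or load) and preprocess the base cohort."""
    if config.base_cohort == "synthetic":
        base = generate_cohort(n=config.base_n, seed=config.global_seed)
    else:
        base = load_cohort(config.base_cohort, config.exposure_col, config.outcome_col)
    return preprocess(base)


def build_dgm(base: CohortTable, scenario: ScenarioConfig) -> DGMSpec:
    """Refit the true outcome model on the base cohort, inject the scenario's
    treatment log-OR and calibrate the intercept to its outcome prevalence."""
    spec = fit_true_outcome_model(base, default_terms(base), true_or=scenario.true_or)
    return calibrate_intercept(
        spec, base, scenario.outcome_prevalence, exposure_prevalence=scenario.exposure_prevalence
    )


def _scenario_base_seed(global_seed: int, scenario: ScenarioConfig) -> int:
    ids = list(PAPER_SCENARIOS)
    s_idx = ids.index(scenario.id) if scenario.id in ids else len(ids)
    return (global_seed * 1_000_003 + s_idx * 100_003) % 2**31


def _run_replicate(
    base: CohortTable,
    spec: DGMSpec,
    scenario: ScenarioConfig,
    i: int,
    methods: tuple[str, ...],
    net: NetConfig,
    run_tmle: bool,
) -> list[dict]:
    rep = make_replicate(base, spec, scenario, i)
    rows = []
    for m in methods:
        row = {
            "scenario": scenario.id,
            "method": m,
            "replicate": i,
            "log_or": np.nan,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "n_pairs": 0,
            "converged": False,
            "max_abs_smd_after": np.nan,
        }
        try:
            ps = estimate_ps(rep.data, m, replace(net, seed=rep.seed))
            matched = match_cohort(rep.data, ps.ps, with_balance=True)
            est = estimate_effect(rep.data, matched, method=m)
            smd_after = matched.smd_table["smd_after"].abs()
            row.update(
                log_or=est.log_or,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                n_pairs=est.n_pairs,
                converged=bool(est.converged and ps.converged),
                max_abs_smd_after=float(smd_after.max()) if len(smd_after) else np.nan,
            )
            if run_tmle:
                t = tmle_estimate(rep.data, ps.ps, method=m, seed=rep.seed)
                rows.append(
                    {
                        **{k: row[k] for k in ("scenario", "replicate")},
                        "method": f"TMLE:{m}",
                        "log_or": t.log_or,
                        "se": t.se,
                        "ci_low": t.ci_low,
                        "ci_high": t.ci_high,
                        "n_pairs": rep.data.n,
                        "converged": True,
                        "max_abs_smd_after": np.nan,
                    }
                )
        except Exception as exc:
            log.warning("scenario %s replicate %d method %s failed: %s", scenario.id, i, m, exc)
        rows.append(row)
    return rows


def run_scenario(
    config: RunConfig,
    scenario: ScenarioConfig,
    base: CohortTable | None = None,
    spec: DGMSpec | None = None,
) -> tuple[list[PerformanceRow], pd.DataFrame]:
    """Run one scenario; returns per-method performance rows and the
    per-replicate results table."""
    base = base if base is not None else prepare_base(config)
    spec = spec if spec is not None else build_dgm(base, scenario)
    if scenario.base_seed == 0:
        scenario = replace(scenario, base_seed=_scenario_base_seed(config.global_seed, scenario))

    run_one = delayed(_run_replicate)
    if config.n_workers > 1:
        chunks = Parallel(n_jobs=config.n_workers)(
            run_one(base, spec, scenario, i, config.methods, config.net, config.run_tmle)
            for i in range(scenario.n_sims)
        )
    else:
        chunks = [
            _run_replicate(base, spec, scenario, i, config.methods, config.net, config.run_tmle)
            for i in range(scenario.n_sims)
        ]
    results = pd.DataFrame([row for chunk in chunks for row in chunk])
    results = results.sort_values(["method", "replicate"]).reset_index(drop=True)

    perf: list[PerformanceRow] = []
    for m in sorted(results["method"].unique()):
        sub = results[results["method"] == m]
        ests = [
            EffectEstimate(
                method=m,
                log_or=r.log_or,
                se=r.se,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                n_pairs=int(r.n_pairs),
                converged=bool(r.converged),
            )
            for r in sub.itertuples()
        ]
        try:
            perf.append(
                summarize(ests, truth=scenario.true_log_or, scenario=scenario.id, method=m)
            )
        except ValueError:
            log.warning("scenario %s method %s: too few converged replicates", scenario.id, m)
    return perf, results


def run_real_data(
    config: RunConfig, cohort: CohortTable | str
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Single-dataset analysis: every requested method through matching and
    the doubly adjusted model (optionally TMLE), reported on the OR scale
    with 95% CIs, plus the per-method SMD balance tables."""
    if isinstance(cohort, str):
        cohort = load_cohort(cohort, config.exposure_col, config.outcome_col)
    if not cohort.scaled:
        cohort = preprocess(cohort)
    rows, balance = [], {}
    for m in config.methods:
        net = replace(config.net, seed=config.global_seed)
        ps = estimate_ps(cohort, m, net)
        matched = match_cohort(cohort, ps.ps, with_balance=True)
        balance[m] = matched.smd_table
        est = estimate_effect(cohort, matched, method=m)
        or_, lo, hi = est.or_scale
        rows.append(
            {
                "estimator": m,
                "odds_ratio": or_,
                "ci_low": lo,
                "ci_high": hi,
                "n_pairs": est.n_pairs,
                "converged": est.converged,
            }
        )
        if config.run_tmle:
            t = tmle_estimate(cohort, ps.ps, method=m, seed=config.global_seed)
            rows.append(
                {
                    "estimator": f"TMLE:{m}",
                    "odds_ratio": float(np.exp(t.log_or)),
                    "ci_low": float(np.exp(t.ci_low)),
                    "ci_high": float(np.exp(t.ci_high)),
                    "n_pairs": cohort.n,
                    "converged": True,
                }
            )
    return pd.DataFrame(rows), balance
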