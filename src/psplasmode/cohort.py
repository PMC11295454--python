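"""Cohort container, synthetic RHC-like cohort generation and preprocessing.

The synthetic generator stands in for the SUPPORT/RHC cohort: ~50
correlated mixed-type covariates, a confounded binary exposure with a
calibratable prevalence, and a baseline binary outcome whose dependence on
the covariates includes the same kinds of non-linearities (polynomials in
age and PaO2/FiO2, a heart-rate x mean-BP interaction, a GCS x hematocrit
x sodium interaction, exp(weight), cos(APACHE)) that the true outcome
model of the plasmode simulation carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import solve_logit_intercept
from .schema import DGM_SPECIAL, Covariate, CovariateSchema, default_schema

log = logging.getLogger(__name__)

# location/scale used to put synthetic continuous covariates on clinical-looking
# raw units; preprocessing standardizes them back
_RAW_UNITS: dict[str, tuple[float, float]] = {
    "age": (62.0, 16.0),
    "pafi": (220.0, 110.0),
    "heart_rate": (115.0, 40.0),
    "mean_bp": (78.0, 35.0),
    "gcs": (10.0, 4.0),
    "hematocrit": (32.0, 7.0),
    "sodium": (137.0, 7.0),
    "weight": (67.0, 25.0),
    "apache": (55.0, 20.0),
}


@dataclass(frozen=True)
class CohortTable:
    """Subjects x covariates plus exposure (A) and optional outcome (Y)."""

    schema: CovariateSchema
    X: pd.DataFrame
    A: np.ndarray
    Y: np.ndarray | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if len(self.X) < 2:
            raise ValueError("cohort needs n >= 2 rows")
        if list(self.X.columns) != self.schema.names:
            raise ValueError("X columns must match schema order")
        if self.X.isna().any().any():
            raise ValueError("cohort contains missing values")
        a = np.asarray(self.A)
        if a.shape != (len(self.X),) or not np.isin(a, (0, 1)).all():
            raise ValueError("exposure A must be a binary vector of length n")
        if self.Y is not None:
            y = np.asarray(self.Y)
            if y.shape != (len(self.X),) or not np.isin(y, (0, 1)).all():
                raise ValueError("outcome Y must be a binary vector of length n")

    @property
    def n(self) -> int:
        return len(self.X)

    def with_outcome(self, y: np.ndarray) -> "CohortTable":
        return replace(self, Y=np.asarray(y, dtype=np.int8))

    def take(self, idx: np.ndarray) -> "CohortTable":
        """Row subset/resample; covariate values are carried unmodified."""
        return replace(
            self,
            X=self.X.iloc[idx].reset_index(drop=True),
            A=np.asarray(self.A)[idx],
            Y=None if self.Y is None else np.asarray(self.Y)[idx],
        )

    def model_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Main-effects design: continuous/binary as-is, categoricals
        reference-coded against their first level.  Shared by every PS
        estimator and the doubly adjusted outcome model."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        for cov in self.schema.covariates:
            if cov.kind == "categorical":
                vals = self.X[cov.name].astype(str)
                for level in cov.levels[1:]:
                    cols.append((vals == level).to_numpy(dtype=float))
                    names.append(f"{cov.name}[{level}]")
            else:
                cols.append(self.X[cov.name].to_numpy(dtype=float))
                names.append(cov.name)
        if not cols:
            return np.empty((self.n, 0)), names
        return np.column_stack(cols), names


def _standardized_continuous(X: pd.DataFrame, schema: CovariateSchema) -> dict[str, np.ndarray]:
    out = {}
    for name in schema.continuous:
        v = X[name].to_numpy(dtype=float)
        out[name] = (v - v.mean()) / v.std(ddof=1)
    return out


def _exposure_design(schema: CovariateSchema) -> list[str]:
    """12 exposure-model covariates: 5 special-term continuous, then other
    continuous, then binaries, as available."""
    chosen = ["age", "pafi", "heart_rate", "gcs", "apache"]
    others = [c for c in schema.continuous if c not in chosen]
    chosen += others[:4]
    chosen += schema.binary[: 12 - len(chosen)]
    return chosen


def generate_cohort(
    n: int,
    schema: CovariateSchema | None = None,
    exposure_prevalence: float = 0.38,
    confounding_strength: float = 1.0,
    seed: int = 0,
    rho: float = 0.2,
) -> CohortTable:
    """Draw an RHC-like base cohort.

    Continuous covariates come from an exchangeable-correlation (``rho``)
    Gaussian block mapped onto clinical-looking units; binary and
    categorical covariates are generated through logistic/multinomial links
    on the continuous block, which induces cross-type correlation.  The
    exposure follows a logistic model on 12 covariates with slopes
    ±0.2·``confounding_strength`` and an intercept calibrated so the mean
    exposure probability equals ``exposure_prevalence``.  A baseline binary
    outcome (30% prevalence, mildly non-linear in the special covariates)
    is included so that the true outcome model of the plasmode simulation
    can be refit on this cohort.
    """
    if not 0.0 < exposure_prevalence < 1.0:
        raise ValueError(f"exposure_prevalence must be in (0,1), got {exposure_prevalence}")
    if n < 2:
        raise ValueError("n must be >= 2")
    if confounding_strength < 0:
        raise ValueError("confounding_strength must be non-negative")
    schema = schema or default_schema()
    schema.require_dgm_specials()
    rng = np.random.default_rng(seed)

    cont = schema.continuous
    k = len(cont)
    # exchangeable correlation via a shared factor
    shared = rng.standard_normal((n, 1))
    Z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
    data: dict[str, np.ndarray] = {}
    zstd: dict[str, np.ndarray] = {}
    for j, name in enumerate(cont):
        zstd[name] = Z[:, j]
        mu, sd = _RAW_UNITS.get(name, (0.0, 1.0))
        data[name] = mu + sd * Z[:, j]

    offsets = (-1.0, -0.5, 0.0, 0.5, 1.0)
    for j, name in enumerate(schema.binary):
        anchor = cont[j % k]
        p = expit(offsets[j % len(offsets)] + 0.8 * zstd[anchor])
        data[name] = (rng.random(n) < p).astype(np.int8)

    for j, cov in enumerate(schema.categorical):
        a1, a2 = cont[j % k], cont[(j + 3) % k]
        util = np.column_stack(
            [np.zeros(n), 0.7 * zstd[a1], -0.5 * zstd[a1] + 0.6 * zstd[a2]]
        )
        probs = np.exp(util - util.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        idx = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        levels = np.array(cov.levels[: probs.shape[1]])
        data[cov.name] = levels[idx]

    X = pd.DataFrame({name: data[name] for name in schema.names})

    # confounded exposure assignment
    exp_covs = _exposure_design(schema)
    lp_a = np.zeros(n)
    for j, name in enumerate(exp_covs):
        val = zstd[name] if name in zstd else X[name].to_numpy(dtype=float)
        lp_a += ((-1.0) ** j) * 0.2 * confounding_strength * val
    b0 = solve_logit_intercept(lp_a, exposure_prevalence)
    A = (rng.random(n) < expit(b0 + lp_a)).astype(np.int8)

    # baseline outcome: modest main effects plus DGM-style non-linearities
    lp_y = (
        -0.30 * zstd["age"]
        + 0.12 * zstd["age"] ** 2
        - 0.04 * zstd["age"] ** 3
        - 0.25 * zstd["pafi"]
        + 0.10 * zstd["pafi"] ** 2
        + 0.20 * zstd["heart_rate"]
        - 0.20 * zstd["mean_bp"]
        + 0.10 * zstd["heart_rate"] * zstd["mean_bp"]
        - 0.25 * zstd["gcs"]
        - 0.10 * zstd["hematocrit"]
        + 0.10 * zstd["sodium"]
        + 0.06 * zstd["gcs"] * zstd["hematocrit"] * zstd["sodium"]
        + 0.05 * np.exp(zstd["weight"])
        + 0.15 * np.cos(zstd["apache"])
        + 0.25 * zstd["apache"]
    )
    for j, name in enumerate(schema.binary[:6]):
        lp_y += ((-1.0) ** j) * 0.2 * X[name].to_numpy(dtype=float)
    lp_y += np.log(0.8) * A
    c0 = solve_logit_intercept(lp_y, 0.30)
    Y = (rng.random(n) < expit(c0 + lp_y)).astype(np.int8)

    return CohortTable(schema=schema, X=X, A=A, Y=Y, scaled=False)


def load_cohort(
    path,
    exposure_col: str,
    outcome_col: str | None = None,
    schema: CovariateSchema | None = None,
) -> CohortTable:
    """Load a cohort CSV.  Rows with missing values are dropped (complete
    case) with a logged count; covariate kinds are inferred from the data
    when no schema is supplied."""
    df = pd.read_csv(path)
    if exposure_col not in df.columns:
        raise ValueError(f"exposure column {exposure_col!r} not found")
    if outcome_col is not None and outcome_col not in df.columns:
        raise ValueError(f"outcome column {outcome_col!r} not found")

    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if n0 - len(df):
        log.info("load_cohort: dropped %d incomplete rows of %d", n0 - len(df), n0)

    def as_binary(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.isin(vals.unique(), (0, 1)).all():
            raise ValueError(f"column {col!r} is not binary 0/1")
        return vals.to_numpy(dtype=np.int8)

    A = as_binary(exposure_col)
    Y = as_binary(outcome_col) if outcome_col is not None else None

    drop = {exposure_col} | ({outcome_col} if outcome_col else set())
    cov_cols = [c for c in df.columns if c not in drop]
    if schema is None:
        covs = []
        for c in cov_cols:
            numeric = pd.to_numeric(df[c], errors="coerce")
            if numeric.isna().any():
                levels = tuple(sorted(df[c].astype(str).unique()))
                covs.append(Covariate(c, "categorical", levels=levels))
            elif np.isin(numeric.unique(), (0, 1)).all():
                covs.append(Covariate(c, "binary"))
            else:
                role = "dgm_special" if c in DGM_SPECIAL else "plain"
                covs.append(Covariate(c, "continuous", role=role))
        schema = CovariateSchema(tuple(covs))
    X = df[schema.names].copy()
    for cov in schema.covariates:
        if cov.kind != "categorical":
            X[cov.name] = pd.to_numeric(X[cov.name])
    return CohortTable(schema=schema, X=X, A=A, Y=Y, scaled=False)


def preprocess(cohort: CohortTable) -> CohortTable:
    """Center and scale continuous covariates to unit SD (n-1 denominator)."""
    if cohort.scaled:
        raise ValueError("cohort is already scaled")
    X = cohort.X.copy()
    for name in cohort.schema.continuous:
        v = X[name].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"zero-variance continuous column {name!r}")
        X[name] = (v - v.mean()) / sd
    return replace(cohort, X=X, scaled=True)
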