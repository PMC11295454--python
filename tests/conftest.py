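import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from psplasmode import (
    CohortTable,
    Covariate,
    CovariateSchema,
    build_dgm,
    generate_cohort,
    preprocess,
)
from psplasmode.plasmode import PAPER_SCENARIOS


@pytest.fixture(scope="session")
def base_small():
    """Preprocessed synthetic base cohort at desk scale."""
    return preprocess(generate_cohort(1200, seed=42))


@pytest.fixture(scope="session")
def base_full():
    """Preprocessed synthetic base cohort at the RHC cohort size."""
    return preprocess(generate_cohort(5735, seed=11))


@pytest.fixture(scope="session")
def dgm_base(base_full):
    """True outcome model calibrated for the base scenario."""
    return build_dgm(base_full, PAPER_SCENARIOS["i"])


def make_linear_cohort(n=3500, seed=0, with_outcome=False):
    """Cohort with a known logistic-linear true propensity score (and
    optionally a logistic-linear outcome), for well-specified checks."""
    rng = np.random.default_rng(seed)
    p = 5
    schema = CovariateSchema(tuple(Covariate(f"x{i}", "continuous") for i in range(p)))
    X = rng.standard_normal((n, p))
    lp = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.3 * X[:, 2]
    true_ps = expit(lp)
    A = (rng.random(n) < true_ps).astype(np.int8)
    Y = None
    if with_outcome:
        lp_y = -0.5 + 0.6 * X[:, 0] + 0.4 * X[:, 3] - 0.35 * A
        Y = (rng.random(n) < expit(lp_y)).astype(np.int8)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    cohort = CohortTable(schema=schema, X=df, A=A, Y=Y, scaled=True)
    return cohort, true_ps


@pytest.fixture(scope="session")
def linear_cohort():
    return make_linear_cohort(n=3500, seed=7)
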