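"""Propensity-score estimation: the six methods under comparison.

All methods see exactly the same input — the main-effects design matrix of
the preprocessed cohort (continuous covariates standardized, categoricals
reference-coded) — and return probabilities clipped into
[1e-6, 1 - 1e-6] so the logit transform downstream is always finite.

Methods
-------
PS     logistic regression (maximum likelihood)
MARS   least-squares MARS with hinge bases and GCV pruning, truncated
DL     supervised feed-forward classifier with dropout 0.3, L2 1e-2,
       batch normalization and He-normal initialization
DL.n   the same classifier with all four design features disabled
AE     autoencoder bottleneck features -> logistic regression on them
AE.o   autoencoder with the DL design features enabled
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .cohort import CohortTable
from .mars import MarsRegressor
from .nnet import FeedForward

PS_CLIP = 1e-6
METHODS = ("PS", "MARS", "DL", "DL.n", "AE", "AE.o")


@dataclass(frozen=True)
class PSResult:
    method: str
    ps: np.ndarray
    diagnostics: dict
    seed: int = 0

    def __post_init__(self) -> None:
        ps = np.asarray(self.ps)
        if ps.ndim != 1 or np.any(ps <= 0) or np.any(ps >= 1):
            raise ValueError("propensity scores must lie strictly inside (0,1)")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))


@dataclass(frozen=True)
class NetConfig:
    """Architecture/training knobs shared by the DL and AE estimators.

    Defaults: classifier hidden (64, 32, 16), 50 epochs; autoencoder
    encoder (32, 16) with a 10-unit bottleneck and symmetric decoder, 100
    epochs; dropout 0.3, L2 penalty 0.01, batch norm and He-normal
    initialization in the regularized variants; Adam at 1e-3, batch 64.
    """

    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    encoder_sizes: tuple[int, ...] = (32, 16)
    bottleneck_size: int = 10
    dropout_rate: float = 0.3
    l2_penalty: float = 0.01
    batch_norm: bool = True
    he_init: bool = True
    epochs: int = 50
    ae_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        if min(self.hidden_sizes, default=1) <= 0 or self.bottleneck_size <= 0:
            raise ValueError("layer sizes must be positive")


def _clip(p: np.ndarray) -> tuple[np.ndarray, int]:
    clipped = np.clip(p, PS_CLIP, 1 - PS_CLIP)
    return clipped, int(np.sum(p != clipped))


def _check_exposure(cohort: CohortTable) -> np.ndarray:
    a = np.asarray(cohort.A)
    if a.min() == a.max():
        raise ValueError("exposure is constant; propensity model is degenerate")
    return a


def ps_logistic(cohort: CohortTable) -> PSResult:
    """Maximum-likelihood logistic regression on covariate main effects."""
    a = _check_exposure(cohort)
    X, _ = cohort.model_matrix()
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500, tol=1e-8)
    model.fit(X, a)
    # separation screen: runaway coefficients on standardized inputs
    converged = bool(model.n_iter_[0] < 500) and float(np.abs(model.coef_).max()) < 15.0
    ps, n_clip = _clip(model.predict_proba(X)[:, 1])
    return PSResult(
        "PS", ps, {"converged": converged, "truncated": n_clip, "n_iter": int(model.n_iter_[0])}
    )


def ps_mars(cohort: CohortTable, max_degree: int = 2, max_terms: int = 15) -> PSResult:
    """MARS fit of exposure on main effects; raw least-squares predictions
    may leave (0,1) and are truncated, with the count reported."""
    a = _check_exposure(cohort).astype(float)
    X, _ = cohort.model_matrix()
    model = MarsRegressor(max_degree=max_degree, max_terms=max_terms)
    model.fit(X, a)
    raw = model.predict(X)
    ps, n_clip = _clip(raw)
    return PSResult(
        "MARS",
        ps,
        {
            "converged": True,
            "truncated": n_clip,
            "n_bases": len(model.bases_),
            "gcv": model.gcv_,
        },
    )


def ps_deep_supervised(
    cohort: CohortTable, config: NetConfig | None = None, naive: bool = False
) -> PSResult:
    """Feed-forward classifier; ``naive=True`` strips dropout, L2, batch
    norm and He initialization (the fairness-experiment variant DL.n)."""
    config = config or NetConfig()
    a = _check_exposure(cohort)
    X, _ = cohort.model_matrix()
    net = FeedForward(
        [X.shape[1], *config.hidden_sizes, 1],
        task="binary",
        dropout=0.0 if naive else config.dropout_rate,
        l2=0.0 if naive else config.l2_penalty,
        batch_norm=False if naive else config.batch_norm,
        he_init=False if naive else config.he_init,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    hist = net.fit(X, a, epochs=config.epochs, batch_size=config.batch_size)
    ps, n_clip = _clip(net.predict(X))
    return PSResult(
        "DL.n" if naive else "DL",
        ps,
        {"converged": hist["converged"], "truncated": n_clip, "loss": hist["loss"]},
        seed=config.seed,
    )


def ps_autoencoder(
    cohort: CohortTable, config: NetConfig | None = None, optimized: bool = False
) -> PSResult:
    """Autoencoder on the covariates (MSE reconstruction loss); the
    propensity score is a logistic regression of exposure on the bottleneck
    activations.  ``optimized=True`` adds dropout 0.3, L2 0.01, batch norm
    and He initialization (the fairness-experiment variant AE.o)."""
    config = config or NetConfig()
    a = _check_exposure(cohort)
    X, _ = cohort.model_matrix()
    enc = list(config.encoder_sizes)
    # symmetric about the bottleneck: encoder sizes mirrored in the decoder
    sizes = [X.shape[1], *enc, config.bottleneck_size, *enc[::-1], X.shape[1]]
    net = FeedForward(
        sizes,
        task="reconstruction",
        dropout=config.dropout_rate if optimized else 0.0,
        l2=config.l2_penalty if optimized else 0.0,
        batch_norm=config.batch_norm if optimized else False,
        he_init=config.he_init if optimized else False,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    hist = net.fit(X, X, epochs=config.ae_epochs, batch_size=config.batch_size)
    bottleneck_index = len(enc)  # blocks 0..len(enc)-1 encode, block len(enc) is the bottleneck
    Z = net.hidden(X, bottleneck_index)
    keep = Z.std(axis=0) > 1e-12  # dead ReLU units carry no information
    Zk = Z[:, keep] if keep.any() else np.zeros((len(a), 1))
    # bottleneck activations are on arbitrary scales; standardize them so the
    # head fit is well-conditioned and the separation screen is scale-free
    if keep.any():
        Zk = (Zk - Zk.mean(axis=0)) / Zk.std(axis=0)
    head = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500, tol=1e-8)
    head.fit(Zk, a)
    head_ok = bool(head.n_iter_[0] < 500) and float(np.abs(head.coef_).max()) < 15.0
    ps, n_clip = _clip(head.predict_proba(Zk)[:, 1])
    return PSResult(
        "AE.o" if optimized else "AE",
        ps,
        {
            "converged": hist["converged"] and head_ok,
            "truncated": n_clip,
            "loss": hist["loss"],
            "bottleneck_active": int(keep.sum()),
        },
        seed=config.seed,
    )


def estimate_ps(cohort: CohortTable, method: str, config: NetConfig | None = None) -> PSResult:
    """Dispatch by method label (PS, MARS, DL, DL.n, AE, AE.o)."""
    if method == "PS":
        return ps_logistic(cohort)
    if method == "MARS":
        return ps_mars(cohort)
    if method == "DL":
        return ps_deep_supervised(cohort, config, naive=False)
    if method == "DL.n":
        return ps_deep_supervised(cohort, config, naive=True)
    if method == "AE":
        return ps_autoencoder(cohort, config, optimized=False)
    if method == "AE.o":
        return ps_autoencoder(cohort, config, optimized=True)
    raise ValueError(f"unknown propensity-score method {method!r}")
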