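"""Multivariate adaptive regression splines (least-squares flavour).

Forward pass: starting from the intercept, repeatedly add the pair of
reflected hinge bases  parent * max(0, x_v - t)  and  parent * max(0, t - x_v)
that most reduces the residual sum of squares, with knots drawn from the
quantiles of x_v over the rows where the parent basis is active, and
interactions limited to ``max_degree`` factors (no variable repeated within
a term).  Backward pass: greedy basis deletion scored by the generalized
cross-validation criterion

    GCV(m) = RSS/n / (1 - C(m)/n)^2,   C(m) = m + penalty * (m - 1) / 2,

keeping the subset with the smallest GCV.  No cross-validation is used.
When the response is a binary indicator the fitted values are ordinary
least-squares predictions and may leave (0, 1); callers truncate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class _Basis:
    # each factor: (variable index, sign, knot); sign +1 -> max(0, x-t), -1 -> max(0, t-x)
    factors: tuple[tuple[int, int, float], ...]

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> set[int]:
        return {v for v, _, _ in self.factors}

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for v, s, t in self.factors:
            out *= np.maximum(0.0, s * (X[:, v] - t))
        return out


class MarsRegressor:
    def __init__(
        self,
        max_degree: int = 2,
        max_terms: int = 15,
        n_knots: int = 5,
        penalty: float | None = None,
        min_rss_decrease: float = 1e-8,
    ):
        self.max_degree = max_degree
        self.max_terms = max_terms
        self.n_knots = n_knots
        # earth-style defaults: 3 with interactions, 2 additive
        self.penalty = penalty if penalty is not None else (3.0 if max_degree > 1 else 2.0)
        self.min_rss_decrease = min_rss_decrease

    # -- forward pass -------------------------------------------------------
    def _candidate_knots(self, x: np.ndarray, active: np.ndarray) -> np.ndarray:
        vals = x[active]
        if vals.size == 0:
            return np.empty(0)
        qs = np.quantile(vals, np.linspace(0.1, 0.9, self.n_knots))
        return np.unique(qs)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarsRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 10:
            raise ValueError("too few rows for basis construction")
        const_cols = np.ptp(X, axis=0) == 0
        bases: list[_Basis] = [_Basis(())]
        B = np.ones((n, 1))
        yss = float(np.sum((y - y.mean()) ** 2))
        if yss == 0.0:  # constant response -> intercept only
            self._finalize(bases, B, y)
            return self

        while B.shape[1] + 2 <= self.max_terms:
            Q, _ = np.linalg.qr(B)
            r = y - Q @ (Q.T @ y)
            rss = float(r @ r)
            best = None  # (reduction, parent_idx, var, knot)
            for pi, parent in enumerate(bases):
                if parent.degree >= self.max_degree:
                    continue
                pb = B[:, pi]
                active = pb > 0
                if active.sum() < 10:
                    continue
                for v in range(p):
                    if const_cols[v] or v in parent.variables:
                        continue
                    knots = self._candidate_knots(X[:, v], active)
                    if knots.size == 0:
                        continue
                    diff = X[:, v][:, None] - knots[None, :]
                    C = np.concatenate(
                        [pb[:, None] * np.maximum(0.0, diff), pb[:, None] * np.maximum(0.0, -diff)],
                        axis=1,
                    )
                    U = C - Q @ (Q.T @ C)
                    k = knots.size
                    for j in range(k):
                        u1, u2 = U[:, j], U[:, k + j]
                        g11, g22, g12 = u1 @ u1, u2 @ u2, u1 @ u2
                        b1, b2 = u1 @ r, u2 @ r
                        det = g11 * g22 - g12 * g12
                        if det > 1e-10 * max(g11 * g22, 1e-30):
                            red = (g22 * b1 * b1 - 2 * g12 * b1 * b2 + g11 * b2 * b2) / det
                        elif g11 > 1e-12:
                            red = b1 * b1 / g11
                        else:
                            continue
                        if best is None or red > best[0]:
                            best = (red, pi, v, knots[j])
            if best is None or best[0] <= self.min_rss_decrease * yss:
                break
            _, pi, v, t = best
            parent = bases[pi]
            for s in (1, -1):
                nb = _Basis(parent.factors + ((v, s, t),))
                bases.append(nb)
                B = np.column_stack([B, nb.evaluate(X)])

        self._prune(bases, B, y)
        return self

    # -- backward pass ------------------------------------------------------
    def _gcv(self, rss: float, n: int, m: int) -> float:
        c = m + self.penalty * (m - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        return np.inf if denom <= 0 else rss / n / denom

    @staticmethod
    def _rss(B: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        return float(resid @ resid), coef

    def _prune(self, bases: list[_Basis], B: np.ndarray, y: np.ndarray) -> None:
        n = len(y)
        keep = list(range(len(bases)))
        rss, _ = self._rss(B, y)
        best_keep, best_gcv = list(keep), self._gcv(rss, n, len(keep))
        while len(keep) > 1:
            drop_best = None
            for j in keep[1:]:  # never drop the intercept
                trial = [i for i in keep if i != j]
                rss_j, _ = self._rss(B[:, trial], y)
                if drop_best is None or rss_j < drop_best[0]:
                    drop_best = (rss_j, j)
            rss_j, j = drop_best
            keep.remove(j)
            gcv = self._gcv(rss_j, n, len(keep))
            if gcv < best_gcv:
                best_gcv, best_keep = gcv, list(keep)
        self._finalize([bases[i] for i in best_keep], B[:, best_keep], y)

    def _finalize(self, bases: list[_Basis], B: np.ndarray, y: np.ndarray) -> None:
        _, coef = self._rss(B, y)
        self.bases_ = bases
        self.coef_ = coef
        self.gcv_ = self._gcv(float(np.sum((y - B @ coef) ** 2)), len(y), len(bases))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        B = np.column_stack([b.evaluate(X) for b in self.bases_])
        return B @ self.coef_
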