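import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_linear_cohort
from psplasmode import (
    CohortTable,
    Covariate,
    CovariateSchema,
    NetConfig,
    estimate_ps,
    ps_autoencoder,
    ps_deep_supervised,
    ps_logistic,
    ps_mars,
)
from psplasmode.mars import MarsRegressor
from psplasmode.nnet import FeedForward

FAST_NET = NetConfig(epochs=8, ae_epochs=10, seed=3)


def make_cohort(X, A):
    p = X.shape[1]
    schema = CovariateSchema(tuple(Covariate(f"x{i}", "continuous") for i in range(p)))
    return CohortTable(
        schema=schema,
        X=pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]),
        A=np.asarray(A, dtype=np.int8),
        scaled=True,
    )


class TestLogistic:
    def test_independent_exposure_flat_ps(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.standard_normal((2000, 3)), rng.random(2000) < 0.4)
        ps = ps_logistic(cohort).ps
        assert abs(ps.mean() - cohort.A.mean()) < 0.01
        assert ps.std() < 0.05

    def test_monotone_in_single_covariate(self):
        x = np.array([[-1.0], [-0.5], [0.5], [1.0]])
        cohort = make_cohort(np.vstack([x] * 5), np.tile([0, 0, 1, 1], 5))
        ps = ps_logistic(cohort).ps
        first = ps[:4]
        # the groups are separable, so the MLE saturates: require monotone
        # non-decreasing with a genuine increase across the boundary
        assert np.all(np.diff(first) >= 0)
        assert first[-1] - first[0] > 0.9

    def test_constant_exposure_rejected(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort(rng.standard_normal((50, 2)), np.ones(50))
        with pytest.raises(ValueError, match="constant"):
            ps_logistic(cohort)


class TestMars:
    def test_step_function_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-2, 2, 400)
        a = (x > 0.3).astype(float)
        model = MarsRegressor(max_degree=1, n_knots=10).fit(x[:, None], a)
        pred = model.predict(x[:, None])
        assert np.mean((pred - a) ** 2) < 0.05
        assert np.corrcoef(pred, a)[0, 1] > 0.9

    def test_pruning_beats_or_matches_full_basis_gcv(self):
        # GCV of the pruned model must be <= an exhaustive search over all
        # subsets that drop one basis from the full forward model
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 2))
        y = np.maximum(0, X[:, 0] - 0.2) + 0.3 * rng.standard_normal(100)
        m = MarsRegressor(max_degree=1, max_terms=7, n_knots=4).fit(X, y)
        full = MarsRegressor(max_degree=1, max_terms=7, n_knots=4)
        full.min_rss_decrease = -np.inf
        full.fit(X, y)
        assert m.gcv_ <= full.gcv_ + 1e-12

    def test_truncation_counted(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-2, 2, 500)
        a = (x > 0).astype(int)
        cohort = make_cohort(x[:, None], a)
        res = ps_mars(cohort)
        assert np.all((res.ps > 0) & (res.ps < 1))
        assert res.diagnostics["truncated"] >= 0

    def test_near_constant_exposure_gives_flat_ps(self):
        rng = np.random.default_rng(5)
        a = np.zeros(300, dtype=int)
        a[:5] = 1  # nearly constant; no covariate signal
        cohort = make_cohort(rng.standard_normal((300, 2)), a)
        res = ps_mars(cohort)
        assert res.ps.std() < 0.15


class TestDeepSupervised:
    def test_strong_signal_auc(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2000, 1))
        a = ((x[:, 0] + 0.3 * rng.standard_normal(2000)) > 0).astype(int)
        cohort = make_cohort(x, a)
        res = ps_deep_supervised(cohort, NetConfig(epochs=20, seed=0))
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(a, res.ps) > 0.8

    def test_no_signal_limit(self):
        rng = np.random.default_rng(7)
        cohort = make_cohort(rng.standard_normal((1500, 3)), rng.random(1500) < 0.35)
        res = ps_deep_supervised(cohort, NetConfig(epochs=15, seed=1))
        assert abs(res.ps.mean() - 0.35) < 0.06
        assert res.ps.std() < 0.12

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        cohort = make_cohort(rng.standard_normal((400, 4)), rng.random(400) < 0.4)
        r1 = ps_deep_supervised(cohort, FAST_NET)
        r2 = ps_deep_supervised(cohort, FAST_NET)
        np.testing.assert_array_equal(r1.ps, r2.ps)

    def test_naive_variant_label(self):
        rng = np.random.default_rng(9)
        cohort = make_cohort(rng.standard_normal((300, 2)), rng.random(300) < 0.5)
        assert ps_deep_supervised(cohort, FAST_NET, naive=True).method == "DL.n"


class TestAutoencoder:
    def test_full_capacity_reconstruction(self):
        # bottleneck as wide as the input: reconstruction MSE driven near 0
        rng = np.random.default_rng(10)
        X = rng.standard_normal((800, 4))
        net = FeedForward([4, 8, 4, 8, 4], task="reconstruction", seed=0, learning_rate=3e-3)
        hist = net.fit(X, X, epochs=150, batch_size=64)
        assert hist["loss"][-1] < 0.1 * np.var(X)

    def test_bottleneck_two_near_pca_bound_on_rank2_data(self):
        # rank-2 data: a 2-unit bottleneck cannot beat the PCA-2 residual,
        # and with linear structure it should approach it
        rng = np.random.default_rng(11)
        Z = rng.standard_normal((1000, 2))
        M = np.array([[1.0, 0.5, -0.3, 0.2], [0.2, -0.7, 0.4, 1.0]])
        X = Z @ M + 0.1 * rng.standard_normal((1000, 4))
        _, s, _ = np.linalg.svd(X - X.mean(0), full_matrices=False)
        pca2_residual = np.sum(s[2:] ** 2) / X.size  # optimal rank-2 MSE
        net = FeedForward([4, 16, 2, 16, 4], task="reconstruction", seed=1, learning_rate=3e-3)
        net.fit(X, X, epochs=300, batch_size=100)
        mse = np.mean((net.predict(X) - X) ** 2)
        assert mse >= 0.999 * pca2_residual  # PCA is the linear optimum
        assert mse < 2.0 * pca2_residual

    def test_no_signal_limit_downstream_ps(self):
        rng = np.random.default_rng(12)
        cohort = make_cohort(rng.standard_normal((1200, 5)), rng.random(1200) < 0.4)
        res = ps_autoencoder(cohort, NetConfig(ae_epochs=15, seed=2))
        assert abs(res.ps.mean() - 0.4) < 0.05

    def test_seed_determinism_and_label(self):
        rng = np.random.default_rng(13)
        cohort = make_cohort(rng.standard_normal((300, 4)), rng.random(300) < 0.45)
        r1 = ps_autoencoder(cohort, FAST_NET, optimized=True)
        r2 = ps_autoencoder(cohort, FAST_NET, optimized=True)
        np.testing.assert_array_equal(r1.ps, r2.ps)
        assert r1.method == "AE.o"


class TestAllMethods:
    @pytest.mark.parametrize("method", ["PS", "MARS", "DL", "DL.n", "AE", "AE.o"])
    def test_valid_probabilities_and_correlation_with_truth(self, linear_cohort, method):
        # on a logistic-linear cohort every method's PS should track the truth
        cohort, true_ps = linear_cohort
        res = estimate_ps(cohort, method, FAST_NET)
        assert res.ps.shape == (cohort.n,)
        assert np.all((res.ps > 0) & (res.ps < 1))
        rho = spearmanr(res.ps, true_ps).statistic
        assert rho > 0.5, f"{method}: Spearman {rho:.3f}"

    def test_unknown_method_rejected(self, linear_cohort):
        with pytest.raises(ValueError, match="unknown"):
            estimate_ps(linear_cohort[0], "GBM")
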