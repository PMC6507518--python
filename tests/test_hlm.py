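import math

import numpy as np
import pytest
from scipy import stats as sps

from aiptw.data import ClusteredDataset
from aiptw.hlm import (RSATC, SATC, TWO_ARM, VarianceComponents,
                       fit_weighted_hlm, gls_fixed_effects, weighted_loglik)
from aiptw.simulate import (AssignmentCoefficients, ScenarioConfig,
                            generate_dataset)
from aiptw.weights import WeightSet


def _unit_weights(data):
    return WeightSet(w=np.ones(data.n_units), v=np.ones(data.n_clusters),
                     estimand="unweighted", c=0.5)


def _random_toy(seed, K=5, max_n=4):
    """Small dataset with random weights for dense-oracle comparisons."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(1, max_n + 1, K)
    cid = np.repeat([f"c{k}" for k in range(K)], sizes).astype(object)
    n = sizes.sum()
    t = rng.integers(0, 2, n)
    t[0], t[-1] = 1, 0       # guarantee both arms somewhere
    y = rng.normal(1.0, 2.0, n)
    d = ClusteredDataset(cluster_id=cid, t=t, y=y)
    w = rng.uniform(0.3, 2.5, n)
    v = rng.uniform(0.5, 1.5, K)
    return d, WeightSet(w=w, v=v, estimand="x", c=0.4)


def _dense_reference(data, ws, beta, vc):
    """Brute-force N x N multivariate-normal evaluation, cluster by cluster."""
    codes, _ = data.cluster_codes()
    X = np.column_stack([data.t, 1 - data.t]).astype(float)
    om = vc.omega()
    ll = 0.0
    bread = np.zeros((2, 2))
    rhs = np.zeros(2)
    for k in range(codes.max() + 1):
        m = codes == k
        Z = X[m]
        V = Z @ om @ Z.T + vc.sigma_eps_sq * np.diag(1.0 / ws.w[m])
        ll += ws.v[k] * sps.multivariate_normal.logpdf(data.y[m], X[m] @ beta, V)
        Vi = np.linalg.inv(V)
        bread += ws.v[k] * X[m].T @ Vi @ X[m]
        rhs += ws.v[k] * X[m].T @ Vi @ data.y[m]
    return ll, np.linalg.solve(bread, rhs), np.linalg.inv(bread)


class TestWeightedLoglik:
    def test_single_standard_normal_unit(self):
        d = ClusteredDataset(cluster_id=np.array(["a"], dtype=object),
                             t=np.array([1]), y=np.array([0.0]))
        ws = WeightSet(w=np.ones(1), v=np.ones(1), estimand="x", c=0.5)
        vc = VarianceComponents(0.0, 0.0, 0.0, 1.0)
        ll = weighted_loglik(d, ws, TWO_ARM, np.array([0.0, 0.0]), vc)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_doubling_cluster_weights_doubles_loglik(self):
        d, ws = _random_toy(7)
        vc = VarianceComponents(1.0, 2.0, 0.3, 1.5)
        beta = np.array([0.2, -0.1])
        ll1 = weighted_loglik(d, ws, TWO_ARM, beta, vc)
        ws2 = WeightSet(w=ws.w, v=2 * ws.v, estimand="x", c=0.4)
        assert weighted_loglik(d, ws2, TWO_ARM, beta, vc) == pytest.approx(2 * ll1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        d, ws = _random_toy(seed)
        vc = VarianceComponents(1.3, 0.7, -0.4, 0.9)
        beta = np.array([0.5, -0.2])
        ours = weighted_loglik(d, ws, TWO_ARM, beta, vc)
        ref, _, _ = _dense_reference(d, ws, beta, vc)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_invariant_to_cluster_relabeling(self):
        d, ws = _random_toy(3)
        vc = VarianceComponents(0.8, 1.1, 0.2, 1.0)
        beta = np.array([0.0, 0.3])
        ll = weighted_loglik(d, ws, TWO_ARM, beta, vc)
        relabeled = ClusteredDataset(
            cluster_id=np.array([f"x_{c}" for c in d.cluster_id], dtype=object),
            t=d.t, y=d.y)
        assert weighted_loglik(relabeled, ws, TWO_ARM, beta, vc) == \
            pytest.approx(ll, abs=1e-10)


class TestGLS:
    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_dense_oracle(self, seed):
        d, ws = _random_toy(seed)
        vc = VarianceComponents(0.9, 1.4, 0.5, 1.2)
        beta, cov = gls_fixed_effects(d, ws, TWO_ARM, vc)
        _, ref_beta, ref_cov = _dense_reference(d, ws, np.zeros(2), vc)
        np.testing.assert_allclose(beta, ref_beta, atol=1e-8)
        np.testing.assert_allclose(cov, ref_cov, atol=1e-8)

    def test_reduces_to_ols_single_cluster(self):
        rng = np.random.default_rng(9)
        n = 12
        d = ClusteredDataset(cluster_id=np.full(n, "a", dtype=object),
                             t=rng.integers(0, 2, n), y=rng.normal(size=n))
        ws = _unit_weights(d)
        vc = VarianceComponents(0.0, 0.0, 0.0, 1.0)
        beta, _ = gls_fixed_effects(d, ws, TWO_ARM, vc)
        X = np.column_stack([d.t, 1 - d.t]).astype(float)
        ols = np.linalg.lstsq(X, d.y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_invariant_to_cluster_permutation(self):
        d, ws = _random_toy(11)
        vc = VarianceComponents(1.0, 1.0, 0.0, 1.0)
        beta, _ = gls_fixed_effects(d, ws, TWO_ARM, vc)
        codes, labels = d.cluster_codes()
        order = np.argsort([-len(np.flatnonzero(codes == k))
                            for k in range(len(labels))], kind="stable")
        idx = np.concatenate([np.flatnonzero(codes == k) for k in order])
        d2 = ClusteredDataset(cluster_id=d.cluster_id[idx], t=d.t[idx],
                              y=d.y[idx])
        ws2 = WeightSet(w=ws.w[idx], v=ws.v[order], estimand="x", c=0.4)
        beta2, _ = gls_fixed_effects(d2, ws2, TWO_ARM, vc)
        np.testing.assert_allclose(beta, beta2, atol=1e-10)


class TestFit:
    def test_pure_noise_recovers_weighted_arm_means(self):
        rng = np.random.default_rng(21)
        n = 600
        cid = np.repeat([f"c{k}" for k in range(30)], 20).astype(object)
        t = rng.integers(0, 2, n)
        y = rng.normal(3.0, 1.0, n) + 2.0 * t
        d = ClusteredDataset(cluster_id=cid, t=t, y=y)
        w = rng.uniform(0.5, 2.0, n)
        ws = WeightSet(w=w, v=np.ones(30), estimand="x", c=0.5)
        fit = fit_weighted_hlm(d, ws, TWO_ARM)
        m1 = np.sum(w * t * y) / np.sum(w * t)
        m0 = np.sum(w * (1 - t) * y) / np.sum(w * (1 - t))
        # Omega ~ 0 here, so the fit collapses to per-arm weighted means
        assert fit["beta1"] == pytest.approx(m1, abs=0.02)
        assert fit["beta0"] == pytest.approx(m0, abs=0.02)

    def test_randomized_parameter_recovery(self):
        cfg = ScenarioConfig(K=500, nk_lo=20, nk_hi=20, beta0=35.0, beta1=40.0,
                             sigma0=8.0, sigma1=8.0, rho=0.8, sigma_eps=20.0,
                             r0=0.0, r1=0.0, p=0.5, violation_frac=0.0)
        gen = generate_dataset(cfg, AssignmentCoefficients(0, 0, 0, 0), seed=42)
        fit = fit_weighted_hlm(gen.dataset, _unit_weights(gen.dataset), TWO_ARM)
        se0 = math.sqrt(fit.beta_cov[1, 1])
        se1 = math.sqrt(fit.beta_cov[0, 0])
        assert abs(fit["beta0"] - 35.0) < 3 * se0
        assert abs(fit["beta1"] - 40.0) < 3 * se1
        assert fit.vc.sigma0 == pytest.approx(8.0, rel=0.25)
        assert fit.vc.sigma_eps == pytest.approx(20.0, rel=0.05)

    def test_refit_from_solution_is_idempotent(self, no_violation_dataset):
        d = no_violation_dataset
        ws = _unit_weights(d)
        fit = fit_weighted_hlm(d, ws, TWO_ARM)
        start = np.array([
            0.5 * math.log(fit.vc.sigma0_sq / fit.vc.sigma_eps_sq),
            0.5 * math.log(fit.vc.sigma1_sq / fit.vc.sigma_eps_sq),
            math.atanh(fit.vc.rho)])
        refit = fit_weighted_hlm(d, ws, TWO_ARM, start=start)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)
        np.testing.assert_allclose(refit.beta, fit.beta, atol=1e-4)

    def test_matches_independent_mixed_model_implementation(
            self, no_violation_dataset):
        statsmodels = pytest.importorskip("statsmodels.api")
        d = no_violation_dataset
        fit = fit_weighted_hlm(d, _unit_weights(d), TWO_ARM)
        X = np.column_stack([d.t, 1 - d.t]).astype(float)
        m = statsmodels.MixedLM(d.y, X, groups=d.cluster_id, exog_re=X)
        r = m.fit(reml=False, method="lbfgs", maxiter=500)
        np.testing.assert_allclose(fit.beta, np.asarray(r.fe_params), atol=1e-2)
        assert fit.loglik >= r.llf - 1e-3   # same optimum (or slightly better)

    def test_unsupported_column_raises(self):
        d = ClusteredDataset(cluster_id=np.array(["a", "a"], dtype=object),
                             t=np.array([0, 0]), y=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="beta1"):
            fit_weighted_hlm(d, _unit_weights(d), TWO_ARM)


class TestBlups:
    def test_missing_arm_blup_is_zero_when_uncorrelated(self):
        rng = np.random.default_rng(33)
        cid = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        t = np.array([1, 1, 1, 0, 0, 0] + [0] * 6)   # cluster b all-control
        y = rng.normal(10, 2, 12)
        d = ClusteredDataset(cluster_id=cid, t=t, y=y)
        ws = _unit_weights(d)
        fit = fit_weighted_hlm(d, ws, TWO_ARM)
        from aiptw.hlm import _ClusterStats, get_spec
        stats = _ClusterStats(d, ws, get_spec("two_arm"))
        vc0 = VarianceComponents(fit.vc.sigma0_sq, fit.vc.sigma1_sq, 0.0,
                                 fit.vc.sigma_eps_sq)
        blups = stats.blups(vc0, fit.beta)
        assert blups[1, 0] == 0.0     # b_hat_k1 for the all-control cluster

    def test_shrinkage_toward_zero_with_less_information(self):
        # same residual, smaller cluster -> smaller |BLUP|
        y = np.array([12.0, 12.0, 12.0, 12.0, 10.0, 12.0])
        d_big = ClusteredDataset(
            cluster_id=np.array(list("aaaabc"), dtype=object),
            t=np.array([1, 1, 1, 1, 1, 0]), y=y)
        d_small = ClusteredDataset(
            cluster_id=np.array(list("aabbcc"), dtype=object)[:6],
            t=np.array([1, 1, 1, 1, 1, 0]),
            y=y)
        from aiptw.hlm import _ClusterStats, get_spec
        vc = VarianceComponents(4.0, 4.0, 0.0, 1.0)
        beta = np.array([11.0, 12.0])
        b_big = _ClusterStats(d_big, _unit_weights(d_big),
                              get_spec("two_arm")).blups(vc, beta)
        b_small = _ClusterStats(d_small, _unit_weights(d_small),
                                get_spec("two_arm")).blups(vc, beta)
        assert abs(b_small[0, 0]) < abs(b_big[0, 0])
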