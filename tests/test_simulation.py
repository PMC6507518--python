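import numpy as np
import pytest
from dataclasses import replace

from aiptw.simulate import (PRESETS, AssignmentCoefficients,
                            InfeasibleTargetsError, ScenarioConfig,
                            analytic_treatment_moments, calibrate_assignment,
                            expected_violation_fraction, generate_dataset)


def _mc_moments(coeffs, sigma0, sigma1, rho, n=1_000_000, seed=0):
    """Monte Carlo oracle for (p, r0, r1) from raw latent draws."""
    rng = np.random.default_rng(seed)
    off = rho * sigma1 * sigma0
    L = np.linalg.cholesky([[sigma1**2, off], [off, sigma0**2]])
    b = rng.standard_normal((n, 2)) @ L.T          # (b1, b0)
    g = (coeffs.c1 + coeffs.c2 * b[:, 1] + coeffs.c3 * b[:, 0]
         + coeffs.c4 * rng.standard_normal(n) + rng.standard_normal(n))
    t = g > 0
    p = t.mean()
    sd = np.sqrt(p * (1 - p))
    r0 = np.cov(t, b[:, 1])[0, 1] / (sd * sigma0)
    r1 = np.cov(t, b[:, 0])[0, 1] / (sd * sigma1)
    return p, r0, r1


class TestAnalyticMoments:
    def test_null_mechanism(self):
        p, r0, r1 = analytic_treatment_moments(
            AssignmentCoefficients(0, 0, 0, 0), 8.0, 8.0, 0.8)
        assert (p, r0, r1) == pytest.approx((0.5, 0.0, 0.0))

    @pytest.mark.parametrize("coeffs,rho", [
        (AssignmentCoefficients(-0.7, 0.05, 0.02, 1.2), 0.5),
        (AssignmentCoefficients(0.4, -0.08, 0.04, 0.3), -0.4),
    ])
    def test_matches_monte_carlo_oracle(self, coeffs, rho):
        exact = analytic_treatment_moments(coeffs, 8.0, 6.0, rho)
        mc = _mc_moments(coeffs, 8.0, 6.0, rho)
        # 3 MC SEs at n = 1e6 is ~0.0015 for p and ~0.004 for correlations
        assert exact[0] == pytest.approx(mc[0], abs=0.002)
        assert exact[1] == pytest.approx(mc[1], abs=0.005)
        assert exact[2] == pytest.approx(mc[2], abs=0.005)

    def test_r0_antisymmetric_in_c2_when_uncorrelated(self):
        a = analytic_treatment_moments(
            AssignmentCoefficients(-0.5, 0.06, 0.0, 1.0), 8.0, 8.0, 0.0)
        b = analytic_treatment_moments(
            AssignmentCoefficients(-0.5, -0.06, 0.0, 1.0), 8.0, 8.0, 0.0)
        assert a[1] == pytest.approx(-b[1])
        assert a[0] == pytest.approx(b[0])


class TestViolationFraction:
    def test_singleton_clusters_always_violate(self):
        cfg = ScenarioConfig(K=10, nk_lo=1, nk_hi=1, beta0=0.0, beta1=1.0,
                             sigma0=8.0, sigma1=8.0, rho=0.0, sigma_eps=1.0,
                             r0=0.0, r1=0.0, p=0.3, violation_frac=0.5)
        co = AssignmentCoefficients(-0.5, 0.0, 0.0, 0.0)
        assert expected_violation_fraction(co, cfg) == pytest.approx(1.0)

    def test_constant_propensity_closed_form(self):
        cfg = ScenarioConfig(K=10, nk_lo=1, nk_hi=19, beta0=0.0, beta1=1.0,
                             sigma0=8.0, sigma1=8.0, rho=0.0, sigma_eps=1.0,
                             r0=0.0, r1=0.0, p=0.3, violation_frac=0.5)
        # c2 = c3 = c4 = 0: pi is the constant Phi(c1)
        from scipy.stats import norm
        c1 = norm.ppf(0.3)
        co = AssignmentCoefficients(c1, 0.0, 0.0, 0.0)
        ns = np.arange(1, 20)
        closed = np.mean(0.3 ** ns + 0.7 ** ns)
        assert expected_violation_fraction(co, cfg) == pytest.approx(
            closed, abs=1e-6)

    def test_quadrature_agrees_with_monte_carlo(self):
        cfg = PRESETS["setting1_80"]
        co = AssignmentCoefficients(-2.5, 0.17, 0.17, 3.8)
        q = expected_violation_fraction(co, cfg, method="quadrature")
        mc = expected_violation_fraction(co, cfg, method="mc",
                                         n_draws=400_000, seed=5)
        assert q == pytest.approx(mc, abs=0.003)


class TestCalibration:
    @pytest.mark.parametrize("preset", ["setting1_80", "setting2_r4m4"])
    def test_round_trips_all_targets(self, preset):
        cfg = PRESETS[preset]
        co = calibrate_assignment(cfg)
        p, r0, r1 = analytic_treatment_moments(co, cfg.sigma0, cfg.sigma1,
                                               cfg.rho)
        assert p == pytest.approx(cfg.p, abs=0.01)
        assert r0 == pytest.approx(cfg.r0, abs=0.01)
        assert r1 == pytest.approx(cfg.r1, abs=0.01)
        viol = expected_violation_fraction(co, cfg, method="mc",
                                           n_draws=300_000, seed=3)
        assert viol == pytest.approx(cfg.violation_frac, abs=0.01)

    def test_null_targets_give_null_coefficients(self):
        cfg = ScenarioConfig(K=100, nk_lo=1, nk_hi=19, beta0=0.0, beta1=1.0,
                             sigma0=8.0, sigma1=8.0, rho=0.5, sigma_eps=1.0,
                             r0=0.0, r1=0.0, p=0.5, violation_frac=0.3)
        co = calibrate_assignment(cfg)
        assert co.c1 == pytest.approx(0.0, abs=1e-8)
        assert co.c2 == pytest.approx(0.0, abs=1e-8)
        assert co.c3 == pytest.approx(0.0, abs=1e-8)
        assert co.c4 > 0.0     # violation target met through cluster noise

    def test_infeasible_targets_raise(self):
        cfg = ScenarioConfig(K=100, nk_lo=10, nk_hi=19, beta0=0.0, beta1=1.0,
                             sigma0=8.0, sigma1=8.0, rho=0.0, sigma_eps=1.0,
                             r0=0.9, r1=0.9, p=0.5, violation_frac=0.0)
        with pytest.raises(InfeasibleTargetsError):
            calibrate_assignment(cfg)


class TestGenerator:
    def test_bit_reproducible(self):
        cfg = PRESETS["setting1_80"]
        co = calibrate_assignment(cfg)
        a = generate_dataset(cfg, co, seed=8)
        b = generate_dataset(cfg, co, seed=8)
        np.testing.assert_array_equal(a.dataset.y, b.dataset.y)
        np.testing.assert_array_equal(a.dataset.t, b.dataset.t)

    def test_observed_outcome_identity(self):
        cfg = PRESETS["setting1_26"]
        gen = generate_dataset(cfg, calibrate_assignment(cfg), seed=12)
        t = gen.dataset.t
        np.testing.assert_array_equal(
            gen.dataset.y, np.where(t == 1, gen.y1, gen.y0))

    def test_empirical_moments_match_targets(self):
        cfg = PRESETS["setting1_80"]
        co = calibrate_assignment(cfg)
        ts, b0s, viols, effects = [], [], [], []
        for seed in range(40):
            gen = generate_dataset(cfg, co, seed=seed)
            codes, _ = gen.dataset.cluster_codes()
            ts.append(gen.dataset.t)
            b0s.append(gen.cluster_truth["b0"].to_numpy()[codes])
            viols.append(gen.violating_fraction)
            effects.append(np.mean(gen.y1 - gen.y0))
        t = np.concatenate(ts).astype(float)
        b0 = np.concatenate(b0s)
        r0_hat = np.cov(t, b0)[0, 1] / (t.std() * b0.std())
        assert t.mean() == pytest.approx(cfg.p, abs=0.02)
        assert r0_hat == pytest.approx(cfg.r0, abs=0.03)
        assert np.mean(viols) == pytest.approx(cfg.violation_frac, abs=0.02)
        assert np.mean(effects) == pytest.approx(cfg.delta, abs=0.5)

    def test_violation_rate_26_percent_preset(self):
        cfg = PRESETS["setting1_26"]
        co = calibrate_assignment(cfg)
        viols = [generate_dataset(cfg, co, seed=s).violating_fraction
                 for s in range(30)]
        assert np.mean(viols) == pytest.approx(0.26, abs=0.025)


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PRESETS["setting2_r26"]
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert ScenarioConfig.from_yaml(p) == cfg

    @pytest.mark.parametrize("bad", [
        dict(nk_lo=0), dict(rho=1.0), dict(p=0.0), dict(violation_frac=1.0)])
    def test_invalid_fields_rejected(self, bad):
        base = dict(K=10, nk_lo=1, nk_hi=5, beta0=0.0, beta1=1.0, sigma0=1.0,
                    sigma1=1.0, rho=0.0, sigma_eps=1.0, r0=0.0, r1=0.0,
                    p=0.5, violation_frac=0.5)
        base.update(bad)
        with pytest.raises(ValueError):
            ScenarioConfig(**base)
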