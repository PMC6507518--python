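"""Synthetic clustered data with a calibrated confounded treatment mechanism.

Data are drawn from the two-arm random-coefficient potential-outcome model

    Y_ik(1) = beta1 + b_k1 + eps_ik(1),   Y_ik(0) = beta0 + b_k0 + eps_ik(0),

with (b_k1, b_k0) ~ N(0, Omega) and eps ~ N(0, sigma_eps^2).  Treatment is
assigned by a latent probit index that ties assignment to the cluster
effects (confounding at the cluster level only):

    T_ik = 1  iff  g = c1 + c2*b_k0 + c3*b_k1 + c4*zeta_k + xi_ik > 0,

with zeta_k and xi_ik standard normal.  The coefficients (c1..c4) are never
specified directly; they are calibrated so that the mechanism hits four
interpretable targets: the treated fraction p, the correlations r0 =
corr(T, b_k0) and r1 = corr(T, b_k1), and the expected fraction of clusters
observed in a single arm (the practical positivity violation rate).

Given targets (p, r0, r1), three of the four coefficients follow in closed
form from normal moment identities up to the overall latent scale
s = sd(g); the violation fraction is then matched by a one-dimensional
root-find on s, with c4 absorbing the remaining latent variance.  The whole
calibration is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .data import ClusteredDataset

__all__ = [
    "ScenarioConfig",
    "AssignmentCoefficients",
    "GeneratedDataset",
    "InfeasibleTargetsError",
    "analytic_treatment_moments",
    "expected_violation_fraction",
    "calibrate_assignment",
    "generate_dataset",
    "PRESETS",
]


class InfeasibleTargetsError(ValueError):
    """No assignment mechanism reaches the requested calibration targets."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative specification of one simulation scenario.

    ``K`` clusters; cluster sizes drawn uniformly on {nk_lo, ..., nk_hi};
    outcome model parameters (beta0, beta1, sigma0, sigma1, rho, sigma_eps);
    assignment calibration targets (r0, r1, p, violation_frac).
    """

    K: int
    nk_lo: int
    nk_hi: int
    beta0: float
    beta1: float
    sigma0: float
    sigma1: float
    rho: float
    sigma_eps: float
    r0: float
    r1: float
    p: float
    violation_frac: float

    def __post_init__(self) -> None:
        if not (self.nk_hi >= self.nk_lo >= 1):
            raise ValueError("cluster size law requires nk_hi >= nk_lo >= 1")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if not 0.0 <= self.violation_frac < 1.0:
            raise ValueError("violation_frac must lie in [0, 1)")

    @property
    def delta(self) -> float:
        return self.beta1 - self.beta0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass(frozen=True)
class AssignmentCoefficients:
    """Latent-index coefficients (c1, c2, c3, c4) of the assignment mechanism."""

    c1: float
    c2: float
    c3: float
    c4: float

    def latent_scale(self, sigma0: float, sigma1: float, rho: float) -> float:
        """sd of g = c1 + c2 b0 + c3 b1 + c4 zeta + xi."""
        var = (self.c2 ** 2 * sigma0 ** 2 + self.c3 ** 2 * sigma1 ** 2
               + 2.0 * self.c2 * self.c3 * rho * sigma0 * sigma1
               + self.c4 ** 2 + 1.0)
        return math.sqrt(var)


@dataclass
class GeneratedDataset:
    """A simulated dataset plus its generating ground truth."""

    dataset: ClusteredDataset
    cluster_truth: pd.DataFrame   # cluster_id, n, b1, b0, pi, delta_k
    y1: np.ndarray                # per-unit potential outcomes
    y0: np.ndarray

    @property
    def violating_fraction(self) -> float:
        codes, labels = self.dataset.cluster_codes()
        n = np.bincount(codes)
        n1 = np.bincount(codes, weights=self.dataset.t)
        return float(((n1 == 0) | (n1 == n)).mean())


def analytic_treatment_moments(coeffs: AssignmentCoefficients, sigma0: float,
                               sigma1: float, rho: float):
    """Exact (p, r0, r1) implied by the latent-index mechanism.

    With g ~ N(c1, s^2): p = Phi(c1/s), and by Stein's identity
    cov(T, b_k0) = phi(c1/s) (c2 sigma0^2 + c3 rho sigma0 sigma1) / s,
    so r0 = cov / (sigma0 sqrt(p(1-p))); r1 analogously.
    """
    s = coeffs.latent_scale(sigma0, sigma1, rho)
    z = coeffs.c1 / s
    p = stats.norm.cdf(z)
    phi = stats.norm.pdf(z)
    sd_t = math.sqrt(p * (1.0 - p))
    cov0 = phi * (coeffs.c2 * sigma0 ** 2 + coeffs.c3 * rho * sigma0 * sigma1) / s
    cov1 = phi * (coeffs.c3 * sigma1 ** 2 + coeffs.c2 * rho * sigma0 * sigma1) / s
    return float(p), float(cov0 / (sigma0 * sd_t)), float(cov1 / (sigma1 * sd_t))


def expected_violation_fraction(coeffs: AssignmentCoefficients,
                                config: ScenarioConfig, *,
                                method: str = "quadrature",
                                n_draws: int = 100_000, seed=None,
                                n_nodes: int = 120) -> float:
    """Expected fraction of clusters observed in one arm only.

    Averages pi^n + (1-pi)^n over the cluster latent u ~ N(c1, s^2 - 1)
    (pi = Phi(u)) and the cluster-size law, by Gauss-Hermite quadrature or
    plain Monte Carlo.
    """
    s = coeffs.latent_scale(config.sigma0, config.sigma1, config.rho)
    sd_u = math.sqrt(max(s * s - 1.0, 0.0))
    ns = np.arange(config.nk_lo, config.nk_hi + 1)
    if method == "quadrature":
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        u = coeffs.c1 + sd_u * x
        w = w / w.sum()
    elif method == "mc":
        rng = np.random.default_rng(seed)
        u = coeffs.c1 + sd_u * rng.standard_normal(n_draws)
        w = np.full(u.shape, 1.0 / u.shape[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    pi = stats.norm.cdf(u)
    per_u = (pi[:, None] ** ns + (1.0 - pi[:, None]) ** ns).mean(axis=1)
    return float(w @ per_u)


def _inner_solve(s: float, config: ScenarioConfig):
    """(c1, c2, c3, c4^2) hitting (p, r0, r1) exactly at latent scale s."""
    zp = stats.norm.ppf(config.p)
    phi = stats.norm.pdf(zp)
    sd_t = math.sqrt(config.p * (1.0 - config.p))
    a0 = config.r0 * config.sigma0 * sd_t * s / phi
    a1 = config.r1 * config.sigma1 * sd_t * s / phi
    off = config.rho * config.sigma0 * config.sigma1
    M = np.array([[config.sigma0 ** 2, off], [off, config.sigma1 ** 2]])
    c2, c3 = np.linalg.solve(M, [a0, a1])
    quad = (c2 ** 2 * config.sigma0 ** 2 + c3 ** 2 * config.sigma1 ** 2
            + 2.0 * c2 * c3 * off)
    c4_sq = s * s - 1.0 - quad
    return float(s * zp), float(c2), float(c3), float(c4_sq)


def calibrate_assignment(config: ScenarioConfig, *, tol: float = 0.01,
                         s_max: float = 200.0) -> AssignmentCoefficients:
    """Solve for (c1..c4) hitting (p, r0, r1, violation_frac).

    (p, r0, r1) are matched exactly in closed form for any admissible latent
    scale s; the violation fraction is matched by a bracketed root-find on s.
    The result is deterministic.  Raises :class:`InfeasibleTargetsError`
    (reporting the best reachable value) when no s achieves the target.
    """
    # smallest s keeping c4^2 >= 0
    quad_share = 1.0 - _inner_solve(1.0, config)[3]  # quad/s^2 + 1/s^2 at s=1
    # c2, c3 scale linearly in s, so c4^2 = s^2 (1 - q) - 1 with q constant
    q = quad_share - 1.0  # quad coefficient per s^2
    if q >= 1.0:
        raise InfeasibleTargetsError(
            f"targets (r0={config.r0}, r1={config.r1}, p={config.p}) demand "
            f"more latent variance than the cluster effects provide (q={q:.3f})")
    s_min = math.sqrt(1.0 / (1.0 - q)) * (1.0 + 1e-12)

    def coeffs_at(s: float) -> AssignmentCoefficients:
        c1, c2, c3, c4_sq = _inner_solve(s, config)
        return AssignmentCoefficients(c1, c2, c3, math.sqrt(max(c4_sq, 0.0)))

    def resid(s: float) -> float:
        return expected_violation_fraction(coeffs_at(s), config) \
            - config.violation_frac

    lo, hi = resid(s_min), resid(s_max)
    if lo > 0.0:
        best = lo + config.violation_frac
        if lo <= tol:
            return coeffs_at(s_min)
        raise InfeasibleTargetsError(
            f"violation fraction target {config.violation_frac} is below the "
            f"minimum {best:.4f} reachable with these (r0, r1, p) targets")
    if hi < 0.0:
        best = hi + config.violation_frac
        raise InfeasibleTargetsError(
            f"violation fraction target {config.violation_frac} is above the "
            f"maximum {best:.4f} reachable within the search bounds")
    s_star = optimize.brentq(resid, s_min, s_max, xtol=1e-10, rtol=1e-12)
    return coeffs_at(s_star)


def generate_dataset(config: ScenarioConfig,
                     coeffs: AssignmentCoefficients | None = None,
                     seed=None) -> GeneratedDataset:
    """Draw one dataset; fully reproducible from ``seed``.

    Draw order: cluster sizes, cluster effects (b_k1, b_k0), cluster latent
    zeta_k, unit latent xi_ik, unit errors eps(1), eps(0).
    """
    if coeffs is None:
        coeffs = calibrate_assignment(config)
    rng = np.random.default_rng(seed)
    K = config.K
    n = rng.integers(config.nk_lo, config.nk_hi + 1, size=K)
    N = int(n.sum())
    off = config.rho * config.sigma1 * config.sigma0
    omega = np.array([[config.sigma1 ** 2, off], [off, config.sigma0 ** 2]])
    L = np.linalg.cholesky(omega)
    b = rng.standard_normal((K, 2)) @ L.T          # columns (b_k1, b_k0)
    zeta = rng.standard_normal(K)
    xi = rng.standard_normal(N)
    eps1 = config.sigma_eps * rng.standard_normal(N)
    eps0 = config.sigma_eps * rng.standard_normal(N)

    codes = np.repeat(np.arange(K), n)
    g = (coeffs.c1 + coeffs.c2 * b[codes, 1] + coeffs.c3 * b[codes, 0]
         + coeffs.c4 * zeta[codes] + xi)
    t = (g > 0).astype(np.int8)
    y1 = config.beta1 + b[codes, 0] + eps1
    y0 = config.beta0 + b[codes, 1] + eps0
    y = np.where(t == 1, y1, y0)

    width = len(str(K))
    labels = np.array([f"c{j:0{width}d}" for j in range(K)], dtype=object)
    dataset = ClusteredDataset(cluster_id=labels[codes], t=t, y=y)
    s = coeffs.latent_scale(config.sigma0, config.sigma1, config.rho)
    u = (coeffs.c1 + coeffs.c2 * b[:, 1] + coeffs.c3 * b[:, 0]
         + coeffs.c4 * zeta)
    cluster_truth = pd.DataFrame({
        "cluster_id": labels, "n": n,
        "b1": b[:, 0], "b0": b[:, 1],
        "pi": stats.norm.cdf(u),       # P(T=1 | cluster latents)
        "delta_k": config.delta + b[:, 0] - b[:, 1],
    })
    return GeneratedDataset(dataset=dataset, cluster_truth=cluster_truth,
                            y1=y1, y0=y0)


_SETTING1 = dict(K=150, nk_lo=1, nk_hi=19, beta0=35.0, beta1=40.0,
                 sigma0=8.0, sigma1=8.0, rho=0.8, sigma_eps=45.0,
                 r0=0.4, r1=0.4, p=0.3)
_SETTING2 = dict(K=200, nk_lo=1, nk_hi=49, beta0=12.0, beta1=15.0,
                 sigma0=8.0, sigma1=8.0, sigma_eps=35.0,
                 p=0.3, violation_frac=0.80)

#: Named scenario presets for the two study designs.
PRESETS: dict[str, ScenarioConfig] = {
    "setting1_26": ScenarioConfig(violation_frac=0.26, **_SETTING1),
    "setting1_80": ScenarioConfig(violation_frac=0.80, **_SETTING1),
    "setting2_r44": ScenarioConfig(rho=0.3, r0=0.4, r1=0.4, **_SETTING2),
    "setting2_r26": ScenarioConfig(rho=0.3, r0=0.2, r1=0.6, **_SETTING2),
    "setting2_r4m4": ScenarioConfig(rho=0.3, r0=0.4, r1=-0.4, **_SETTING2),
    "setting3_r4m4_rm3": ScenarioConfig(rho=-0.3, r0=0.4, r1=-0.4, **_SETTING2),
    "setting3_r4m4_rm8": ScenarioConfig(rho=-0.8, r0=0.4, r1=-0.4, **_SETTING2),
    "setting3_r6m6_rm8": ScenarioConfig(rho=-0.8, r0=0.6, r1=-0.6, **_SETTING2),
}
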