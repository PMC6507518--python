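"""Weighted maximum-likelihood estimation for two-arm random-coefficient models.

The model for unit i in cluster k is

    y_ik = x_ik' beta + t_ik * b_k1 + (1 - t_ik) * b_k0 + e_ik,

with (b_k1, b_k0) ~ N(0, Omega), Omega = [[s1^2, rho*s1*s0], [rho*s1*s0, s0^2]],
and e_ik ~ N(0, sigma_eps^2 / w_ik): unit weights act as residual precisions,
the convention of standard mixed-model software.  Cluster weights v_k enter as
multipliers of each cluster's marginal log-likelihood ("maximum
pseudo-likelihood").  The fixed-effect vector is profiled out by generalized
least squares at each variance-component value, and the four variance
parameters are optimized on an unconstrained scale
(log sigma0, log sigma1, atanh rho, log sigma_eps).

All per-cluster linear algebra is reduced to 2x2 operations through the
Woodbury identity on sufficient statistics, so one likelihood evaluation
costs O(K) after a single O(N) pass over the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import ClusteredDataset
from .weights import WeightSet

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "HLMFit",
    "TWO_ARM",
    "SATC",
    "RSATC",
    "weighted_loglik",
    "gls_fixed_effects",
    "fit_weighted_hlm",
    "unit_cluster_means",
    "shape_start",
]


def shape_start(vc: "VarianceComponents") -> np.ndarray:
    """Optimizer start vector (log s0/se, log s1/se, atanh rho) from a fit."""
    rho = min(max(vc.rho, -1.0 + 1e-12), 1.0 - 1e-12)
    x = np.array([
        0.5 * math.log(max(vc.sigma0_sq, 1e-300) / vc.sigma_eps_sq),
        0.5 * math.log(max(vc.sigma1_sq, 1e-300) / vc.sigma_eps_sq),
        math.atanh(rho)])
    return np.clip(x, -15.0, 15.0)

_LOG_2PI = math.log(2.0 * math.pi)
_RHO_EPS = 1e-12


def _clamp_rho(rho: float) -> float:
    """Keep the correlation strictly inside (-1, 1) at numerical boundaries."""
    return min(max(rho, -1.0 + _RHO_EPS), 1.0 - _RHO_EPS)


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect covariance (sigma1, sigma0, rho) and residual variance."""

    sigma0_sq: float
    sigma1_sq: float
    rho: float
    sigma_eps_sq: float

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0 or self.sigma1_sq < 0:
            raise ValueError("random-effect variances must be >= 0")
        if self.sigma_eps_sq <= 0:
            raise ValueError("residual variance must be > 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def sigma0(self) -> float:
        return math.sqrt(self.sigma0_sq)

    @property
    def sigma1(self) -> float:
        return math.sqrt(self.sigma1_sq)

    @property
    def sigma_eps(self) -> float:
        return math.sqrt(self.sigma_eps_sq)

    def omega(self) -> np.ndarray:
        """2x2 covariance of (b_k1, b_k0)."""
        off = self.rho * self.sigma1 * self.sigma0
        return np.array([[self.sigma1_sq, off], [off, self.sigma0_sq]])


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect design for the two-arm model family.

    The random design is always [t, 1 - t] onto (b_k1, b_k0).  Supported
    fixed designs:

    - ``two_arm``: [t, 1-t] -> (beta1, beta0)
    - ``satc``:    [t, 1-t, Tbar*t, Tbar*(1-t)] -> (beta1, beta0, gamma1, gamma0)
    - ``rsatc``:   [t, 1-t, Tbar] -> (beta1, beta0, gamma)
    """

    name: str
    param_names: tuple[str, ...]

    def build_design(self, t: np.ndarray, tbar: np.ndarray | None) -> np.ndarray:
        t = t.astype(float)
        if self.name == "two_arm":
            return np.column_stack([t, 1.0 - t])
        if tbar is None:
            raise ValueError(f"design '{self.name}' requires cluster treatment means")
        if self.name == "satc":
            return np.column_stack([t, 1.0 - t, tbar * t, tbar * (1.0 - t)])
        if self.name == "rsatc":
            return np.column_stack([t, 1.0 - t, tbar])
        raise ValueError(f"unknown design {self.name!r}")


TWO_ARM = ModelSpec("two_arm", ("beta1", "beta0"))
SATC = ModelSpec("satc", ("beta1", "beta0", "gamma1", "gamma0"))
RSATC = ModelSpec("rsatc", ("beta1", "beta0", "gamma"))

_SPECS = {s.name: s for s in (TWO_ARM, SATC, RSATC)}


def get_spec(name) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; expected one of {sorted(_SPECS)}")


@dataclass
class HLMFit:
    """Result of a weighted random-coefficient fit."""

    spec: str
    param_names: tuple[str, ...]
    beta: np.ndarray
    beta_cov: np.ndarray            # model-based GLS covariance
    vc: VarianceComponents
    cluster_id: np.ndarray          # labels, first-appearance order
    blups: np.ndarray               # (K, 2): predicted (b_k1, b_k0)
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.param_names.index(name)])

    def to_json(self) -> str:
        return json.dumps({
            "spec": self.spec,
            "beta": dict(zip(self.param_names, map(float, self.beta))),
            "vc": {"sigma0_sq": self.vc.sigma0_sq, "sigma1_sq": self.vc.sigma1_sq,
                   "rho": self.vc.rho, "sigma_eps_sq": self.vc.sigma_eps_sq},
            "loglik": self.loglik, "converged": self.converged,
            "boundary": self.boundary, "n_iter": self.n_iter,
        }, indent=2)


def unit_cluster_means(data: ClusteredDataset) -> np.ndarray:
    """Per-unit broadcast of the cluster's treated fraction Tbar_k."""
    codes, labels = data.cluster_codes()
    n = np.bincount(codes, minlength=len(labels))
    n1 = np.bincount(codes, weights=data.t, minlength=len(labels))
    return (n1 / n)[codes]


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

class _ClusterStats:
    """Per-cluster weighted cross-products; everything a likelihood needs."""

    def __init__(self, data: ClusteredDataset, weights: WeightSet,
                 spec: ModelSpec, X: np.ndarray | None = None,
                 check_identified: bool = False):
        codes, labels = data.cluster_codes()
        K = len(labels)
        t = data.t.astype(float)
        y = data.y
        w = weights.w
        if X is None:
            tbar = unit_cluster_means(data) if spec.name != "two_arm" else None
            X = spec.build_design(data.t, tbar)
        p = X.shape[1]
        self.labels = labels
        self.K, self.p = K, p
        self.v = np.asarray(weights.v, dtype=float)
        if self.v.shape[0] != K:
            raise ValueError("cluster weight vector length != number of clusters")
        self.nk = np.bincount(codes, minlength=K).astype(float)
        self.sumlogw = np.bincount(codes, weights=np.log(w), minlength=K)
        # Z'WZ diagonal (off-diagonal is zero: t*(1-t) = 0)
        self.g1 = np.bincount(codes, weights=w * t, minlength=K)
        self.g0 = np.bincount(codes, weights=w * (1.0 - t), minlength=K)
        wX = w[:, None] * X
        self.Szx = np.empty((K, 2, p))
        for j in range(p):
            self.Szx[:, 0, j] = np.bincount(codes, weights=wX[:, j] * t, minlength=K)
            self.Szx[:, 1, j] = np.bincount(codes, weights=wX[:, j] * (1.0 - t),
                                            minlength=K)
        self.Szy = np.column_stack([
            np.bincount(codes, weights=w * t * y, minlength=K),
            np.bincount(codes, weights=w * (1.0 - t) * y, minlength=K)])
        self.Sxx = np.empty((K, p, p))
        for i in range(p):
            for j in range(i, p):
                s = np.bincount(codes, weights=wX[:, i] * X[:, j], minlength=K)
                self.Sxx[:, i, j] = s
                self.Sxx[:, j, i] = s
        self.Sxy = np.empty((K, p))
        for j in range(p):
            self.Sxy[:, j] = np.bincount(codes, weights=wX[:, j] * y, minlength=K)
        self.Syy = np.bincount(codes, weights=w * y * y, minlength=K)
        self._SzxT = np.ascontiguousarray(self.Szx.transpose(0, 2, 1))
        self._const = float(self.v @ (self.nk * _LOG_2PI - self.sumlogw))
        if check_identified:
            self._check_identified(X, spec)

    def _check_identified(self, X: np.ndarray, spec: ModelSpec) -> None:
        total = (self.v[:, None, None] * self.Sxx).sum(axis=0)
        for j, name in enumerate(spec.param_names):
            if total[j, j] == 0.0:
                raise ValueError(
                    f"fixed-effect column '{name}' has no support in the data")
        if np.linalg.matrix_rank(total) < self.p:
            raise ValueError(
                f"collinear fixed-effect design for '{spec.name}': columns "
                f"{spec.param_names} are linearly dependent (e.g. all cluster "
                f"treatment means equal)")

    # -- Woodbury pieces --------------------------------------------------
    def _h_and_logdet(self, vc: VarianceComponents):
        """H_k = (I + Omega G_k)^-1 Omega and log det(I + Omega G_k) per cluster."""
        se2 = vc.sigma_eps_sq
        o11, o00 = vc.sigma1_sq, vc.sigma0_sq
        o10 = vc.rho * vc.sigma1 * vc.sigma0
        G1, G0 = self.g1 / se2, self.g0 / se2
        detO = o11 * o00 - o10 * o10
        detM = (1.0 + o11 * G1) * (1.0 + o00 * G0) - (o10 * o10) * G1 * G0
        H = np.empty((self.K, 2, 2))
        H[:, 0, 0] = (o11 + G0 * detO) / detM
        H[:, 0, 1] = o10 / detM
        H[:, 1, 0] = H[:, 0, 1]
        H[:, 1, 1] = (o00 + G1 * detO) / detM
        logdet = self.nk * math.log(se2) - self.sumlogw + np.log(detM)
        return H, logdet

    def quadratic_forms(self, vc: VarianceComponents):
        """Per-cluster X'V^-1X, X'V^-1y, y'V^-1y and log det V."""
        se2 = vc.sigma_eps_sq
        H, logdet = self._h_and_logdet(vc)
        Axx = self.Sxx / se2 - np.einsum("kai,kab,kbj->kij", self.Szx, H,
                                         self.Szx) / (se2 * se2)
        axy = self.Sxy / se2 - np.einsum("kai,kab,kb->ki", self.Szx, H,
                                         self.Szy) / (se2 * se2)
        qyy = self.Syy / se2 - np.einsum("ka,kab,kb->k", self.Szy, H,
                                         self.Szy) / (se2 * se2)
        return Axx, axy, qyy, logdet

    def gls(self, vc: VarianceComponents):
        """Profiled GLS fixed effects, their covariance, and the profile loglik."""
        Axx, axy, qyy, logdet = self.quadratic_forms(vc)
        bread = np.einsum("k,kij->ij", self.v, Axx)
        rhs = np.einsum("k,ki->i", self.v, axy)
        try:
            beta = np.linalg.solve(bread, rhs)
            cov = np.linalg.inv(bread)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular GLS information matrix") from exc
        quad = float(self.v @ qyy - beta @ rhs)
        ll = -0.5 * (float(self.v @ (self.nk * _LOG_2PI + logdet)) + quad)
        return beta, cov, ll

    def _profile_core(self, a: float, b: float, c: float):
        """Hot path: profile log-likelihood at shape parameters.

        (a, b, c) = (log sigma0/sigma_eps, log sigma1/sigma_eps, atanh rho):
        beta is profiled by GLS and sigma_eps^2 has the closed form
        quad / sum_k v_k n_k, since rescaling sigma_eps moves Omega and the
        residual variance together when the ratios are held fixed.
        Works on the sigma_eps = 1 scale throughout.
        """
        o00, o11 = math.exp(2.0 * a), math.exp(2.0 * b)
        rho = _clamp_rho(math.tanh(c))
        o10 = rho * math.sqrt(o11 * o00)
        G1, G0 = self.g1, self.g0
        detO = o11 * o00 - o10 * o10
        detM = (1.0 + o11 * G1) * (1.0 + o00 * G0) - (o10 * o10) * G1 * G0
        H = np.empty((self.K, 2, 2))
        H[:, 0, 0] = (o11 + G0 * detO) / detM
        H[:, 0, 1] = o10 / detM
        H[:, 1, 0] = H[:, 0, 1]
        H[:, 1, 1] = (o00 + G1 * detO) / detM
        hzx = H @ self.Szx                                     # (K, 2, p)
        Axx = self.Sxx - self._SzxT @ hzx
        hzy = (H @ self.Szy[:, :, None])[:, :, 0]              # (K, 2)
        axy = self.Sxy - (self.Szx * hzy[:, :, None]).sum(axis=1)
        qyy = self.Syy - (self.Szy * hzy).sum(axis=1)
        bread = np.tensordot(self.v, Axx, axes=1)
        rhs = self.v @ axy
        beta = np.linalg.solve(bread, rhs)
        quad = float(self.v @ qyy - beta @ rhs)
        nv = float(self.v @ self.nk)
        if quad <= 0.0 or not np.isfinite(quad):
            raise FloatingPointError("degenerate residual quadratic form")
        se2 = quad / nv
        ll = -0.5 * (self._const
                     + float(self.v @ np.log(detM))
                     + nv * math.log(se2) + nv)
        return ll, beta, se2, bread

    def profiled3(self, a: float, b: float, c: float):
        """Profile fit at shape parameters; returns (beta, cov, ll, vc)."""
        ll, beta, se2, bread = self._profile_core(a, b, c)
        vc = VarianceComponents(sigma0_sq=math.exp(2.0 * a) * se2,
                                sigma1_sq=math.exp(2.0 * b) * se2,
                                rho=_clamp_rho(math.tanh(c)),
                                sigma_eps_sq=se2)
        return beta, se2 * np.linalg.inv(bread), ll, vc

    def loglik_at(self, vc: VarianceComponents, beta: np.ndarray) -> float:
        Axx, axy, qyy, logdet = self.quadratic_forms(vc)
        quad = (self.v * (qyy - 2.0 * axy @ beta
                          + np.einsum("kij,i,j->k", Axx, beta, beta))).sum()
        return -0.5 * (float(self.v @ (self.nk * _LOG_2PI + logdet)) + float(quad))

    def blups(self, vc: VarianceComponents, beta: np.ndarray) -> np.ndarray:
        """Predicted random effects b_hat_k = Omega Z'V^-1 (y - X beta)."""
        se2 = vc.sigma_eps_sq
        H, _ = self._h_and_logdet(vc)
        q = (self.Szy - self.Szx @ beta) / se2          # (K, 2) = Z'P r
        Hq = np.einsum("kab,kb->ka", H, q)
        Gq = np.column_stack([self.g1 / se2 * Hq[:, 0], self.g0 / se2 * Hq[:, 1]])
        return (q - Gq) @ vc.omega().T


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def weighted_loglik(data: ClusteredDataset, weights: WeightSet,
                    spec: ModelSpec | str, beta: np.ndarray,
                    vc: VarianceComponents) -> float:
    """Weighted marginal log-likelihood at given fixed effects and components.

    Returns sum_k v_k * (-1/2) [n_k log 2pi + log det V_k + r_k' V_k^-1 r_k]
    with V_k = Z_k Omega Z_k' + sigma_eps^2 diag(1/w_ik), r_k = y_k - X_k beta.
    """
    spec = get_spec(spec)
    stats = _ClusterStats(data, weights, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != len(spec.param_names):
        raise ValueError(f"beta has length {beta.shape[0]}; design "
                         f"'{spec.name}' expects {len(spec.param_names)}")
    return stats.loglik_at(vc, beta)


def gls_fixed_effects(data: ClusteredDataset, weights: WeightSet,
                      spec: ModelSpec | str, vc: VarianceComponents):
    """GLS fixed effects at fixed variance components, with model covariance."""
    spec = get_spec(spec)
    stats = _ClusterStats(data, weights, spec)
    beta, cov, _ = stats.gls(vc)
    return beta, cov


def _moment_start(data: ClusteredDataset, spec: ModelSpec) -> np.ndarray:
    """Deterministic variance-component start values from simple moments."""
    codes, labels = data.cluster_codes()
    K = len(labels)
    t = data.t.astype(int)
    y = data.y
    # pooled within-(cluster, arm) variance for sigma_eps^2
    group = codes * 2 + t
    cnt = np.bincount(group, minlength=2 * K)
    s = np.bincount(group, weights=y, minlength=2 * K)
    ss = np.bincount(group, weights=y * y, minlength=2 * K)
    dof = np.maximum(cnt - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = ss - s * s / np.where(cnt > 0, cnt, 1)
    se2 = within[dof > 0].sum() / max(dof.sum(), 1) if dof.sum() > 0 else np.var(y)
    se2 = max(float(se2), 1e-8, 1e-6 * float(np.var(y) + 1.0))

    def arm_var(arm):
        mask = cnt[arm::2] > 0
        if mask.sum() < 2:
            return 0.1 * se2
        means = s[arm::2][mask] / cnt[arm::2][mask]
        v = float(np.var(means, ddof=1)) - se2 * float(np.mean(1.0 / cnt[arm::2][mask]))
        return max(v, 0.05 * se2)

    s0_sq, s1_sq = arm_var(0), arm_var(1)
    # correlation start from clusters observed in both arms
    both = (cnt[0::2] > 0) & (cnt[1::2] > 0)
    rho0 = 0.0
    if both.sum() >= 10:
        m0 = s[0::2][both] / cnt[0::2][both]
        m1 = s[1::2][both] / cnt[1::2][both]
        r = np.corrcoef(m1, m0)[0, 1]
        if np.isfinite(r):
            rho0 = float(np.clip(r, -0.8, 0.8))
    return np.array([0.5 * math.log(s0_sq), 0.5 * math.log(s1_sq),
                     math.atanh(rho0), 0.5 * math.log(se2)])


_XCAP = 20.0  # |transformed parameter| beyond this is treated as a boundary


def fit_weighted_hlm(data: ClusteredDataset, weights: WeightSet,
                     spec: ModelSpec | str = TWO_ARM, *,
                     start: np.ndarray | None = None,
                     tol: float = 1e-8, max_iter: int = 2000) -> HLMFit:
    """Maximize the weighted marginal likelihood over (beta, variance components).

    beta is profiled out by GLS and sigma_eps^2 has a closed profile form, so
    Nelder-Mead searches only the three shape parameters
    (log sigma0/sigma_eps, log sigma1/sigma_eps, atanh rho), unconstrained,
    from a deterministic moment-based start.  ``start``, if given, is a
    3-vector on that scale.
    """
    spec = get_spec(spec)
    stats = _ClusterStats(data, weights, spec, check_identified=True)
    if start is not None:
        x0 = np.asarray(start, dtype=float)
    else:
        m = _moment_start(data, spec)       # (log s0, log s1, atanh rho, log se)
        x0 = np.array([m[0] - m[3], m[1] - m[3], m[2]])

    def negll(x: np.ndarray) -> float:
        x = np.clip(x, -_XCAP, _XCAP)
        try:
            ll = stats._profile_core(x[0], x[1], x[2])[0]
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options=dict(xatol=1e-5, fatol=tol, maxiter=max_iter,
                     maxfev=2 * max_iter, adaptive=False))
    x = np.clip(res.x, -_XCAP, _XCAP)
    beta, cov, ll, vc = stats.profiled3(*x)
    boundary = bool(np.max(np.abs(x)) >= _XCAP - 1e-9)
    return HLMFit(
        spec=spec.name, param_names=spec.param_names, beta=beta, beta_cov=cov,
        vc=vc, cluster_id=stats.labels, blups=stats.blups(vc, beta),
        loglik=float(ll), converged=bool(res.success) or boundary,
        boundary=boundary, n_iter=int(res.nit))
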