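"""Standard errors: cluster-robust sandwich covariance and cluster bootstrap.

The sandwich estimator targets the IPT-weighted two-arm fit: with
W_k = V_k^-1 evaluated at the fitted variance components (V_k the cluster's
marginal covariance including the 1/w residual precisions),

    cov(beta_hat) = bread^-1 . meat . bread^-1,
    bread = sum_k v_k X_k' W_k X_k,
    meat  = sum_k v_k^2 (X_k' W_k r_k)(X_k' W_k r_k)',

i.e. the meat is blocked by cluster, the standard robust form for clustered
scores.  For the augmented estimators, whose weights depend on an estimated
outcome model, standard errors come from a nonparametric cluster bootstrap
that reruns the full pipeline on each resample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import ClusteredDataset
from .hlm import HLMFit, _ClusterStats, get_spec
from .weights import WeightSet

__all__ = [
    "CovarianceEstimate",
    "robust_sandwich",
    "cluster_bootstrap",
    "confidence_interval",
]


@dataclass(frozen=True)
class CovarianceEstimate:
    """2x2 covariance of (beta0_hat, beta1_hat) and derived standard errors."""

    cov: np.ndarray                 # ordered (beta0, beta1)
    method: str                     # "sandwich" or "cluster_bootstrap"
    B: int | None = None            # bootstrap replicates, if applicable

    @property
    def se_beta0(self) -> float:
        return math.sqrt(max(self.cov[0, 0], 0.0))

    @property
    def se_beta1(self) -> float:
        return math.sqrt(max(self.cov[1, 1], 0.0))

    @property
    def se_delta(self) -> float:
        v = self.cov[0, 0] + self.cov[1, 1] - 2.0 * self.cov[0, 1]
        return math.sqrt(max(v, 0.0))


def robust_sandwich(data: ClusteredDataset, weights: WeightSet,
                    fit: HLMFit) -> CovarianceEstimate:
    """Cluster-robust covariance of the two-arm weighted fixed effects."""
    if fit.spec != "two_arm":
        raise ValueError("the sandwich covariance is defined for the two-arm fit")
    stats = _ClusterStats(data, weights, get_spec(fit.spec))
    Axx, axy, _, _ = stats.quadratic_forms(fit.vc)
    bread = np.einsum("k,kij->ij", stats.v, Axx)
    score = axy - np.einsum("kij,j->ki", Axx, fit.beta)   # X' V^-1 r per cluster
    meat = np.einsum("k,ki,kj->ij", stats.v ** 2, score, score)
    binv = np.linalg.inv(bread)
    cov = binv @ meat @ binv
    # design order is (beta1, beta0); report as (beta0, beta1)
    perm = np.array([[0.0, 1.0], [1.0, 0.0]])
    return CovarianceEstimate(cov=perm @ cov @ perm, method="sandwich")


def cluster_bootstrap(data: ClusteredDataset, estimator, B: int = 30,
                      seed=None, max_redraws: int = 50) -> CovarianceEstimate:
    """Covariance of (beta0_hat, beta1_hat) over B cluster resamples.

    Clusters are resampled with replacement (each draw gets a fresh label so
    repeated clusters stay distinct) and ``estimator`` — any callable mapping
    a dataset to a :class:`~aiptw.estimators.CausalEstimate` — is rerun from
    scratch on each resample.  A resample with no treatment variation at all
    is redrawn; more than ``max_redraws`` consecutive redraws is an error.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    codes, labels = data.cluster_codes()
    K = len(labels)
    rows_of = [np.flatnonzero(codes == j) for j in range(K)]
    n1_of = np.bincount(codes, weights=data.t, minlength=K)
    n_of = np.bincount(codes, minlength=K)
    ests = np.empty((B, 2))
    for b in range(B):
        for attempt in range(max_redraws + 1):
            draw = rng.integers(0, K, size=K)
            N1 = n1_of[draw].sum()
            if 0 < N1 < n_of[draw].sum():
                break
        else:
            raise RuntimeError(
                f"exceeded {max_redraws} consecutive redraws: resamples keep "
                "lacking treatment variation")
        idx = np.concatenate([rows_of[j] for j in draw])
        new_labels = np.concatenate(
            [np.full(len(rows_of[j]), f"bs{i}", dtype=object)
             for i, j in enumerate(draw)])
        resample = ClusteredDataset(
            cluster_id=new_labels, t=data.t[idx], y=data.y[idx],
            is_pseudo=data.is_pseudo[idx])
        est = estimator(resample)
        ests[b] = (est.beta0_hat, est.beta1_hat)
    cov = np.cov(ests, rowvar=False, ddof=1)
    return CovarianceEstimate(cov=np.atleast_2d(cov), method="cluster_bootstrap", B=B)


def confidence_interval(estimate: float, se: float,
                        level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile interval estimate +/- z_(1+level)/2 * se."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if se < 0:
        raise ValueError("standard error must be >= 0")
    z = sps.norm.ppf(0.5 * (1.0 + level))
    return (estimate - z * se, estimate + z * se)
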