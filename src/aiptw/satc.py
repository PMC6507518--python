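"""Cluster-mean-corrected outcome models and missing-arm predictions.

When treatment assignment depends on the cluster random effects, adding the
cluster's treated fraction Tbar_k as a covariate (a Mundlak-style device)
absorbs that dependence and restores consistent fixed-effect estimation by
ordinary maximum likelihood.  Two variants are fit:

- SATC ("school-average-T corrected"): separate cluster-mean slopes per arm,
    y = (beta1'' + b_k1'' + gamma1 Tbar_k) t + (beta0'' + b_k0'' + gamma0 Tbar_k)(1-t) + e
- RSATC (reduced SATC): a single shared slope gamma.

Either fit supplies the predicted missing-arm potential outcome for a cluster
observed in only one arm.  Because the random-effect prediction for an arm
with no observations shrinks to zero, those predictions use the fixed part
only: e.g. a cluster with no treated units (Tbar = 0) gets
E[Y(1)|k] = beta1'' under SATC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ALL_CONTROL, MIXED, ClusteredDataset, ClusterSummary
from .hlm import RSATC, SATC, HLMFit, fit_weighted_hlm
from .weights import WeightSet

__all__ = [
    "ClusterMeans",
    "SATCFit",
    "RSATCFit",
    "cluster_treatment_means",
    "fit_satc",
    "fit_rsatc",
    "predict_missing_arm",
]


@dataclass(frozen=True)
class ClusterMeans:
    """Per-cluster treated fractions Tbar_k and their unweighted grand mean."""

    cluster_id: np.ndarray
    tbar: np.ndarray

    @property
    def grand_mean(self) -> float:
        return float(self.tbar.mean())

    def tbar_for(self, label) -> float:
        idx = np.flatnonzero(self.cluster_id == label)
        if idx.size == 0:
            raise KeyError(label)
        return float(self.tbar[idx[0]])


def cluster_treatment_means(data: ClusteredDataset) -> ClusterMeans:
    """Exact treated fraction per cluster, first-appearance order."""
    codes, labels = data.cluster_codes()
    n = np.bincount(codes, minlength=len(labels))
    n1 = np.bincount(codes, weights=data.t, minlength=len(labels))
    return ClusterMeans(cluster_id=labels, tbar=n1 / n)


class SATCFit:
    """SATC maximum-likelihood fit; thin view over the underlying HLM fit."""

    model = "satc"

    def __init__(self, fit: HLMFit):
        self.fit = fit

    @property
    def beta_ddot1(self) -> float:
        return self.fit["beta1"]

    @property
    def beta_ddot0(self) -> float:
        return self.fit["beta0"]

    @property
    def gamma1(self) -> float:
        return self.fit["gamma1"]

    @property
    def gamma0(self) -> float:
        return self.fit["gamma0"]

    @property
    def vc(self):
        return self.fit.vc

    @property
    def blups(self) -> np.ndarray:
        return self.fit.blups

    @property
    def loglik(self) -> float:
        return self.fit.loglik


class RSATCFit:
    """RSATC maximum-likelihood fit (single shared cluster-mean slope)."""

    model = "rsatc"

    def __init__(self, fit: HLMFit):
        self.fit = fit

    @property
    def beta_dot1(self) -> float:
        return self.fit["beta1"]

    @property
    def beta_dot0(self) -> float:
        return self.fit["beta0"]

    @property
    def gamma(self) -> float:
        return self.fit["gamma"]

    @property
    def vc(self):
        return self.fit.vc

    @property
    def blups(self) -> np.ndarray:
        return self.fit.blups

    @property
    def loglik(self) -> float:
        return self.fit.loglik


def _unit_weights(data: ClusteredDataset) -> WeightSet:
    K = len(set(data.cluster_id.tolist()))
    return WeightSet(w=np.ones(data.n_units), v=np.ones(K),
                     estimand="unweighted", c=float("nan"))


def fit_satc(data: ClusteredDataset, **options) -> SATCFit:
    """Unweighted ML fit of the SATC design (requires >= 2 distinct Tbar_k)."""
    return SATCFit(fit_weighted_hlm(data, _unit_weights(data), SATC, **options))


def fit_rsatc(data: ClusteredDataset, **options) -> RSATCFit:
    """Unweighted ML fit of the RSATC design."""
    return RSATCFit(fit_weighted_hlm(data, _unit_weights(data), RSATC, **options))


def predict_missing_arm(fit: SATCFit | RSATCFit, summary: ClusterSummary,
                        means: ClusterMeans | None = None) -> float:
    """Predicted potential outcome for the arm a violating cluster never shows.

    Uses the fixed part of the corrected model only (the missing arm's
    random-effect prediction is zero by shrinkage): for an all-control
    cluster Tbar = 0 and the treated-arm mean is predicted; for an
    all-treated cluster Tbar = 1 and the control-arm mean is predicted.
    """
    if summary.status == MIXED:
        raise ValueError(
            f"cluster {summary.cluster_id!r} has both arms observed; "
            "missing-arm prediction is only defined for violating clusters")
    if isinstance(fit, SATCFit):
        if summary.status == ALL_CONTROL:      # Tbar = 0, predict arm 1
            return fit.beta_ddot1
        return fit.beta_ddot0 + fit.gamma0     # Tbar = 1, predict arm 0
    if isinstance(fit, RSATCFit):
        if summary.status == ALL_CONTROL:
            return fit.beta_dot1
        return fit.beta_dot0 + fit.gamma
    raise TypeError(f"expected SATCFit or RSATCFit, got {type(fit).__name__}")
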