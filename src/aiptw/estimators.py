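"""Causal estimators for clustered data under practical positivity violation.

Four estimators of the average causal effect Delta = beta1 - beta0:

- ``iptw_orig``: weighted random-coefficient fit on the full sample with
  within-cluster inverse-probability weights.
- ``iptw_trim``: the same after discarding every cluster without treatment
  variation (changes the target population).
- ``aiptw`` (SATC or RSATC flavor): augments every violating cluster with one
  pseudo-unit carrying the predicted missing-arm potential outcome, then
  refits the weighted model on the augmented data.
- ``aiptw_nonparametric``: the cluster-average contrast that replaces a
  missing arm mean by its model prediction.

The augmentation recomputes propensities and the normalization constant on
the augmented sample, treating pseudo-rows as observed; an augmented cluster
therefore has propensity strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (ALL_TREATED, MIXED, ClusteredDataset,
                   summarize_clusters)
from .hlm import TWO_ARM, HLMFit, fit_weighted_hlm
from .satc import (RSATCFit, SATCFit, cluster_treatment_means, fit_rsatc,
                   fit_satc, predict_missing_arm)
from .weights import (STUDENT_POPULATION, WeightSet, compute_unit_weights,
                      estimate_propensity)

__all__ = [
    "AugmentedDataset",
    "CausalEstimate",
    "trim",
    "iptw_orig",
    "iptw_trim",
    "build_augmented_data",
    "aiptw",
    "aiptw_nonparametric",
    "METHODS",
]

METHODS = ("iptw_orig", "iptw_trim", "aiptw_satc", "aiptw_rsatc",
           "aiptw_nonparametric")


@dataclass
class CausalEstimate:
    """Point estimates of the arm means and their contrast."""

    method: str
    beta0_hat: float
    beta1_hat: float
    vc_hat: object | None
    n_clusters_used: int
    n_violating: int
    fit: HLMFit | None = None
    weights: WeightSet | None = None
    data_used: ClusteredDataset | None = None
    correction_vc: object | None = None   # correction-model components (AIPTW)
    _delta: float | None = None      # set only by estimators of the contrast alone

    @property
    def delta_hat(self) -> float:
        if self._delta is not None:
            return self._delta
        return self.beta1_hat - self.beta0_hat


@dataclass
class AugmentedDataset:
    """A dataset with one pseudo-row per violating cluster, plus provenance."""

    dataset: ClusteredDataset
    correction_fit: SATCFit | RSATCFit | None
    predictions: dict            # cluster label -> predicted missing-arm outcome
    n_violating: int


def trim(data: ClusteredDataset) -> ClusteredDataset:
    """Retain only clusters with both arms observed."""
    summaries = summarize_clusters(data)
    mixed = {s.cluster_id for s in summaries if s.status == MIXED}
    if not mixed:
        raise ValueError("trimming removed every cluster: no cluster has "
                         "both treated and control units")
    keep = np.array([cid in mixed for cid in data.cluster_id])
    if keep.all():
        return data
    return ClusteredDataset(
        cluster_id=data.cluster_id[keep], t=data.t[keep], y=data.y[keep],
        is_pseudo=data.is_pseudo[keep],
        unit_weight=None if data.unit_weight is None else data.unit_weight[keep])


def _weighted_two_arm(data: ClusteredDataset, estimand: str, method: str,
                      n_violating: int, **options) -> CausalEstimate:
    summaries = summarize_clusters(data)
    prop = estimate_propensity(summaries)
    weights = compute_unit_weights(data, prop, estimand)
    fit = fit_weighted_hlm(data, weights, TWO_ARM, **options)
    return CausalEstimate(
        method=method, beta0_hat=fit["beta0"], beta1_hat=fit["beta1"],
        vc_hat=fit.vc, n_clusters_used=len(summaries),
        n_violating=n_violating, fit=fit, weights=weights, data_used=data)


def iptw_orig(data: ClusteredDataset, estimand: str = STUDENT_POPULATION,
              **options) -> CausalEstimate:
    """IPT-weighted random-coefficient fit on the original sample."""
    n_viol = sum(s.violates for s in summarize_clusters(data))
    return _weighted_two_arm(data, estimand, "iptw_orig", n_viol, **options)


def iptw_trim(data: ClusteredDataset, estimand: str = STUDENT_POPULATION,
              **options) -> CausalEstimate:
    """IPTW after discarding clusters without treatment variation.

    Propensities and the normalization constant are recomputed on the
    trimmed sample, which is the sample this estimator targets.
    """
    n_viol = sum(s.violates for s in summarize_clusters(data))
    est = _weighted_two_arm(trim(data), estimand, "iptw_trim", n_viol, **options)
    return est


def _fit_correction(data: ClusteredDataset, model: str, **options):
    if model == "satc":
        return fit_satc(data, **options)
    if model == "rsatc":
        return fit_rsatc(data, **options)
    raise ValueError(f"unknown correction model {model!r}; expected 'satc' or 'rsatc'")


def build_augmented_data(data: ClusteredDataset, model: str = "satc",
                         **options) -> AugmentedDataset:
    """Append one predicted-outcome pseudo-row to every violating cluster.

    The correction model is always fit on the original (unweighted,
    unaugmented) data.  With no violating cluster the input is returned
    unchanged and no correction model is fit.
    """
    summaries = summarize_clusters(data)
    violating = [s for s in summaries if s.violates]
    if not violating:
        return AugmentedDataset(dataset=data, correction_fit=None,
                                predictions={}, n_violating=0)
    cfit = _fit_correction(data, model, **options)
    means = cluster_treatment_means(data)
    predictions = {s.cluster_id: predict_missing_arm(cfit, s, means)
                   for s in violating}
    extra_id = np.array([s.cluster_id for s in violating], dtype=object)
    extra_t = np.array([0 if s.status == ALL_TREATED else 1 for s in violating],
                       dtype=np.int8)
    extra_y = np.array([predictions[s.cluster_id] for s in violating])
    augmented = ClusteredDataset(
        cluster_id=np.concatenate([data.cluster_id, extra_id]),
        t=np.concatenate([data.t, extra_t]),
        y=np.concatenate([data.y, extra_y]),
        is_pseudo=np.concatenate([data.is_pseudo,
                                  np.ones(len(violating), dtype=bool)]))
    return AugmentedDataset(dataset=augmented, correction_fit=cfit,
                            predictions=predictions, n_violating=len(violating))


def aiptw(data: ClusteredDataset, model: str = "satc",
          estimand: str = STUDENT_POPULATION,
          correction_options: dict | None = None, **options) -> CausalEstimate:
    """Augmented IPTW: weighted two-arm fit on the augmented dataset.

    Weights are recomputed on the augmented sample (pseudo-rows counted as
    observed), so every cluster has propensity in (0, 1).  Cluster weights
    for the school-population estimand use the observed cluster sizes, not
    the augmented ones.  ``correction_options`` go to the correction-model
    fit; ``options`` go to the weighted two-arm fit.
    """
    aug = build_augmented_data(data, model, **(correction_options or {}))
    est = _weighted_two_arm(aug.dataset, estimand, f"aiptw_{model}",
                            aug.n_violating, **options)
    if estimand != STUDENT_POPULATION and aug.n_violating:
        # v_k from observed n_k: recompute on the pre-augmentation sample
        prop = estimate_propensity(summarize_clusters(aug.dataset))
        w = compute_unit_weights(aug.dataset, prop, STUDENT_POPULATION).w
        from .weights import cluster_weights
        v = cluster_weights(summarize_clusters(data), estimand)
        weights = WeightSet(w=w, v=v, estimand=estimand, c=prop.c)
        fit = fit_weighted_hlm(aug.dataset, weights, TWO_ARM, **options)
        est = CausalEstimate(
            method=f"aiptw_{model}", beta0_hat=fit["beta0"],
            beta1_hat=fit["beta1"], vc_hat=fit.vc,
            n_clusters_used=len(set(aug.dataset.cluster_id.tolist())),
            n_violating=aug.n_violating, fit=fit, weights=weights,
            data_used=aug.dataset)
    if aug.correction_fit is not None:
        est.correction_vc = aug.correction_fit.vc
    return est


def aiptw_nonparametric(data: ClusteredDataset, model: str = "satc",
                        estimand: str = STUDENT_POPULATION,
                        predictions: dict | None = None,
                        **options) -> CausalEstimate:
    """Cluster-average contrast with model predictions filling missing arms.

    Delta_hat = (1/K) sum_k v_k * d_k where d_k is the within-cluster
    difference of arm means for a mixed cluster, the treated mean minus the
    predicted control mean for an all-treated cluster, and the predicted
    treated mean minus the control mean for an all-control cluster.
    Only the contrast is defined; the arm levels are NaN.  ``predictions``
    may supply precomputed missing-arm values (cluster label -> value),
    bypassing the correction-model fit.
    """
    from .weights import cluster_weights

    summaries = summarize_clusters(data)
    violating = [s for s in summaries if s.violates]
    if violating and predictions is None:
        cfit = _fit_correction(data, model, **options)
        means = cluster_treatment_means(data)
        predictions = {s.cluster_id: predict_missing_arm(cfit, s, means)
                       for s in violating}
    elif predictions is None:
        predictions = {}
    codes, labels = data.cluster_codes()
    t = data.t.astype(float)
    sum1 = np.bincount(codes, weights=t * data.y, minlength=len(labels))
    n1 = np.bincount(codes, weights=t, minlength=len(labels))
    sum0 = np.bincount(codes, weights=(1 - t) * data.y, minlength=len(labels))
    n0 = np.bincount(codes, weights=1 - t, minlength=len(labels))
    d = np.empty(len(labels))
    for j, lab in enumerate(labels):
        if n1[j] > 0 and n0[j] > 0:
            d[j] = sum1[j] / n1[j] - sum0[j] / n0[j]
        elif n0[j] == 0:     # all treated: observed treated mean - predicted control
            d[j] = sum1[j] / n1[j] - predictions[lab]
        else:                # all control: predicted treated - observed control mean
            d[j] = predictions[lab] - sum0[j] / n0[j]
    v = cluster_weights(summaries, estimand)
    delta = float((v * d).mean())
    return CausalEstimate(
        method="aiptw_nonparametric", beta0_hat=float("nan"),
        beta1_hat=float("nan"), vc_hat=None, n_clusters_used=len(labels),
        n_violating=len(violating), _delta=delta)
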