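"""Within-cluster propensity estimation and inverse-probability weights.

Treatment assignment is assumed random within cluster, so the propensity in
cluster k is estimated by the empirical proportion pi_k = n_k1 / n_k.  Unit
weights

    w_ik = t * c / pi_k + (1 - t) * (1 - c) / (1 - pi_k)

use the normalization constant c = N1 / N (overall treated fraction), which
makes the weights sum to n_k within every cluster that has both arms.  In a
cluster without treatment variation the formula is evaluated at pi in {0, 1}
for the arm actually observed, giving w = 1 - c (all-control) or w = c
(all-treated).

Cluster-level weights v_k encode the estimand: v_k = 1 targets the unit
(student) population; v_k = N / (n_k K) weights every cluster equally
(school population).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .data import ClusteredDataset, ClusterSummary, summarize_clusters

__all__ = [
    "PropensityTable",
    "WeightSet",
    "NoTreatmentVariationError",
    "estimate_propensity",
    "compute_unit_weights",
    "cluster_weights",
    "STUDENT_POPULATION",
    "SCHOOL_POPULATION",
]

STUDENT_POPULATION = "student_population"
SCHOOL_POPULATION = "school_population"


class NoTreatmentVariationError(ValueError):
    """The sample contains no treated units or no control units at all."""


@dataclass(frozen=True)
class PropensityTable:
    """Per-cluster empirical propensities plus the global normalization constant."""

    cluster_id: np.ndarray           # labels, first-appearance order
    pi_hat: np.ndarray               # n_k1 / n_k per cluster
    violates: np.ndarray             # pi_hat in {0, 1}
    c: float                         # N1 / N
    N1: int
    N: int

    def pi_for(self, label) -> float:
        idx = np.flatnonzero(self.cluster_id == label)
        if idx.size == 0:
            raise KeyError(label)
        return float(self.pi_hat[idx[0]])

    @property
    def n_violating(self) -> int:
        return int(self.violates.sum())


@dataclass(frozen=True)
class WeightSet:
    """Unit-level IPT weights (aligned with dataset rows) and cluster weights."""

    w: np.ndarray                    # one per unit, positive
    v: np.ndarray                    # one per cluster, first-appearance order
    estimand: str
    c: float


def estimate_propensity(summaries: list[ClusterSummary]) -> PropensityTable:
    """Empirical within-cluster propensities pi_k = n_k1/n_k and c = N1/N."""
    if not summaries:
        raise ValueError("no cluster summaries supplied")
    n = np.array([s.n for s in summaries], dtype=int)
    n1 = np.array([s.n1 for s in summaries], dtype=int)
    N, N1 = int(n.sum()), int(n1.sum())
    if N1 == 0 or N1 == N:
        raise NoTreatmentVariationError(
            "no treatment variation anywhere in the sample: "
            f"N1={N1}, N={N}; no weighted estimator is identified")
    pi = n1 / n
    return PropensityTable(
        cluster_id=np.array([s.cluster_id for s in summaries], dtype=object),
        pi_hat=pi, violates=(n1 == 0) | (n1 == n),
        c=N1 / N, N1=N1, N=N)


def compute_unit_weights(data: ClusteredDataset, prop: PropensityTable,
                         estimand: str = STUDENT_POPULATION) -> WeightSet:
    """IPT weights per unit; clusters without variation get the formula's limit."""
    codes, labels = data.cluster_codes()
    order = {lab: i for i, lab in enumerate(prop.cluster_id)}
    try:
        remap = np.array([order[lab] for lab in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"no propensity available for cluster {exc}") from exc
    pi = prop.pi_hat[remap][codes]
    t = data.t.astype(float)
    c = prop.c
    w = np.empty(data.n_units, dtype=float)
    treated = data.t == 1
    # the pi in {0,1} cases only ever pair t=1 with pi=1 and t=0 with pi=0
    with np.errstate(divide="ignore", invalid="ignore"):
        w[treated] = c / pi[treated]
        w[~treated] = (1.0 - c) / (1.0 - pi[~treated])
    if not np.isfinite(w).all():
        raise ValueError("weight formula produced a division by zero: "
                         "a unit's observed arm has estimated propensity 0")
    summaries = summarize_clusters(data)
    v = cluster_weights(summaries, estimand)
    return WeightSet(w=w, v=v, estimand=estimand, c=c)


def cluster_weights(summaries: list[ClusterSummary], estimand: str) -> np.ndarray:
    """Cluster weights v_k = omega_k N / (n_k K) for the chosen estimand."""
    K = len(summaries)
    n = np.array([s.n for s in summaries], dtype=float)
    N = n.sum()
    if estimand == STUDENT_POPULATION:
        # omega_k = n_k K / N  =>  v_k = 1
        return np.ones(K)
    if estimand == SCHOOL_POPULATION:
        # omega_k = 1  =>  v_k = N / (n_k K)
        return N / (n * K)
    raise ValueError(f"unknown estimand {estimand!r}; expected "
                     f"{STUDENT_POPULATION!r} or {SCHOOL_POPULATION!r}")


def exact_propensity(summary: ClusterSummary) -> Fraction:
    """pi_k as an exact rational, for callers that need exact arithmetic."""
    return Fraction(summary.n1, summary.n)
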