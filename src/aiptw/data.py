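"""Clustered data representation, cluster summaries, validation and CSV I/O.

The central container is :class:`ClusteredDataset`: long-format data with one
row per unit carrying a cluster label, a binary treatment indicator ``t`` and
a continuous outcome ``y``.  Rows appended during score-function augmentation
are marked with ``is_pseudo=True``; freshly loaded or generated data carry
only observed rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDataset",
    "ClusterSummary",
    "DataValidationError",
    "load_dataset",
    "summarize_clusters",
    "write_dataset",
]

MIXED = "mixed"
ALL_TREATED = "all_treated"
ALL_CONTROL = "all_control"


class DataValidationError(ValueError):
    """Raised when input data violate the clustered-data contract."""


@dataclass
class ClusteredDataset:
    """Long-format clustered data: one row per unit.

    Parameters
    ----------
    cluster_id : array of str
        Opaque cluster labels, one per unit.  No ordering is assumed.
    t : array of int
        Treatment indicator in {0, 1}.
    y : array of float
        Continuous outcome.
    is_pseudo : array of bool, optional
        Marks augmentation rows; all-False for observed data.
    unit_weight : array of float or None
        Inverse-probability weights; ``None`` until computed.
    """

    cluster_id: np.ndarray
    t: np.ndarray
    y: np.ndarray
    is_pseudo: np.ndarray = field(default=None)  # type: ignore[assignment]
    unit_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=object).ravel()
        self.t = np.asarray(self.t).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.is_pseudo is None:
            self.is_pseudo = np.zeros(self.y.shape[0], dtype=bool)
        else:
            self.is_pseudo = np.asarray(self.is_pseudo, dtype=bool).ravel()
        if self.unit_weight is not None:
            self.unit_weight = np.asarray(self.unit_weight, dtype=float).ravel()
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n = self.y.shape[0]
        if n == 0:
            raise DataValidationError("dataset has no rows")
        for name, arr in (("cluster_id", self.cluster_id), ("t", self.t),
                          ("is_pseudo", self.is_pseudo)):
            if arr.shape[0] != n:
                raise DataValidationError(f"column '{name}' length {arr.shape[0]} != {n}")
        if self.unit_weight is not None and self.unit_weight.shape[0] != n:
            raise DataValidationError("unit_weight length mismatch")
        bad = ~np.isfinite(self.y)
        if bad.any():
            raise DataValidationError(
                f"non-finite outcome y at row index {int(np.flatnonzero(bad)[0])}")
        tvals = np.unique(self.t)
        if not np.isin(tvals, [0, 1]).all():
            raise DataValidationError(f"treatment must be coded 0/1, found {tvals!r}")
        self.t = self.t.astype(np.int8)
        if self.unit_weight is not None and not (self.unit_weight > 0).all():
            raise DataValidationError("unit weights must be positive")

    # -- convenience ------------------------------------------------------
    @property
    def n_units(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_treated(self) -> int:
        return int(self.t.sum())

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_id.tolist()))

    def cluster_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer codes (first-appearance order) and the label array."""
        codes, uniques = pd.factorize(self.cluster_id, sort=False)
        return codes, np.asarray(uniques, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cluster_id": self.cluster_id,
            "t": self.t.astype(int),
            "y": self.y,
            "is_pseudo": self.is_pseudo,
        })
        if self.unit_weight is not None:
            df["unit_weight"] = self.unit_weight
        return df

    def replace(self, **kwargs) -> "ClusteredDataset":
        base = dict(cluster_id=self.cluster_id, t=self.t, y=self.y,
                    is_pseudo=self.is_pseudo, unit_weight=self.unit_weight)
        base.update(kwargs)
        return ClusteredDataset(**base)


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster unit and treated counts, plus positivity status."""

    cluster_id: object
    n: int
    n1: int

    @property
    def status(self) -> str:
        if self.n1 == 0:
            return ALL_CONTROL
        if self.n1 == self.n:
            return ALL_TREATED
        return MIXED

    @property
    def violates(self) -> bool:
        return self.status != MIXED


def summarize_clusters(data: ClusteredDataset) -> list[ClusterSummary]:
    """One :class:`ClusterSummary` per distinct cluster, in first-appearance order."""
    codes, labels = data.cluster_codes()
    n = np.bincount(codes, minlength=len(labels))
    n1 = np.bincount(codes, weights=data.t, minlength=len(labels)).astype(int)
    return [ClusterSummary(lab, int(nk), int(nk1))
            for lab, nk, nk1 in zip(labels, n, n1)]


def load_dataset(path, columns: Mapping[str, str] | None = None,
                 treated_level=None, delimiter: str = ",") -> ClusteredDataset:
    """Read a delimited file into a validated :class:`ClusteredDataset`.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    columns : mapping, optional
        Maps canonical names (``cluster_id``, ``t``, ``y``, optionally
        ``is_pseudo``, ``unit_weight``) to the file's column names.
    treated_level : optional
        If the treatment column uses a two-level coding other than 0/1,
        the level to recode as treated (1).
    """
    colmap = {"cluster_id": "cluster_id", "t": "t", "y": "y",
              "is_pseudo": "is_pseudo", "unit_weight": "unit_weight"}
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"empty file: {path}") from exc
    for key in ("cluster_id", "t", "y"):
        if colmap[key] not in df.columns:
            raise DataValidationError(
                f"missing required column '{colmap[key]}' in {path}")
    traw = df[colmap["t"]]
    if treated_level is not None:
        levels = pd.unique(traw)
        if len(levels) > 2:
            raise DataValidationError(
                f"treatment column has {len(levels)} levels; expected 2")
        t = (traw == treated_level).astype(int)
    else:
        t = pd.to_numeric(traw, errors="coerce")
        if t.isna().any():
            raise DataValidationError(
                "treatment column is not numeric; pass treated_level to recode")
    y = pd.to_numeric(df[colmap["y"]], errors="coerce")
    if y.isna().any():
        raise DataValidationError(
            f"missing or non-numeric outcome at row index {int(y.isna().idxmax())}")
    kwargs = {}
    if colmap["is_pseudo"] in df.columns:
        kwargs["is_pseudo"] = df[colmap["is_pseudo"]].astype(bool).to_numpy()
    if colmap["unit_weight"] in df.columns:
        kwargs["unit_weight"] = df[colmap["unit_weight"]].to_numpy(dtype=float)
    return ClusteredDataset(
        cluster_id=df[colmap["cluster_id"]].astype(str).to_numpy(dtype=object),
        t=t.to_numpy(), y=y.to_numpy(dtype=float), **kwargs)


def write_dataset(data: ClusteredDataset, path, delimiter: str = ",") -> None:
    """Write the dataset as delimited text; round-trips through :func:`load_dataset`."""
    df = data.to_frame()
    df.to_csv(path, index=False, sep=delimiter)
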