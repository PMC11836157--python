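"""Exploratory agglomerative hierarchical clustering of survey records.

Two analyses are supported: socioeconomic dummy variables compared with the
Jaccard distance, and the three metric model variables (travel time, patch
residence time, gain) compared with the raw-unit Euclidean distance, both
agglomerated under complete linkage. A scree series of merge heights feeds
an automated elbow rule (maximum second difference); the full series is
always returned so a human can overrule the automatic choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ElbowResult",
    "jaccard_distance_matrix",
    "euclidean_distance_matrix",
    "complete_linkage",
    "scree_elbow",
    "cut_at_height",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: scipy-style linkage plus leaf labels.

    ``merges`` has one row per merge ``(id_a, id_b, height, size)``; leaf
    ids are ``0..n-1`` and merge ``m`` creates cluster ``n + m``. For ``n``
    leaves there are exactly ``n - 1`` merges, and under complete linkage
    the heights are non-decreasing.
    """

    merges: np.ndarray          # (n-1, 4) linkage matrix
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "merges": [
                {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
                for a, b, h, s in self.merges
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _check_table(table: pd.DataFrame | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError(f"{name} needs a 2-D table with at least 2 rows")
    if np.isnan(arr).any():
        raise ValueError(
            f"{name} contains missing cells; complete the rows in preprocessing first"
        )
    return arr


def jaccard_distance_matrix(binary_table) -> np.ndarray:
    """Pairwise Jaccard distances ``1 - |intersection| / |union|`` on 0/1 rows.

    A pair of identical all-zero rows has an empty union; its distance is
    defined as 0 (the rows are indistinguishable) and logged.
    """
    arr = _check_table(binary_table, "binary_table")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("binary_table must contain only 0/1 values")
    bools = arr.astype(bool)
    if (~bools.any(axis=1)).sum() >= 2:
        logger.info("all-zero row pairs present: their Jaccard distance is 0")
    return squareform(pdist(bools, metric="jaccard"))


def euclidean_distance_matrix(numeric_table) -> np.ndarray:
    """Pairwise L2 distances on raw (unstandardized) numeric columns."""
    arr = _check_table(numeric_table, "numeric_table")
    return squareform(pdist(arr, metric="euclidean"))


def complete_linkage(distance_matrix, labels=None) -> Dendrogram:
    """Agglomerate with complete linkage: D(C1∪C2, C3) = max(D(C1,C3), D(C2,C3))."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    Z = linkage(squareform(D, checks=False), method="complete")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    return Dendrogram(merges=Z, labels=tuple(labels))


@dataclass(frozen=True)
class ElbowResult:
    k: int
    series: np.ndarray          # h(kappa) for kappa = 1..k_max
    second_diffs: np.ndarray    # at kappa = 2..k_max-1
    no_elbow: bool              # all second differences equal (flat scree)

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_clusters": np.arange(1, len(self.series) + 1), "merge_height": self.series}
        )


def scree_elbow(dendrogram: Dendrogram, k_max: int) -> ElbowResult:
    """Pick a cluster count at the bend of the merge-height scree curve.

    ``h(kappa)`` is the height of the merge that reduces ``kappa + 1``
    clusters to ``kappa`` — i.e. the cost of going *below* ``kappa + 1``
    clusters; the series is decreasing in ``kappa``. The elbow is the
    ``kappa`` maximizing the discrete second difference
    ``h(kappa+1) - 2*h(kappa) + h(kappa-1)``; ties break to the smallest
    ``kappa``. A perfectly linear series has no elbow: the smallest
    ``kappa`` (2) is returned with ``no_elbow`` set.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    n = dendrogram.n_leaves
    if n < k_max + 1:
        raise ValueError(f"need more than k_max={k_max} leaves, got {n}")
    heights = dendrogram.heights
    # merge index n-1-kappa creates the kappa-cluster partition
    series = np.array([heights[n - 1 - kappa] for kappa in range(1, k_max + 1)])
    kappas = np.arange(2, k_max)
    second = series[2:] - 2.0 * series[1:-1] + series[:-2]
    no_elbow = bool(np.allclose(second, second[0]))
    k = int(kappas[int(np.argmax(second))])
    if no_elbow:
        k = int(kappas[0])
        logger.warning("scree series has no elbow (linear); returning k=%d", k)
    return ElbowResult(k=k, series=series, second_diffs=second, no_elbow=no_elbow)


def cut_at_height(dendrogram: Dendrogram, height: float) -> np.ndarray:
    """Flat cluster labels from cutting the tree at ``height`` (inclusive)."""
    return fcluster(dendrogram.merges, t=height, criterion="distance")
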