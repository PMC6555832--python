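"""Hierarchical clustering of genomic bins on the (wild-type H3K27me3,
oncohistone, mutant H3K27me3) triplet, autosomes and X clustered separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .track_io import BinnedTrack, _require_same_grid

COLUMNS = ("wt_k27me3", "oncohistone", "mut_k27me3")
PARTITIONS = ("autosomes", "X")


@dataclass(frozen=True)
class ClusterMatrix:
    bins: tuple[tuple[str, int], ...]  # (chrom, start) per row
    data: np.ndarray  # rows x 3, column order COLUMNS
    partition: str

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def empty(self) -> bool:
        return self.n_rows == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(COLUMNS))
        df.insert(0, "chrom", [b[0] for b in self.bins])
        df.insert(1, "start", [b[1] for b in self.bins])
        return df


def build_matrix(
    wt: BinnedTrack, onco: BinnedTrack, mut: BinnedTrack, partition: str
) -> ClusterMatrix:
    """Stack the three tracks into a bins x 3 matrix restricted to the
    requested partition; column order is fixed as (wt, onco, mut)."""
    if partition not in PARTITIONS:
        raise ValidationError(f"partition must be one of {PARTITIONS}, got {partition!r}")
    _require_same_grid(wt, onco)
    _require_same_grid(wt, mut)
    if partition == "autosomes":
        chroms = wt.assembly.autosome_names()
    else:
        chroms = (wt.assembly.x_name(),)
    bins: list[tuple[str, int]] = []
    rows: list[np.ndarray] = []
    for c in chroms:
        n = wt.values[c].size
        bins.extend((c, i * wt.bin_size) for i in range(n))
        rows.append(np.column_stack([wt.values[c], onco.values[c], mut.values[c]]))
    data = np.vstack(rows) if rows else np.zeros((0, 3))
    return ClusterMatrix(tuple(bins), data, partition)


def _correlation_condensed(data: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances with a deterministic convention for
    zero-variance rows: two constant rows are identical (distance 0), a
    constant row is maximally distant (1) from any varying row."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    unit = np.zeros_like(centered)
    unit[ok] = centered[ok] / norms[ok, None]
    sim = unit @ unit.T
    dist = 1.0 - sim
    flat = ~ok
    if flat.any():
        dist[flat, :] = 1.0
        dist[:, flat] = 1.0
        dist[np.ix_(flat, flat)] = 0.0
    np.fill_diagonal(dist, 0.0)
    n = data.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.clip(dist[iu], 0.0, 2.0)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # 1..k per row
    linkage: np.ndarray
    order: np.ndarray  # dendrogram leaf order
    k: int

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


def cluster_bins(
    matrix: ClusterMatrix,
    k: int = 6,
    metric: str = "correlation",
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of the bin matrix, cut to k clusters.

    Default distance is 1 - Pearson correlation across the three columns with
    average linkage; Euclidean and complete linkage are offered as
    alternatives. Deterministic for a fixed input (no random initialization;
    scipy breaks ties by index order).
    """
    if matrix.empty:
        raise ValidationError(f"cannot cluster an empty {matrix.partition} matrix")
    if not 1 <= k <= matrix.n_rows:
        raise ValidationError(f"k must be in 1..{matrix.n_rows}, got {k}")
    if metric == "correlation":
        condensed = _correlation_condensed(matrix.data)
    elif metric == "euclidean":
        condensed = pdist(matrix.data, metric="euclidean")
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    if linkage_method not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage_method!r}")
    if matrix.n_rows == 1:
        return ClusterResult(np.array([1]), np.zeros((0, 4)), np.array([0]), k)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = np.asarray(hierarchy.leaves_list(Z))
    return ClusterResult(labels, Z, order, k)


def cluster_summary(matrix: ClusterMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster column means and sizes, largest cluster first."""
    labels = np.asarray(labels)
    if labels.size != matrix.n_rows:
        raise ValidationError("labels do not align with matrix rows")
    rows = []
    for lab in np.unique(labels):
        mask = labels == lab
        entry = {"cluster": int(lab), "n_bins": int(mask.sum())}
        for j, col in enumerate(COLUMNS):
            entry[f"mean_{col}"] = float(matrix.data[mask, j].mean())
        rows.append(entry)
    df = pd.DataFrame(rows).sort_values(
        ["n_bins", "cluster"], ascending=[False, True], ignore_index=True
    )
    return df
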