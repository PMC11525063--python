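"""Gene regulatory module (GRM) discovery: row-scaled double k-means over the
gene x TF differential-binding matrix, k selection by elbow + silhouette,
differential-binding-density scoring, and top-module selection.

A GRM is the pairing of one TF cluster with one gene cluster; its score is
the differential-binding density, the sum of the (gene, TF) mean
differential-binding cells in the submatrix divided by its surface area
(number of genes x number of TFs). Density is always computed on the raw
(unscaled) matrix — row scaling exists only to make the two k-means
comparable across genes. Single-TF clusters can be excluded from selection,
mirroring the treatment of lone insulator-like modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .binding import TFBSRecord, duplicate_fraction

__all__ = [
    "ClusteringResult",
    "KSelection",
    "GRM",
    "row_zscore",
    "choose_k",
    "double_kmeans",
    "module_density",
    "select_modules",
]

WEAK_SILHOUETTE = 0.3


@dataclass(frozen=True)
class KSelection:
    """Chosen cluster number with the silhouette/elbow diagnostics behind it."""

    k: int
    silhouette: dict
    inertia: dict
    weak_structure: bool


@dataclass(frozen=True)
class ClusteringResult:
    """Row (gene) and column (TF) partitions of one binding matrix."""

    row_labels: pd.Series
    col_labels: pd.Series
    k_rows: int
    k_cols: int
    seed: int
    inertia_rows: float
    inertia_cols: float


@dataclass(frozen=True)
class GRM:
    """A (TF cluster, gene cluster) pairing with its density score."""

    tf_cluster: frozenset
    gene_cluster: frozenset
    direction: str
    density: float
    duplicate_tfbs_fraction: Optional[float] = None
    name: str = ""


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to population sd 1.

    Constant rows (zero variance) map to all-zeros rather than NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 columns to scale rows")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (values - mean) / sd, 0.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def _kmeans(data: np.ndarray, k: int, seed: int, n_init: int = 10) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed, max_iter=300, tol=1e-6).fit(data)


def choose_k(
    matrix: pd.DataFrame,
    axis: str = "rows",
    k_range: Iterable[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> KSelection:
    """Pick k by maximum mean silhouette (Euclidean); report the elbow curve.

    k-means is run for every k in ``k_range`` (restricted to valid values for
    the axis size); ties in silhouette go to the smaller k. A best silhouette
    <= 0.3 flags weak structure.
    """
    data = matrix.to_numpy(dtype=float)
    if axis == "cols":
        data = data.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    n = data.shape[0]
    if n <= 2:
        raise ValueError("axis too small to cluster")
    silhouettes: dict[int, float] = {}
    inertias: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k < n:
            continue
        fit = _kmeans(data, k, seed, n_init)
        inertias[k] = float(fit.inertia_)
        silhouettes[k] = float(silhouette_score(data, fit.labels_, metric="euclidean"))
    if not silhouettes:
        raise ValueError("no valid k in range for this axis size")
    best = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    return KSelection(
        k=best,
        silhouette=silhouettes,
        inertia=inertias,
        weak_structure=silhouettes[best] <= WEAK_SILHOUETTE,
    )


def double_kmeans(
    scaled_matrix: pd.DataFrame, k_rows: int, k_cols: int, seed: int = 0, n_init: int = 10
) -> ClusteringResult:
    """Two independent k-means on the same row-scaled matrix, one per axis.

    Rows (genes) are clustered as observations in TF space; columns (TFs) as
    observations in gene space. Each k-means keeps the best of ``n_init``
    k-means++ restarts; results are deterministic given the seed.
    """
    data = scaled_matrix.to_numpy(dtype=float)
    if not (1 < k_rows <= data.shape[0]) or not (1 < k_cols <= data.shape[1]):
        raise ValueError("cluster numbers out of range for matrix shape")
    row_fit = _kmeans(data, k_rows, seed, n_init)
    col_fit = _kmeans(data.T, k_cols, seed + 1, n_init)
    return ClusteringResult(
        row_labels=pd.Series(row_fit.labels_, index=scaled_matrix.index, name="cluster"),
        col_labels=pd.Series(col_fit.labels_, index=scaled_matrix.columns, name="cluster"),
        k_rows=k_rows,
        k_cols=k_cols,
        seed=seed,
        inertia_rows=float(row_fit.inertia_),
        inertia_cols=float(col_fit.inertia_),
    )


def module_density(
    raw_matrix: pd.DataFrame, gene_cluster: Iterable[str], tf_cluster: Iterable[str]
) -> float:
    """Differential-binding density of one module, on the unscaled matrix.

    density = sum of the submatrix cells / (|genes| * |TFs|).
    """
    genes = sorted(set(gene_cluster))
    tfs = sorted(set(tf_cluster))
    if not genes or not tfs:
        raise ValueError("empty cluster")
    sub = raw_matrix.loc[genes, tfs].to_numpy(dtype=float)
    return float(sub.sum() / (len(genes) * len(tfs)))


def select_modules(
    clustering: ClusteringResult,
    raw_matrix: pd.DataFrame,
    direction: str,
    top_n: int = 3,
    exclude_singletons: bool = True,
    tfbs: Optional[Sequence[TFBSRecord]] = None,
) -> list[GRM]:
    """Rank all (gene cluster, TF cluster) pairings by |density| and keep the top.

    TF clusters of size 1 are skipped when ``exclude_singletons``. When the
    underlying footprints are supplied, each module gets its duplicate-TFBS
    fraction (share of module footprints shared by several TFs at identical
    coordinates). The module name is the TF with the strongest mean |cell|
    inside the module, suffixed with the expression direction.
    """
    candidates: list[GRM] = []
    for gc in sorted(clustering.row_labels.unique()):
        genes = frozenset(clustering.row_labels.index[clustering.row_labels == gc])
        for tc in sorted(clustering.col_labels.unique()):
            tfs = frozenset(clustering.col_labels.index[clustering.col_labels == tc])
            if exclude_singletons and len(tfs) < 2:
                continue
            density = module_density(raw_matrix, genes, tfs)
            dup = None
            if tfbs is not None:
                members = [
                    r for r in tfbs if r.tf in tfs and r.gene_id is not None and r.gene_id in genes
                ]
                dup = duplicate_fraction(members) if members else 0.0
            sub = raw_matrix.loc[sorted(genes), sorted(tfs)]
            dominant = sub.abs().mean(axis=0).idxmax()
            candidates.append(
                GRM(
                    tf_cluster=tfs,
                    gene_cluster=genes,
                    direction=direction,
                    density=density,
                    duplicate_tfbs_fraction=dup,
                    name=f"{dominant}_{direction}",
                )
            )
    candidates.sort(key=lambda m: (-abs(m.density), m.name))
    return candidates[:top_n]
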