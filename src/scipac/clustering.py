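"""Cell clustering (pipeline step 1) and cluster centroids.

Cells are grouped by community detection on a shared-nearest-neighbor graph
built from the top principal components of the normalized expression matrix
— the standard scRNA-seq clustering recipe.  The single tuning parameter is
the resolution, controlling granularity (default 2.0, deliberately finer
than typical so that sub-types of a major cell type can receive their own
association strength).  User-supplied labels bypass clustering entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = ["ClusterLabels", "CentroidMatrix", "cluster_cells", "compute_centroids",
           "labels_from_series"]


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment, clusters indexed 1..K, all non-empty."""

    assignments: np.ndarray
    K: int
    source: str = "inferred"

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.ndim != 1:
            raise ValueError("assignments must be 1-D")
        present = set(np.unique(self.assignments))
        if present != set(range(1, self.K + 1)):
            raise ValueError(
                f"clusters must be exactly 1..{self.K} and non-empty; got {sorted(present)}"
            )
        if self.source not in ("inferred", "user_supplied"):
            raise ValueError("source must be inferred or user_supplied")

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class CentroidMatrix:
    """K × p mean expression profiles of the clusters, on the normalized scale."""

    values: np.ndarray
    cluster_ids: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if self.values.shape != (len(self.cluster_ids), len(self.gene_ids)):
            raise ValueError("centroid matrix shape mismatch")


def cluster_cells(
    sc_mat: ExpressionMatrix,
    resolution: float = 2.0,
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 20,
) -> ClusterLabels:
    """Leiden community detection on an SNN graph of PCA-reduced cells.

    Deterministic for a fixed seed.  Larger resolution gives (on average)
    more, smaller communities.
    """
    if sc_mat.layer_tag != "normalized":
        raise ValueError("cluster_cells expects normalized expression")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if sc_mat.n_obs <= n_neighbors:
        raise ValueError(
            f"only {sc_mat.n_obs} cells but {n_neighbors} neighbors requested; "
            "reduce n_neighbors to build the graph"
        )
    import anndata as ad

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import scanpy as sc

        adata = ad.AnnData(sc_mat.values.copy())
        n_comps = min(n_pcs, sc_mat.n_obs - 1, sc_mat.n_genes - 1)
        sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            n_iterations=2,
        )
    codes = adata.obs["leiden"].astype(int).to_numpy()
    # relabel to contiguous 1..K in order of first appearance
    _, inverse = np.unique(codes, return_inverse=True)
    assignments = inverse + 1
    K = int(assignments.max())
    if K == 1:
        warnings.warn(
            "clustering produced a single cluster; association strengths "
            "will differ only through bootstrap noise",
            stacklevel=2,
        )
    return ClusterLabels(assignments, K, source="inferred")


def labels_from_series(labels: pd.Series | np.ndarray) -> ClusterLabels:
    """Convert user-provided per-cell labels (any hashable values) into
    :class:`ClusterLabels` with source ``user_supplied``."""
    arr = np.asarray(labels)
    uniq, inverse = np.unique(arr, return_inverse=True)
    return ClusterLabels(inverse + 1, len(uniq), source="user_supplied")


def compute_centroids(
    sc_mat: ExpressionMatrix, labels: ClusterLabels
) -> CentroidMatrix:
    """Mean normalized expression profile per cluster (the g_k of the model)."""
    if len(labels) != sc_mat.n_obs:
        raise ValueError("labels length does not match number of cells")
    K = labels.K
    out = np.empty((K, sc_mat.n_genes))
    for k in range(1, K + 1):
        mask = labels.assignments == k
        if not mask.any():
            raise ValueError(f"cluster {k} is empty")
        out[k - 1] = sc_mat.values[mask].mean(axis=0)
    return CentroidMatrix(out, np.arange(1, K + 1), list(sc_mat.gene_ids))
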