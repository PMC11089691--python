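"""Association strengths (pipeline step 3).

For cluster k with centroid g_k and a bulk cohort with mean profile G-bar,
the association strength is the dot product

    Lambda_k = beta' (g_k - G-bar),

the change in the fitted model's linear predictor (log odds, outcome value,
log hazard, or right-tail log odds, depending on the phenotype kind) per
unit over-representation of cluster k, averaged over the bulk samples.  The
per-sample version lambda_k = beta' (g_k - G_i) averages to Lambda_k.

Per-cell strengths (each cell inherits its cluster's Lambda) are
standardized across all cells — centred and scaled by their mean and
standard deviation — which makes runs robust to unbalanced bulk cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import CentroidMatrix, ClusterLabels
from .data import ExpressionMatrix
from .regression import RegressionFit

__all__ = [
    "AssociationResult",
    "association_strength",
    "sample_specific_strength",
    "standardize_strengths",
    "perturbed_bulk_profile",
    "per_cell_association",
]


@dataclass
class AssociationResult:
    """Per-cell standardized strengths plus the per-cluster raw values."""

    cell_ids: list[str]
    cluster: np.ndarray
    lambda_std: np.ndarray
    lambda_raw: np.ndarray  # per cluster, indexed 1..K
    bulk_mean: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "cluster": self.cluster,
             "Lambda": self.lambda_std}
        )


def association_strength(
    beta: np.ndarray, centroids: CentroidMatrix | np.ndarray, bulk_mean: np.ndarray
) -> np.ndarray:
    """Lambda_k = beta' (g_k - G-bar) for every cluster k."""
    g = centroids.values if isinstance(centroids, CentroidMatrix) else np.asarray(centroids)
    beta = np.asarray(beta, dtype=float)
    bulk_mean = np.asarray(bulk_mean, dtype=float)
    if g.shape[1] != beta.shape[0] or bulk_mean.shape[0] != beta.shape[0]:
        raise ValueError("gene dimensions of beta, centroids and bulk mean differ")
    return (g - bulk_mean) @ beta


def sample_specific_strength(
    beta: np.ndarray, g_k: np.ndarray, G_i: np.ndarray
) -> float:
    """lambda_k = beta' (g_k - G_i): the effect of over-representing cluster
    k in the single bulk sample with profile G_i."""
    beta = np.asarray(beta, dtype=float)
    g_k = np.asarray(g_k, dtype=float)
    G_i = np.asarray(G_i, dtype=float)
    if g_k.shape != beta.shape or G_i.shape != beta.shape:
        raise ValueError("dimension mismatch")
    return float(beta @ (g_k - G_i))


def perturbed_bulk_profile(G: np.ndarray, g_k: np.ndarray, delta_gamma: float) -> np.ndarray:
    """Bulk profile after adding cells of cluster k amounting to a
    ``delta_gamma`` fraction of the original cells:
    ``G* = (G + delta_gamma * g_k) / (1 + delta_gamma)``.

    Note the cell-type proportions never appear — the perturbed profile is
    a function of the observed G alone, which is why no deconvolution is
    needed anywhere in the pipeline.
    """
    if delta_gamma < 0:
        raise ValueError("delta_gamma must be non-negative")
    return (np.asarray(G, dtype=float) + delta_gamma * np.asarray(g_k, dtype=float)) / (
        1.0 + delta_gamma
    )


def standardize_strengths(per_cell_raw: np.ndarray) -> np.ndarray:
    """Centre and scale per-cell strengths: ``(x - mean) / sd`` (sample sd).

    A degenerate input (sd = 0) returns all zeros with a warning."""
    x = np.asarray(per_cell_raw, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two cells to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("all association strengths identical; standardized to 0",
                      stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def per_cell_association(
    fit: RegressionFit,
    centroids: CentroidMatrix,
    labels: ClusterLabels,
    bulk_normalized: ExpressionMatrix,
    cell_ids: list[str],
) -> AssociationResult:
    """Assemble the per-cell standardized association strengths."""
    bulk_mean = bulk_normalized.values.mean(axis=0)
    lam_raw = association_strength(fit.beta, centroids, bulk_mean)
    per_cell = lam_raw[labels.assignments - 1]
    return AssociationResult(
        cell_ids=list(cell_ids),
        cluster=labels.assignments.copy(),
        lambda_std=standardize_strengths(per_cell),
        lambda_raw=lam_raw,
        bulk_mean=bulk_mean,
    )
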