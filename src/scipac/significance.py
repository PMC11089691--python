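"""Bootstrap z-scores and p-values for per-cell associations (step 4).

The bulk samples (paired with their phenotype values) are resampled with
replacement B times (default 50, enough to estimate a standard error).
Each replicate refits the elastic net at the original CV-selected penalty
and recomputes standardized per-cell strengths.  The z-score of cell i is
its point-estimate strength divided by the standard deviation of its B
replicate strengths, and the p-value follows from the standard Gaussian
CDF (two-sided by default; associations are signed in both directions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .association import association_strength, standardize_strengths
from .clustering import CentroidMatrix, ClusterLabels
from .data import ExpressionMatrix, Phenotype
from .regression import RegressionFit, fit_elastic_net

__all__ = ["BootstrapResult", "bootstrap_pvalues", "bootstrap_betas",
           "zscores_and_pvalues"]

P_FLOOR = 1e-300


@dataclass
class BootstrapResult:
    B: int
    replicates: np.ndarray  # cells x B standardized strengths
    z: np.ndarray
    p_value: np.ndarray
    degenerate: np.ndarray  # cells whose replicate sd was 0 with Lambda != 0


def _resample_phenotype(pheno: Phenotype, idx: np.ndarray) -> Phenotype:
    if pheno.kind == "survival":
        return Phenotype("survival", None, time=pheno.time[idx], event=pheno.event[idx])
    return Phenotype(pheno.kind, pheno.values[idx],
                     n_levels=pheno.n_levels if pheno.kind == "ordinal" else None)


def _replicate_valid(pheno: Phenotype, idx: np.ndarray) -> bool:
    if pheno.kind == "binary":
        return len(np.unique(pheno.values[idx])) == 2
    if pheno.kind == "ordinal":
        return len(np.unique(pheno.values[idx])) >= 2
    if pheno.kind == "survival":
        return int(pheno.event[idx].sum()) >= 1
    return True


def bootstrap_betas(
    bulk: ExpressionMatrix,
    pheno: Phenotype,
    fit: RegressionFit,
    B: int = 50,
    seed: int = 0,
    max_redraws: int = 100,
) -> np.ndarray:
    """B x p matrix of coefficient vectors refitted on bootstrap resamples
    of the bulk cohort, at the original fit's penalty.

    The bulk-side resampling does not involve the single-cell data, so one
    replicate set serves any clustering of the same cells.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = bulk.n_obs
    betas = np.empty((B, bulk.n_genes))
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if _replicate_valid(pheno, idx):
                break
        else:
            raise RuntimeError(
                f"could not draw a valid bootstrap replicate in {max_redraws} tries"
            )
        boot_bulk = ExpressionMatrix(
            bulk.values[idx], [f"b{j}" for j in range(n)], list(bulk.gene_ids),
            bulk.layer_tag,
        )
        boot_fit = fit_elastic_net(
            boot_bulk,
            _resample_phenotype(pheno, idx),
            alpha_mix=fit.alpha_mix,
            cv_folds=fit.cv_folds,
            seed=seed,
            lambda_penalty=fit.lambda_penalty,
            tol=1e-6,
        )
        betas[b] = boot_fit.beta
    return betas


def zscores_and_pvalues(
    lambda_std: np.ndarray,
    betas: np.ndarray,
    centroids: CentroidMatrix,
    labels: ClusterLabels,
    bulk_mean: np.ndarray,
    one_sided: bool = False,
) -> BootstrapResult:
    """Combine point-estimate strengths with replicate coefficient vectors."""
    B = betas.shape[0]
    m = len(labels)
    reps = np.empty((m, B))
    for b in range(B):
        lam_raw = association_strength(betas[b], centroids, bulk_mean)
        per_cell = lam_raw[labels.assignments - 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate replicates allowed
            reps[:, b] = standardize_strengths(per_cell)
    sd = reps.std(axis=1, ddof=1)
    z = np.zeros(m)
    nonzero = sd > 1e-12  # below this the replicates are numerically constant
    z[nonzero] = lambda_std[nonzero] / sd[nonzero]
    degenerate = (~nonzero) & (lambda_std != 0)
    z[degenerate] = np.inf * np.sign(lambda_std[degenerate])
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) with zero bootstrap spread but "
            "nonzero strength; p floored", stacklevel=2,
        )
    if one_sided:
        p = norm.sf(np.abs(z))
    else:
        p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, P_FLOOR, 1.0)
    return BootstrapResult(B=B, replicates=reps, z=z, p_value=p,
                           degenerate=degenerate)


def bootstrap_pvalues(
    bulk: ExpressionMatrix,
    pheno: Phenotype,
    centroids: CentroidMatrix,
    labels: ClusterLabels,
    fit: RegressionFit,
    lambda_std: np.ndarray,
    B: int = 50,
    seed: int = 0,
    one_sided: bool = False,
) -> BootstrapResult:
    """Full bootstrap: resample bulk cohort, refit, recompute standardized
    strengths, then z and p per cell.  Deterministic given the seed."""
    betas = bootstrap_betas(bulk, pheno, fit, B=B, seed=seed)
    bulk_mean = bulk.values.mean(axis=0)
    return zscores_and_pvalues(lambda_std, betas, centroids, labels, bulk_mean,
                               one_sided=one_sided)
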