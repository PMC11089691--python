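"""Validation runs on synthetic data: full-pipeline F1 / FSC sweeps.

The bulk-side model (elastic-net fit and its bootstrap replicates) does
not depend on how the cells are clustered, so a resolution sweep fits the
regression once per dataset and re-clusters per resolution — the same
computation as independent full runs, factored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import per_cell_association
from .clustering import cluster_cells, compute_centroids
from .data import harmonize_genes, normalize
from .evaluation import calls_from_results, f1_association, fraction_sign_correct
from .regression import fit_elastic_net
from .significance import bootstrap_betas, zscores_and_pvalues
from .simulate import SyntheticDataset

__all__ = ["sweep_resolutions", "scheme_metrics"]


def sweep_resolutions(
    ds: SyntheticDataset,
    resolutions: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    seed: int = 0,
    bootstrap_reps: int = 50,
    p_threshold: float = 0.05,
    alpha_mix: float = 0.4,
    cv_folds: int = 10,
) -> pd.DataFrame:
    """Run the full pipeline on a synthetic dataset at several clustering
    resolutions; returns one row per resolution with F1, FSC, K and the
    per-cell standardized strengths (column ``lambda_std``)."""
    sc_h, bulk_h = harmonize_genes(ds.sc, ds.bulk)
    sc_n = normalize(sc_h)
    bulk_n = normalize(bulk_h)
    fit = fit_elastic_net(bulk_n, ds.pheno, alpha_mix=alpha_mix,
                          cv_folds=cv_folds, seed=seed)
    betas = bootstrap_betas(bulk_n, ds.pheno, fit, B=bootstrap_reps, seed=seed)
    bulk_mean = bulk_n.values.mean(axis=0)
    rows = []
    for r in resolutions:
        labels = cluster_cells(sc_n, resolution=r, seed=seed)
        centroids = compute_centroids(sc_n, labels)
        assoc = per_cell_association(fit, centroids, labels, bulk_n, sc_n.obs_ids)
        boot = zscores_and_pvalues(assoc.lambda_std, betas, centroids, labels,
                                   bulk_mean)
        calls = calls_from_results(assoc.lambda_std, boot.p_value, p_threshold)
        row = {
            "resolution": r,
            "K": labels.K,
            "lambda_std": assoc.lambda_std,
            "p_value": boot.p_value,
        }
        if ds.params.get("scheme") == "discrete":
            row["F1"] = f1_association(ds.truth, calls)
            row["FSC"] = fraction_sign_correct(ds.truth, calls)
        rows.append(row)
    return pd.DataFrame(rows)


def scheme_metrics(
    make_dataset,
    seeds: tuple[int, ...],
    resolutions: tuple[float, ...] = (2.0,),
    bootstrap_reps: int = 50,
    **dataset_kw,
) -> pd.DataFrame:
    """F1/FSC for a scheme generator over several seeds and resolutions."""
    frames = []
    for seed in seeds:
        ds = make_dataset(seed=seed, **dataset_kw)
        df = sweep_resolutions(ds, resolutions=resolutions, seed=seed,
                               bootstrap_reps=bootstrap_reps)
        df["seed"] = seed
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
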