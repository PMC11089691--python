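"""The SCIPAC model: one object from paired data to per-cell associations.

Usage::

    model = SCIPAC(sc_counts, bulk_counts, phenotype)
    res = model.fit(seed=1)
    res.summary()          # run-level overview
    res.frame              # per-cell table: cluster, Lambda, z, p_value

The fit runs the four pipeline steps: (1) cluster the cells (or accept
user labels), (2) fit the penalized bulk-expression -> phenotype
regression, (3) compute per-cell standardized association strengths
Lambda = beta' (g_k - G-bar), (4) bootstrap the bulk cohort for z-scores
and p-values.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .association import AssociationResult, per_cell_association
from .clustering import (ClusterLabels, CentroidMatrix, cluster_cells,
                         compute_centroids, labels_from_series)
from .data import ExpressionMatrix, Phenotype, harmonize_genes, normalize
from .regression import RegressionFit, fit_elastic_net
from .significance import BootstrapResult, bootstrap_betas, zscores_and_pvalues
from .summary import summarize_cell_types

__all__ = ["SCIPAC", "SCIPACResults"]


class SCIPAC:
    """Cell-phenotype association model for paired single-cell + bulk data.

    Parameters
    ----------
    sc_counts, bulk_counts
        Raw-count expression matrices (cells x genes, samples x genes).
        Genes are harmonized to the shared set with nonzero bulk variance,
        then both matrices are library-size normalized (total 10^4, log1p).
    phenotype
        Outcome of the bulk samples (binary / continuous / survival /
        ordinal).
    cell_labels
        Optional per-cell cluster or cell-type labels; clustering is
        skipped when given.
    resolution
        Granularity of the graph community detection (default 2.0).
    alpha_mix, cv_folds
        Elastic-net mixing weight (default 0.4) and CV folds (default 10).
    """

    def __init__(
        self,
        sc_counts: ExpressionMatrix,
        bulk_counts: ExpressionMatrix,
        phenotype: Phenotype,
        cell_labels=None,
        resolution: float = 2.0,
        alpha_mix: float = 0.4,
        cv_folds: int = 10,
        n_pcs: int = 30,
        n_neighbors: int = 20,
        scale_total: float = 1e4,
    ):
        if bulk_counts.n_obs != len(phenotype):
            raise ValueError("phenotype length does not match bulk samples")
        sc_h, bulk_h = harmonize_genes(sc_counts, bulk_counts)
        self.sc = normalize(sc_h, scale_total=scale_total)
        self.bulk = normalize(bulk_h, scale_total=scale_total)
        self.phenotype = phenotype
        self.cell_labels = (
            None if cell_labels is None else labels_from_series(cell_labels)
        )
        self.resolution = resolution
        self.alpha_mix = alpha_mix
        self.cv_folds = cv_folds
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.scale_total = scale_total

    @classmethod
    def from_files(
        cls,
        sc_path: str,
        bulk_path: str,
        pheno_path: str,
        phenotype_kind: str,
        sc_format: str = "mtx",
        bulk_format: str = "csv",
        cell_labels_path: str | None = None,
        **kwargs,
    ) -> "SCIPAC":
        from .data import load_expression_matrix, load_phenotype

        sc_mat = load_expression_matrix(sc_path, format=sc_format)
        bulk = load_expression_matrix(bulk_path, format=bulk_format)
        pheno = load_phenotype(pheno_path, phenotype_kind)
        labels = None
        if cell_labels_path is not None:
            lab = pd.read_csv(cell_labels_path)
            lab = lab.set_index("cell_id").loc[sc_mat.obs_ids, "label"]
            labels = lab.to_numpy()
        return cls(sc_mat, bulk, pheno, cell_labels=labels, **kwargs)

    def fit(
        self,
        bootstrap_reps: int = 50,
        seed: int = 0,
        one_sided: bool = False,
    ) -> "SCIPACResults":
        """Run the full pipeline; deterministic given the seed."""
        if self.cell_labels is not None:
            labels = self.cell_labels
        else:
            labels = cluster_cells(
                self.sc, resolution=self.resolution, seed=seed,
                n_pcs=self.n_pcs, n_neighbors=self.n_neighbors,
            )
        centroids = compute_centroids(self.sc, labels)
        fit = fit_elastic_net(
            self.bulk, self.phenotype, alpha_mix=self.alpha_mix,
            cv_folds=self.cv_folds, seed=seed,
        )
        assoc = per_cell_association(fit, centroids, labels, self.bulk,
                                     self.sc.obs_ids)
        betas = bootstrap_betas(self.bulk, self.phenotype, fit,
                                B=bootstrap_reps, seed=seed)
        boot = zscores_and_pvalues(assoc.lambda_std, betas, centroids, labels,
                                   assoc.bulk_mean, one_sided=one_sided)
        return SCIPACResults(
            model=self, labels=labels, centroids=centroids,
            regression_fit=fit, association=assoc, bootstrap=boot,
            seed=seed, one_sided=one_sided,
        )


@dataclass
class SCIPACResults:
    """Results of a SCIPAC fit: per-cell strengths, z-scores and p-values."""

    model: SCIPAC
    labels: ClusterLabels
    centroids: CentroidMatrix
    regression_fit: RegressionFit
    association: AssociationResult
    bootstrap: BootstrapResult
    seed: int
    one_sided: bool
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """Per-cell table: cell_id, cluster, Lambda, z, p_value."""
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "cell_id": self.association.cell_ids,
                    "cluster": self.association.cluster,
                    "Lambda": self.association.lambda_std,
                    "z": self.bootstrap.z,
                    "p_value": self.bootstrap.p_value,
                }
            )
        return self._frame

    @property
    def lambda_std(self) -> np.ndarray:
        return self.association.lambda_std

    @property
    def pvalues(self) -> np.ndarray:
        return self.bootstrap.p_value

    def calls(self, threshold: float = 0.05) -> np.ndarray:
        from .evaluation import calls_from_results

        return calls_from_results(self.lambda_std, self.pvalues, threshold)

    def cluster_frame(self) -> pd.DataFrame:
        """Per-cluster table with the raw (unstandardized) strengths."""
        return pd.DataFrame(
            {
                "cluster": self.centroids.cluster_ids,
                "Lambda_raw": self.association.lambda_raw,
                "n_cells": np.bincount(self.labels.assignments,
                                       minlength=self.labels.K + 1)[1:],
            }
        )

    def summarize_cell_types(self, cell_types, p_threshold: float = 0.05
                             ) -> pd.DataFrame:
        return summarize_cell_types(self.frame.assign(
            p_value=self.bootstrap.p_value), cell_types,
            p_threshold=p_threshold)

    def summary(self) -> str:
        sig = int((self.pvalues < 0.05).sum())
        pos = int(((self.pvalues < 0.05) & (self.lambda_std > 0)).sum())
        neg = sig - pos
        fit = self.regression_fit
        lines = [
            "SCIPAC cell-phenotype association results",
            "=" * 45,
            f"phenotype kind:        {fit.kind}",
            f"cells / bulk samples:  {len(self.labels)} / {self.model.bulk.n_obs}",
            f"shared genes:          {len(fit.gene_ids)}",
            f"clusters (K):          {self.labels.K} ({self.labels.source})",
            f"elastic net:           alpha={fit.alpha_mix}, "
            f"lambda={fit.lambda_penalty:.4g} ({fit.cv_folds}-fold CV)",
            f"nonzero coefficients:  {int((fit.beta != 0).sum())}",
            f"bootstrap replicates:  {self.bootstrap.B}",
            f"significant cells:     {sig} (p<0.05: {pos} positive, {neg} negative)",
            f"seed:                  {self.seed}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | os.PathLike) -> None:
        """Write results CSV, cluster CSV and a reproducibility manifest."""
        os.makedirs(out_dir, exist_ok=True)
        out = str(out_dir)
        self.frame.to_csv(os.path.join(out, "results.csv"), index=False,
                          float_format="%.10g")
        self.cluster_frame().to_csv(os.path.join(out, "clusters.csv"),
                                    index=False, float_format="%.10g")
        manifest = {
            "scipac_version": _version,
            "phenotype_kind": self.regression_fit.kind,
            "resolution": self.model.resolution,
            "alpha_mix": self.regression_fit.alpha_mix,
            "lambda_penalty": self.regression_fit.lambda_penalty,
            "cv_folds": self.regression_fit.cv_folds,
            "bootstrap_reps": self.bootstrap.B,
            "one_sided": self.one_sided,
            "n_pcs": self.model.n_pcs,
            "n_neighbors": self.model.n_neighbors,
            "scale_total": self.model.scale_total,
            "seed": self.seed,
            "K": self.labels.K,
            "labels_source": self.labels.source,
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
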