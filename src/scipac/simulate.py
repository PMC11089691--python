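"""Synthetic paired single-cell / bulk data with known cell-phenotype truth.

The generator emulates the structure of the validation studies:

* **Discrete schemes** — K cell types, each with a mean expression profile
  sharing a common baseline plus type-specific marker genes; single cells
  are negative-binomial draws around their type's profile.  Each bulk
  sample is a mixture of the type profiles with Dirichlet-distributed
  proportions ``gamma`` (the generative mixture assumption: the expected
  bulk profile is exactly ``sum_k gamma_k * profile_k``), and a binary
  phenotype is drawn from a logistic link on the difference between the
  summed proportions of positively and negatively associated types.
  Preset I has three types (+ / - / null); preset II has seven
  (-, +, -, +, null, null, null).
* **Ordinal scheme** (preset III) — cells sit on four differentiation
  paths with a shared root profile and path-specific terminal profiles;
  a cell's mean expression interpolates linearly between root and
  terminal as its step runs 0..n_steps.  Steps are divided into four
  equal stages (step 0 belongs to stage I).  Each bulk sample has a
  latent mean-step and mixes the path profiles at that step; its ordinal
  phenotype is the stage of the latent step.

Defaults (documented in the methods note): 1000 genes, 10% marker genes
per type at 2-fold elevation, NB dispersion 0.3 (single cell) / 0.1
(bulk), Dirichlet concentration 5, logistic effect size 8.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, Phenotype

__all__ = [
    "SyntheticDataset",
    "simulate_discrete_scheme",
    "simulate_ordinal_scheme",
    "scheme_i",
    "scheme_ii",
    "scheme_iii",
    "stage_from_step",
    "write_dataset",
]


@dataclass
class SyntheticDataset:
    sc: ExpressionMatrix
    bulk: ExpressionMatrix
    pheno: Phenotype
    truth: np.ndarray  # per-cell {positive,negative,null} or step (ordinal)
    mixing: np.ndarray  # per-bulk-sample true proportions (rows sum to 1)
    params: dict
    seed: int
    cell_types: np.ndarray = None  # per-cell type / path index (1-based)
    stage: np.ndarray = None  # ordinal scheme: per-cell stage 1..4
    type_profiles: np.ndarray = None  # K x p mean profiles (relative scale)
    bulk_expected: np.ndarray = None  # n_bulk x p expected mean counts

    def __post_init__(self) -> None:
        if self.mixing is not None:
            if np.any(self.mixing < 0):
                raise ValueError("mixing proportions must be non-negative")
            if not np.allclose(self.mixing.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("mixing proportions must sum to 1 per sample")
        if len(self.truth) != self.sc.n_obs:
            raise ValueError("truth length must equal number of cells")
        if len(self.pheno) != self.bulk.n_obs:
            raise ValueError("phenotype length must equal number of bulk samples")


def stage_from_step(steps: np.ndarray, n_steps: int) -> np.ndarray:
    """Map differentiation steps 0..n_steps to stages 1..4 (four equal
    blocks; step 0 belongs to stage I)."""
    quarter = n_steps // 4
    steps = np.asarray(steps)
    return np.maximum(-(-steps // quarter), 1).astype(int)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Gamma-Poisson draw with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def _baseline_profile(rng: np.random.Generator, p_genes: int) -> np.ndarray:
    """Relative gene abundances: gamma-distributed, heavy on low expression."""
    base = rng.gamma(shape=2.0, scale=1.0, size=p_genes) + 0.05
    return base


def _marker_blocks(p_genes: int, n_groups: int, marker_fraction: float):
    """Disjoint marker gene index blocks, one per group."""
    block = int(round(p_genes * marker_fraction))
    if block * n_groups > p_genes:
        raise ValueError("marker blocks exceed the number of genes")
    return [np.arange(g * block, (g + 1) * block) for g in range(n_groups)]


def simulate_discrete_scheme(
    n_types: int,
    assoc: tuple[int, ...],
    m_cells: int = 3000,
    n_bulk: int = 300,
    p_genes: int = 1000,
    effect_size: float = 8.0,
    seed: int = 0,
    marker_fraction: float = 0.1,
    marker_fold: float = 2.0,
    sc_dispersion: float = 0.3,
    bulk_dispersion: float = 0.1,
    dirichlet_conc: float = 5.0,
    mixing_tilt_sd: float = 1.0,
    sc_depth: float = 2000.0,
    bulk_depth: float = 100000.0,
) -> SyntheticDataset:
    """Generate a discrete-cell-type dataset with a binary phenotype.

    ``assoc`` gives each type's true association: +1, -1 or 0.

    The Dirichlet proportions are perturbed per sample by a log-normal tilt
    along the positive-vs-negative axis (``exp(+d/2)`` on positive types,
    ``exp(-d/2)`` on negative types, ``d ~ N(0, mixing_tilt_sd^2)``, then
    renormalized), so the contrast driving the phenotype varies across the
    cohort the way tumor composition varies across patients.
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if len(assoc) != n_types:
        raise ValueError("assoc length must equal n_types")
    if not set(assoc) <= {-1, 0, 1}:
        raise ValueError("assoc entries must be in {-1, 0, +1}")
    ss = np.random.SeedSequence(seed)
    rng_prof, rng_cells, rng_bulk = [np.random.default_rng(s) for s in ss.spawn(3)]

    base = _baseline_profile(rng_prof, p_genes)
    blocks = _marker_blocks(p_genes, n_types, marker_fraction)
    profiles = np.tile(base, (n_types, 1))
    for k, idx in enumerate(blocks):
        profiles[k, idx] *= marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)  # relative abundances

    # single cells
    types = rng_cells.integers(1, n_types + 1, size=m_cells)
    sc_mean = profiles[types - 1] * sc_depth
    sc_counts = _nb_counts(rng_cells, sc_mean, sc_dispersion)
    sc_mat = ExpressionMatrix(
        sc_counts, [f"cell{i}" for i in range(m_cells)],
        [f"g{j}" for j in range(p_genes)],
    )

    # bulk mixtures (expected profile is exactly the gamma-weighted profile sum)
    gamma = rng_bulk.dirichlet(np.full(n_types, dirichlet_conc), size=n_bulk)
    assoc_sign = np.asarray(assoc, dtype=float)
    if mixing_tilt_sd > 0 and np.any(assoc_sign != 0):
        delta = rng_bulk.normal(0.0, mixing_tilt_sd, size=n_bulk)
        gamma = gamma * np.exp(0.5 * delta[:, None] * assoc_sign[None, :])
        gamma /= gamma.sum(axis=1, keepdims=True)
    bulk_expected = gamma @ profiles * bulk_depth
    bulk_counts = _nb_counts(rng_bulk, bulk_expected, bulk_dispersion)
    bulk_mat = ExpressionMatrix(
        bulk_counts, [f"sample{i}" for i in range(n_bulk)],
        [f"g{j}" for j in range(p_genes)],
    )

    # binary phenotype from the mixing proportions
    assoc_arr = np.asarray(assoc)
    score = gamma[:, assoc_arr == 1].sum(axis=1) - gamma[:, assoc_arr == -1].sum(axis=1)
    intercept = -effect_size * float(score.mean())
    y = None
    for _ in range(20):  # recalibrate the intercept if the draw is unbalanced
        prob = 1.0 / (1.0 + np.exp(-(effect_size * score + intercept)))
        y = (rng_bulk.random(n_bulk) < prob).astype(float)
        balance = y.mean()
        if 0.35 <= balance <= 0.65:
            break
        intercept += np.log(0.5 / max(balance, 1e-3)) if balance > 0.5 else \
            -np.log(0.5 / max(1 - balance, 1e-3))
    else:
        raise RuntimeError(
            f"could not calibrate phenotype class balance; achieved {balance:.2f}"
        )
    label_map = {1: "positive", -1: "negative", 0: "null"}
    truth = np.array([label_map[assoc[t - 1]] for t in types], dtype=object)
    pheno = Phenotype("binary", y)
    return SyntheticDataset(
        sc=sc_mat, bulk=bulk_mat, pheno=pheno, truth=truth, mixing=gamma,
        params=dict(
            scheme="discrete", n_types=n_types, assoc=tuple(assoc),
            m_cells=m_cells, n_bulk=n_bulk, p_genes=p_genes,
            effect_size=effect_size, marker_fraction=marker_fraction,
            marker_fold=marker_fold, sc_dispersion=sc_dispersion,
            bulk_dispersion=bulk_dispersion, dirichlet_conc=dirichlet_conc,
        ),
        seed=seed, cell_types=types, type_profiles=profiles,
        bulk_expected=bulk_expected,
    )


def simulate_ordinal_scheme(
    n_paths: int = 4,
    n_steps: int = 2000,
    m_cells: int = 3000,
    n_bulk: int = 300,
    p_genes: int = 1000,
    seed: int = 0,
    marker_fraction: float = 0.1,
    marker_fold: float = 3.0,
    sc_dispersion: float = 0.3,
    bulk_dispersion: float = 0.1,
    sc_depth: float = 2000.0,
    bulk_depth: float = 100000.0,
) -> SyntheticDataset:
    """Differentiation-path dataset with an ordinal (stage) phenotype.

    All cells are truly associated: the later a cell's step, the more its
    over-representation pushes a bulk sample toward later stages.  ``truth``
    holds the per-cell step; ``stage`` the per-cell stage I..IV (coded 1..4).
    """
    if n_steps % 4 != 0:
        raise ValueError("n_steps must be divisible by 4 (four stages)")
    if m_cells < n_paths:
        raise ValueError("need at least one cell per path")
    ss = np.random.SeedSequence(seed)
    rng_prof, rng_cells, rng_bulk = [np.random.default_rng(s) for s in ss.spawn(3)]

    root = _baseline_profile(rng_prof, p_genes)
    blocks = _marker_blocks(p_genes, n_paths, marker_fraction)
    terminals = np.tile(root, (n_paths, 1))
    for k, idx in enumerate(blocks):
        terminals[k, idx] *= marker_fold
    root = root / root.sum()
    terminals /= terminals.sum(axis=1, keepdims=True)

    paths = rng_cells.integers(1, n_paths + 1, size=m_cells)
    steps = rng_cells.integers(0, n_steps + 1, size=m_cells)
    s = steps / n_steps
    cell_profiles = (1 - s)[:, None] * root + s[:, None] * terminals[paths - 1]
    sc_counts = _nb_counts(rng_cells, cell_profiles * sc_depth, sc_dispersion)
    sc_mat = ExpressionMatrix(
        sc_counts, [f"cell{i}" for i in range(m_cells)],
        [f"g{j}" for j in range(p_genes)],
    )
    stage = stage_from_step(steps, n_steps)

    # bulk: latent mean-step + Dirichlet weights over paths
    latent = rng_bulk.uniform(0.0, n_steps, size=n_bulk)
    w = rng_bulk.dirichlet(np.full(n_paths, 5.0), size=n_bulk)
    sb = latent / n_steps
    bulk_expected = ((1 - sb)[:, None] * root
                     + sb[:, None] * (w @ terminals)) * bulk_depth
    bulk_counts = _nb_counts(rng_bulk, bulk_expected, bulk_dispersion)
    bulk_mat = ExpressionMatrix(
        bulk_counts, [f"sample{i}" for i in range(n_bulk)],
        [f"g{j}" for j in range(p_genes)],
    )
    quarter = n_steps / 4.0
    y = np.minimum(np.ceil(latent / quarter), 4)
    y = np.maximum(y, 1).astype(float)
    if len(np.unique(y)) < 2:  # pathological draw; latent is continuous so rare
        raise RuntimeError("ordinal phenotype degenerate: a single stage drawn")
    pheno = Phenotype("ordinal", y, n_levels=4)
    return SyntheticDataset(
        sc=sc_mat, bulk=bulk_mat, pheno=pheno, truth=steps.astype(float),
        mixing=w,
        params=dict(
            scheme="ordinal", n_paths=n_paths, n_steps=n_steps,
            m_cells=m_cells, n_bulk=n_bulk, p_genes=p_genes,
            marker_fraction=marker_fraction, marker_fold=marker_fold,
        ),
        seed=seed, cell_types=paths, stage=stage,
        type_profiles=np.vstack([root, terminals]),
        bulk_expected=bulk_expected,
    )


def scheme_i(seed: int = 0, **kw) -> SyntheticDataset:
    """Three cell types: positive, negative, null."""
    return simulate_discrete_scheme(3, (1, -1, 0), seed=seed, **kw)


def scheme_ii(seed: int = 0, **kw) -> SyntheticDataset:
    """Seven cell types: types 1 and 3 negative, 2 and 4 positive, 5-7 null."""
    return simulate_discrete_scheme(7, (-1, 1, -1, 1, 0, 0, 0), seed=seed, **kw)


def scheme_iii(seed: int = 0, **kw) -> SyntheticDataset:
    """Four differentiation paths, ordinal stage phenotype."""
    return simulate_ordinal_scheme(seed=seed, **kw)


def write_dataset(ds: SyntheticDataset, out_dir: str | os.PathLike) -> None:
    """Write a dataset in the formats the readers accept: single-cell MTX
    with sidecars, bulk CSV, phenotype CSV and truth CSV."""
    os.makedirs(out_dir, exist_ok=True)
    out = str(out_dir)
    ds.sc.write_mtx(os.path.join(out, "sc"))
    ds.bulk.write_csv(os.path.join(out, "bulk.csv"))
    if ds.pheno.kind == "survival":
        pdf = pd.DataFrame({"sample_id": ds.bulk.obs_ids, "time": ds.pheno.time,
                            "event": ds.pheno.event})
    else:
        pdf = pd.DataFrame({"sample_id": ds.bulk.obs_ids, "value": ds.pheno.values})
    pdf.to_csv(os.path.join(out, "phenotype.csv"), index=False)
    tdf = pd.DataFrame({"cell_id": ds.sc.obs_ids, "truth": ds.truth})
    if ds.cell_types is not None:
        tdf["cell_type"] = ds.cell_types
    if ds.stage is not None:
        tdf["stage"] = ds.stage
    tdf.to_csv(os.path.join(out, "truth.csv"), index=False)
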