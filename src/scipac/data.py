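"""Domain containers and I/O for paired single-cell / bulk expression data.

Two lightweight containers are shared by every stage of the pipeline:

* :class:`ExpressionMatrix` — a dense observations × genes matrix with
  string identifiers on both axes and a tag recording whether the values
  are raw counts or library-size-normalized.
* :class:`Phenotype` — the per-bulk-sample outcome, one of four kinds
  (binary, continuous, survival, ordinal).

Readers accept MatrixMarket triplets (with barcode/feature sidecars, the
10x convention) and dense CSV/TSV with a header row of gene identifiers.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

__all__ = [
    "ExpressionMatrix",
    "Phenotype",
    "load_expression_matrix",
    "harmonize_genes",
    "normalize",
]

PHENOTYPE_KINDS = ("binary", "continuous", "survival", "ordinal")


@dataclass
class ExpressionMatrix:
    """Non-negative expression values, observations (cells or samples) × genes."""

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n_obs, n_genes = self.values.shape
        if n_obs != len(self.obs_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.obs_ids)} obs ids / {len(self.gene_ids)} gene ids"
            )
        if n_obs < 2 or n_genes < 2:
            raise ValueError("need at least 2 observations and 2 genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        for name, ids in (("gene", self.gene_ids), ("observation", self.obs_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")
        if self.layer_tag not in ("raw_counts", "normalized"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes``, in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols].copy(), list(self.obs_ids), list(genes), self.layer_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)

    def write_csv(self, path: str | os.PathLike, sep: str = ",") -> None:
        """Write as obs × gene table with gene header; read back with
        :func:`load_expression_matrix` (orientation ``obs_by_gene``)."""
        self.to_frame().to_csv(path, sep=sep, float_format="%.12g")

    def write_mtx(self, prefix: str | os.PathLike) -> None:
        """Write ``<prefix>.mtx`` (genes × obs, 10x-style) plus
        ``<prefix>.barcodes.tsv`` and ``<prefix>.features.tsv`` sidecars."""
        from scipy import sparse

        prefix = str(prefix)
        mat = sparse.csr_matrix(self.values.T)
        with open(prefix + ".mtx", "wb") as fh:
            mmwrite(fh, mat)
        with open(prefix + ".barcodes.tsv", "w") as fh:
            fh.write("\n".join(self.obs_ids) + "\n")
        with open(prefix + ".features.tsv", "w") as fh:
            fh.write("\n".join(self.gene_ids) + "\n")


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


@dataclass
class Phenotype:
    """Typed outcome for the bulk samples.

    ``kind``
        one of ``binary`` (0/1), ``continuous`` (real), ``survival``
        (positive time plus 0/1 event indicator) or ``ordinal``
        (integer levels 1..J).
    """

    kind: str
    values: np.ndarray
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    n_levels: int | None = None
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in PHENOTYPE_KINDS:
            raise ValueError(f"kind must be one of {PHENOTYPE_KINDS}")
        if self.kind == "survival":
            if self.time is None or self.event is None:
                raise ValueError("survival phenotype needs time and event arrays")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if self.time.shape != self.event.shape:
                raise ValueError("time and event lengths differ")
            if np.any(self.time <= 0):
                raise ValueError("survival times must be positive")
            if not set(np.unique(self.event)) <= {0, 1}:
                raise ValueError("event indicator must be 0/1")
            if self.event.sum() < 1:
                raise ValueError("survival phenotype needs at least one event")
            self.values = self.time
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.kind == "binary":
                uniq = set(np.unique(self.values))
                if not uniq <= {0.0, 1.0}:
                    raise ValueError("binary phenotype must be coded 0/1")
                if len(uniq) < 2:
                    raise ValueError("binary phenotype needs both classes present")
            elif self.kind == "ordinal":
                levels = np.unique(self.values)
                if not np.allclose(levels, np.round(levels)):
                    raise ValueError("ordinal levels must be integers")
                if levels.min() < 1:
                    raise ValueError("ordinal levels are 1-based")
                if len(levels) < 2:
                    raise ValueError("ordinal phenotype needs >= 2 observed levels")
                if self.n_levels is None:
                    self.n_levels = int(levels.max())
                elif self.n_levels < int(levels.max()):
                    raise ValueError("n_levels smaller than the largest observed level")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "Phenotype":
        """Build from a table with ``sample_id`` plus ``value`` or ``time,event``."""
        ids = df["sample_id"].astype(str).tolist() if "sample_id" in df else None
        if kind == "survival":
            return cls(kind, None, time=df["time"].to_numpy(),
                       event=df["event"].to_numpy(), sample_ids=ids)
        return cls(kind, df["value"].to_numpy(), sample_ids=ids)


def load_expression_matrix(
    path: str | os.PathLike,
    format: str = "csv",
    orientation: str = "obs_by_gene",
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        For ``csv``/``tsv``: the table itself, with the first column holding
        observation ids and the header row holding gene ids (or the
        transpose, with ``orientation='gene_by_obs'``).  For ``mtx``: either
        the ``.mtx`` file or a shared prefix; ``<prefix>.barcodes.tsv`` and
        ``<prefix>.features.tsv`` sidecars must sit alongside it.
    orientation
        Whether rows of the file are observations or genes.  MTX files are
        stored genes × observations (the 10x convention), so the default for
        them is effectively ``gene_by_obs``; the flag is ignored for MTX.
    """
    if format not in ("mtx", "csv", "tsv"):
        raise ValueError("format must be one of mtx, csv, tsv")
    if orientation not in ("obs_by_gene", "gene_by_obs"):
        raise ValueError("orientation must be obs_by_gene or gene_by_obs")
    path = str(path)
    if format == "mtx":
        return _load_mtx(path)
    sep = "," if format == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed {format} file {path}: {exc}") from exc
    if orientation == "gene_by_obs":
        df = df.T
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(values, df.index.tolist(), df.columns.tolist())


def _load_mtx(path: str) -> ExpressionMatrix:
    prefix = path[:-4] if path.endswith(".mtx") else path
    mtx_path = prefix + ".mtx"
    if not os.path.exists(mtx_path):
        raise FileNotFoundError(mtx_path)
    barcodes = _read_id_file(prefix + ".barcodes.tsv")
    features = _read_id_file(prefix + ".features.tsv")
    try:
        mat = mmread(mtx_path)
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    if issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{mtx_path}: shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    # stored genes x obs; flip to the internal obs x genes convention
    return ExpressionMatrix(mat.T, barcodes, features)


def _read_id_file(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing sidecar {path}")
    with open(path) as fh:
        # 10x feature files may carry extra columns; the first is the id
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def harmonize_genes(
    sc: ExpressionMatrix, bulk: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, in a common order.

    Genes with zero variance across the bulk samples are dropped from both
    matrices: the bulk regression coefficient of a constant predictor is
    unidentifiable, so such genes can never contribute to the association.
    The shared order is the single-cell matrix's gene order, making the
    operation idempotent.
    """
    bulk_set = set(bulk.gene_ids)
    shared = [g for g in sc.gene_ids if g in bulk_set]
    if len(shared) < 2:
        raise ValueError(
            f"insufficient shared genes: only {len(shared)} in common"
        )
    bulk_shared = bulk.subset_genes(shared)
    variances = bulk_shared.values.var(axis=0)
    kept = [g for g, v in zip(shared, variances) if v > 0]
    if len(kept) < 2:
        raise ValueError(
            "insufficient shared genes after removing zero-variance genes"
        )
    return sc.subset_genes(kept), bulk_shared.subset_genes(kept)


def normalize(
    x: ExpressionMatrix,
    scale_total: float = 1e4,
    log_transform: bool = True,
) -> ExpressionMatrix:
    """Library-size normalization: scale each observation to a common total,
    then optionally ``log(1 + x)``.

    Applied identically to single-cell and bulk matrices so that cluster
    centroids and bulk profiles live on one scale — required for the
    association strength, which subtracts one from the other.
    """
    if x.layer_tag != "raw_counts":
        raise ValueError("normalize expects a raw_counts matrix")
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = x.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"observation(s) with zero total expression: "
            f"{[x.obs_ids[i] for i in zero[:5]]}"
        )
    vals = x.values * (scale_total / totals)[:, None]
    if log_transform:
        vals = np.log1p(vals)
    return ExpressionMatrix(vals, list(x.obs_ids), list(x.gene_ids), "normalized")


def load_phenotype(path: str | os.PathLike, kind: str) -> Phenotype:
    """Read a phenotype CSV (``sample_id`` + ``value`` or ``time,event``)."""
    df = pd.read_csv(path)
    return Phenotype.from_frame(df, kind)
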