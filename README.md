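# scipac

Quantitative cell–phenotype association from paired single-cell and bulk
RNA-seq data.

## The problem

Single-cell RNA-seq resolves the cell types in a tissue but rarely comes
with phenotype information, because it is typically collected from a
handful of individuals. Bulk RNA-seq cohorts (TCGA and the like) carry
rich phenotypes — cancer status, stage, survival — but average over cell
types. `scipac` connects the two: for **every cell** in a single-cell
dataset it estimates a signed **association strength** with a phenotype
observed only in the bulk cohort, together with a bootstrap **p-value**.
It supports binary, continuous, survival and ordinal phenotypes, and is
aimed at anyone asking "which cells in this tissue drive (or protect
against) this phenotype?"

## The model

A bulk expression profile **G** is assumed to be a mixture of cell-type
profiles, G = Σₖ γₖ **g**ₖ with proportions γₖ. A regression model links
expression to the phenotype through a linear predictor β₀ + **β**ᵀ**G**
(log odds for a binary phenotype; the outcome itself, the log hazard, or
the right-tail log odds Pr(Y ≥ j+1) for continuous, survival and ordinal
phenotypes). Adding cells of cluster *k* in proportion Δγ perturbs a bulk
profile to G\* = (G + Δγ **g**ₖ)/(1 + Δγ), and the induced change in the
linear predictor works out to

    Δγ/(1+Δγ) · βᵀ(gₖ − G)

— the mixing proportions cancel, so **no deconvolution is needed**.
Averaged over the cohort this defines the association strength of
cluster *k*,

    Λₖ = βᵀ(gₖ − Ḡ),

where Ḡ is the mean bulk profile and **g**ₖ the cluster centroid. The
pipeline is:

1. **Cluster** the cells (Leiden community detection on an SNN graph of
   top principal components; single tuning parameter: the resolution,
   default 2.0), or accept user labels.
2. **Fit** β by an elastic net (α = 0.4, λ by 10-fold CV) on the bulk
   data — logistic, linear, Cox, or right-tail proportional-odds
   likelihood.
3. **Compute** Λₖ per cluster, assign it to member cells, and standardize
   across cells.
4. **Bootstrap** the bulk cohort (50 replicates) to get per-cell z-scores
   and Gaussian p-values.

The package also ships the synthetic-data generator and the scoring
metrics (F1 on associated-vs-null, FSC = fraction of true discoveries
with the correct direction) used to validate the method.

## Worked example

```python
from scipac import SCIPAC, scheme_i
from scipac.evaluation import f1_association, fraction_sign_correct

# synthetic tissue: 3 cell types (positive / negative / null association),
# bulk cohort mixed from the same type profiles, binary phenotype
ds = scheme_i(seed=1, m_cells=1000, n_bulk=200, p_genes=500)

model = SCIPAC(ds.sc, ds.bulk, ds.pheno)   # harmonizes genes, normalizes
res = model.fit(bootstrap_reps=50, seed=1)
print(res.summary())
```

```
SCIPAC cell-phenotype association results
=============================================
phenotype kind:        binary
cells / bulk samples:  1000 / 200
shared genes:          500
clusters (K):          12 (inferred)
elastic net:           alpha=0.4, lambda=0.07941 (10-fold CV)
nonzero coefficients:  85
bootstrap replicates:  50
significant cells:     661 (p<0.05: 331 positive, 330 negative)
seed:                  1
```

Per-cell results live in `res.frame` (`Lambda` is the standardized
strength; its sign is the direction of the association):

```
cell_id  cluster    Lambda         z      p_value
  cell0        9 -0.255880 -1.499895 1.336416e-01
  cell1        4 -1.061201 -8.048248 8.398741e-16
  cell2       10  1.301803 12.792802 1.798687e-37
```

Scoring the calls (p < 0.05, direction by sign of Λ) against the
generator's ground truth:

```python
calls = res.calls()
f1_association(ds.truth, calls)        # 1.0
fraction_sign_correct(ds.truth, calls) # 0.998
```

So every truly associated cell population is recovered and essentially
every significant call points in the true direction.

The same pipeline runs from the shell:

```sh
scipac simulate --scheme 1 --out-dir sim/
scipac run --sc sim/sc.mtx --bulk sim/bulk.csv --pheno sim/phenotype.csv \
           --phenotype-kind binary --out out/ --seed 1
scipac evaluate --truth sim/truth.csv --results out/results.csv
```

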