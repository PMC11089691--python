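# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `scipac`, including the places where the
design was genuinely open and what the package chose.

## Model and derivation

A bulk expression profile **G** ∈ ℝᵖ is modelled as a convex mixture of
cell-type profiles, G = Σₖ γₖ gₖ, Σ γₖ = 1. A generalized linear predictor
η(G) = β₀ + βᵀG links expression to the phenotype:

| phenotype  | likelihood                         | η is …                         |
|------------|------------------------------------|--------------------------------|
| binary     | logistic                           | log odds                       |
| continuous | Gaussian (ordinary linear model)   | the outcome mean               |
| survival   | Cox proportional hazards (Breslow) | log hazard ratio (no β₀)       |
| ordinal    | right-tail proportional odds       | logit Pr(Y ≥ j+1), slope shared |

Over-representing cluster *k* by Δγ turns G into
G\* = (G + Δγ gₖ)/(1 + Δγ); the γ's cancel, so no deconvolution is ever
performed. The induced shift in η is Δγ/(1+Δγ) · βᵀ(gₖ − G); since the
leading factor is positive and shared by all clusters, the per-sample
effect is summarized by λₖ = βᵀ(gₖ − G) and its cohort average

Λₖ = βᵀ(gₖ − Ḡ).

Per-cell strengths (each cell inherits its cluster's Λ) are standardized
— centred and scaled by their mean and sample standard deviation across
all cells — which makes results robust to unbalanced bulk cohorts. Λ is
therefore interpretable only relative to the cell population analysed,
with sign carrying the direction.

The **ordinal** model deliberately uses the right-tail parameterization
logit Pr(Y ≥ j+1) = β₀ⱼ + βᵀx rather than the conventional cumulative
(left-tail) one, so that a positive coefficient means a higher chance of
a *higher* level and the sign of Λ reads the same way for every
phenotype kind. Intercepts must decrease strictly in j for all category
probabilities to be positive.

## Estimation

β is estimated on the bulk data by the elastic net

min −(1/n)·l(β₀, β) + λ[(1−α)/2‖β‖₂² + α‖β‖₁],

with α fixed at 0.4 (overridable) and λ selected by 10-fold
cross-validation at the minimum mean held-out deviance (not the 1-SE
rule; the choice is recorded on the fit object). Folds are seeded and
stratified by class (binary/ordinal) or event status (survival);
survival CV uses the Verweij–Van Houwelingen construction
−2(pl_full − pl_train). The λ path has 30 points, log-spaced from the
smallest λ that zeroes every coefficient down to 0.01·λ_max.

All four likelihoods share one in-repo solver: monotone FISTA
(accelerated proximal gradient) with backtracking line search. The ridge
term is folded into the smooth part; the ℓ1 term is applied by
soft-thresholding the gene coefficients only — intercepts are never
penalized. For the ordinal model, parameter points with non-decreasing
intercepts evaluate to +∞ and are rejected by the line search; the
likelihood is convex in (β₀, β), so this is a simple feasibility
barrier. Convergence: relative objective change ≤ 1e-7 (1e-5 inside CV
folds, 1e-6 in bootstrap refits), at most 10 000 iterations. The solver
is validated in the test suite against independent implementations
(scikit-learn's coordinate-descent and saga solvers, lifelines' Cox
fit, and a by-hand enumeration of Breslow risk sets).

Genes are standardized (mean 0, sd 1 across bulk samples) inside the
solver so the penalty treats them comparably; the returned coefficients
are mapped back to the normalized-expression scale, which the Λ formula
requires. A gene constant within a (bootstrap) sample keeps coefficient
0. Cluster centroids gₖ are the mean normalized expression of member
cells; Ḡ is the mean normalized bulk profile.

## Preprocessing

Both matrices are restricted to their shared genes; genes with zero
variance across bulk samples are dropped (their coefficients are
unidentifiable). Both are then library-size normalized to a total of
10⁴ per observation and log1p-transformed — identical treatment keeps
centroids and bulk profiles on one scale, which the subtraction in Λ
requires. No highly-variable-gene selection or per-gene scaling is
applied; the preprocessing is deliberately minimal and is a stand-in
choice where a canonical protocol is not dictated by the model.

## Clustering

Leiden community detection on a shared-nearest-neighbor graph built from
the top 30 principal components with 20 neighbors (common single-cell
practice; fixed for reproducibility, configurable). The resolution
(default 2.0, deliberately finer than typical) is the only tuning
parameter; validation shows per-cell Λ is rank-stable (Spearman > 0.8)
across resolutions 0.5–4. One seed drives PCA and community detection.
K = 1 is allowed but warns, since strengths then differ only through
bootstrap noise. User-supplied labels bypass clustering entirely.

## Significance

Bulk samples are resampled with replacement, paired with their phenotype
values, B = 50 times (enough for a standard-error estimate). Each
replicate refits the elastic net **at the original CV-selected λ** — λ is
treated as a property of the study design; re-running CV inside every
replicate would dominate runtime with little effect on the spread — and
recomputes standardized per-cell strengths, standardizing within each
replicate so replicate and point values are commensurable. Then
zᵢ = Λᵢ / sd(Λᵢ⁽¹⁾…Λᵢ⁽ᴮ⁾) (sample sd, B−1 denominator) and
pᵢ = 2(1 − Φ(|zᵢ|)). Two-sided is the default because associations are
signed in both directions; a one-sided option exists. Replicates that
lose a phenotype class (or all events) are redrawn, up to 100 attempts.
p-values are floored at 1e-300; a cell with zero replicate spread
(numerically, sd ≤ 1e-12) but nonzero Λ gets the floor and a flag. No
multiple-testing correction is applied; the method reports raw p-values.

Under minimum-deviance CV an occasional permuted-null cohort retains
small noise coefficients (independent CV implementations behave the
same); the pipeline-level consequence is bounded — across permuted-
phenotype runs the average fraction of cells at p < 0.05 stays well
under 15% — and is checked by the test suite.

## Cell-type summaries

For a known cell type, p₊ is the share of its cells called significantly
positive (p < 0.05 and Λ > 0; the threshold is configurable) and p_a the
same share over all cells. The enrichment is the natural-log odds ratio
ρ₊ = log[(p₊/(1−p₊))/(p_a/(1−p_a))], and ρ₋ analogously. A type is
positive if ρ₊ ≥ 1 and ρ₋ < 1, negative in the mirror case, otherwise
inconclusive; types under 1% of the population are not called. When a
margin of the implied 2×2 table is zero the Haldane–Anscombe correction
(+0.5) keeps ρ finite — except that identical raw rates (including the
common 0/0 case) are defined as ρ = 0, since the correction alone would
otherwise hand every small group a spurious log(m/n_group) enrichment.

## Synthetic data

The generator recreates the *structure* of the validation studies with
its own documented defaults; it makes no attempt to match any external
dataset numerically.

**Discrete schemes.** K type profiles share a gamma-distributed baseline
(shape 2, floor 0.05); each type elevates its own disjoint 10% marker
block 2-fold; profiles are normalized to relative abundances. Cells draw
their type uniformly and their counts from a negative binomial
(gamma-Poisson) around the type profile at depth 2000, dispersion 0.3.
Bulk mixing proportions are Dirichlet(5), then perturbed per sample by a
log-normal tilt along the positive-vs-negative axis (exp(±δ/2) on
positive/negative types, δ ~ N(0, 1), renormalized) so the contrast
driving the phenotype varies across the cohort the way composition
varies across patients. Expected bulk counts are exactly the γ-weighted
profile mixture at depth 10⁵; observed counts are NB with dispersion
0.1 (bulk averages over many cells, so less dispersed than single
cells). The binary phenotype is Bernoulli(σ(8·(Σ₊γ − Σ₋γ) + c)) with c
calibrated so class balance lands in [0.35, 0.65]. Preset I: 3 types
(+, −, 0); preset II: 7 types (−, +, −, +, 0, 0, 0).

**Ordinal scheme.** Four differentiation paths share a root profile and
have path-specific terminals (10% markers at 3-fold); a cell at step
s ∈ [0, 2000] has mean profile (1−s/2000)·root + (s/2000)·terminal.
Steps split into four equal stages (step 0 → stage I, 500 → I,
501 → II, …). Each bulk sample has a latent mean-step uniform on
(0, 2000), Dirichlet path weights, and the stage of its latent step as
ordinal phenotype.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, gene–gene correlation beyond the type/path structure,
library-size variation beyond NB noise, or dropout beyond what the NB
produces. Passing the synthetic benchmarks therefore demonstrates the
statistical machinery (signal propagation from mixing proportions
through the penalized fit to calibrated per-cell calls), not robustness
to every artefact of real data.

Randomness is split into independent streams (profiles / cells / bulk)
from one seed, so changing the number of cells leaves the type profiles
and mixtures untouched, and identical seeds reproduce datasets
bit-for-bit.

## Validation problem sizes

The benchmark runs (`scripts/acceptance.py`, mirrored in the test suite)
use 3000 cells, 300 bulk samples and 1000 genes per dataset, three seeds
per scheme, resolutions 0.5/1/2/4 for the scheme-I sweep; null
calibration uses ten permuted-phenotype cohorts at 1000 cells, 200 bulk
samples, 500 genes. Because the bulk-side fit and its bootstrap
replicates do not depend on the clustering, the resolution sweep fits
the regression once per dataset and re-clusters per resolution — the
identical computation as independent runs, factored.

## Known limitations

* Association is defined through a linear predictor in (normalized)
  expression; strongly non-linear expression–phenotype relations are out
  of model.
* λ is not re-cross-validated inside bootstrap replicates (see above);
  the replicate spread conditions on the design-level penalty.
* The bootstrap resamples the bulk cohort only; uncertainty from the
  single-cell side (clustering, centroid estimation) is not propagated.
* Count phenotypes (Poisson/NB) and other penalties (SCAD) would slot
  into the same framework but are not implemented.
* Cell-type summaries require user-provided annotations; clusters are
  never auto-named.
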