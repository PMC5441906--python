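# Methods

This note documents the statistical models implemented in `mqtlnet`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
affect results.

## Study design assumed

A panel of *n* inbred lines (default 135, a scale typical of elite
cereal breeding panels) is grown in *nE* environments (default 3) with
*nR* replicates each (default 2), laid out in incomplete blocks within
replicates. Metabolite abundances are measured per plot; genotypes are
biallelic SNP dosages (0/1/2, residual heterozygosity and missingness
allowed).

## Trial model

**Adjusted entry means.** Per environment and trait, the model
`value = line (fixed) + replicate (random) + block-within-replicate
(random) + error` is fitted by REML; the fixed line estimates,
recentred on the grand mean, are the adjusted entry means. On a
balanced complete design with zero block variance these reduce exactly
to arithmetic line means. Because block variance is *estimated*, block
effects are shrunken BLUPs: a planted block effect is largely but not
perfectly absorbed (the fixed-block least-squares answer is the
infinite-variance limit).

**BLUEs.** Across environments, `entry mean = line (fixed) +
environment (fixed)` by least squares with deviation-coded environment
effects, so with a complete line × environment table a line's BLUE is
the row mean. Lines with no entry mean anywhere are dropped with a
warning.

**One-step variance components.** On replicate-level data,
`value = environment (+ replicate within environment, fixed) +
block (random) + line (random) + line×environment (random) + error`,
fitted by REML. Estimates are constrained non-negative. On balanced
data the estimates agree with the closed-form ANOVA expected-mean-square
estimators to ~1e-7 (verified in the test suite).

**Significance of σ²_G.** Because the null value lies on the boundary,
the LRT p-value is halved: p = 0.5 · P(χ²₁ ≥ LR), i.e. 0.5 at LR = 0.

**Heritability and repeatability.** Entry-mean broad-sense
heritability H² = σ²_G / (σ²_G + σ²_G×E/nE + σ²_ε/(nE·nR)) — the
standard plant-breeding convention for the design above. Repeatability
w² = σ²_G / (σ²_G + σ²_ε/nR) from a within-environment two-component
fit (block variance is design nuisance and excluded from the
denominator).

**Maturity subgroups.** Lines are split into equal-frequency terciles
by heading date (the split rule is a convention; no cut points are
canonical); variance components and H² are re-estimated within each
group and averaged over traits. A constant covariate degrades to an
equal-size random split with a warning.

## REML engine

All mixed models are fitted by one engine (`reml.py`): the residual
variance is profiled out and the restricted likelihood is maximized
over log variance ratios γᵢ = σ²ᵢ/σ²_e with a bounded Nelder–Mead
simplex (restarted once at its own optimum; convergence tolerance
1e-10 on the objective). The likelihood is evaluated through the
mixed-model equations (one Cholesky per evaluation), which is exact
for independent random-effect blocks; correlated effects (the
polygene with covariance K) are reduced to the i.i.d. case by passing
Z·L with K = LL'. Ratios pinned at the lower bound (log γ = −25) are
reported as zero components. Data that the full design interpolates
exactly (saturated or noise-free cases) make the profiled objective
unbounded; they are detected and handled by hierarchical coarse-to-fine
attribution of variance, which matches the balanced ANOVA limit.

## Correlation structure

Pearson correlations and two-sided t-tests on BLUEs for all unordered
trait pairs; significance tiers at p < 0.05/0.01/0.001 are cumulative
(a pair significant at 0.001 counts in all three), matching the nesting
of published tier counts. Clustering is UPGMA on d = 1 − r (scipy).
The metabolome–genome association is a Mantel test: Pearson correlation
of lower-triangle entries between the Euclidean distance on
standardized BLUEs and the allele-sharing distance (mean dosage
mismatch over non-missing SNPs, scaled to [0,1]); the permutation
p-value (default 9999 permutations, seeded generator) relabels the
lines of one matrix. Distance metrics are a package choice — sources
in this literature rarely state theirs — so the Mantel r is comparable
only qualitatively across studies.

## GWAS

**Kinship.** VanRaden genomic relationship matrix: per-SNP
mean-imputation of missing dosages, centering at 2p̂, cross-product
scaled by Σ2p̂(1−p̂), ridge 1e-6 on the diagonal. For fully inbred
panels the diagonal is near 1 + F ≈ 2.

**Scan.** Per-environment adjusted entry means are stacked
(n·nE observations). The null model `Y = environment (fixed) +
u + e`, u ~ N(0, σ²_u K) repeated across environments, is fitted by
REML once per trait; σ²_u/σ²_e is then fixed and reused for every SNP
(the standard population-parameters-previously-determined shortcut,
trading a negligible approximation for a per-SNP GLS solve in a
pre-rotated eigenbasis). Each SNP enters as a fixed allele-substitution
effect tested by Wald F with one numerator degree of freedom.
Environment effects are fixed: with ~3 levels the fixed/random
distinction is numerically negligible, and fixed effects keep the
per-SNP profile exact.

**SNP×environment.** The interaction is one random effect per
environment scaled by the dosage (a single variance), tested against
the SNP-only model by the halved-p LRT. Because each test costs two
REML fits, it is computed by default only for FDR-significant SNPs
(modes `all`/`none` available).

**Multiple testing and effect sizes.** Benjamini–Hochberg q-values per
trait; thresholds 0.20 for reporting and 0.10 for network anchors.
Single-SNP R² is the marginal squared correlation of BLUEs with dosage
(×100); the joint value over a trait's significant SNPs is the
rank-aware adjusted R² of the multiple regression (duplicated or
collinear SNPs cannot inflate it). p_G = R²/H², capped at 100 with a
flag — R² is a share of phenotypic variance, so dividing by the
genotypic share H² expresses the SNP's contribution on the genotypic
scale.

## Causal network

Traits entering the network are those whose genotypic variance passes
the halved-p LRT at α = 0.05. The skeleton is the PC deletion phase
with Fisher-z partial-correlation tests,
z = atanh(r_partial)·√(n − |S| − 3): starting complete, an edge (i, j)
is removed as soon as some subset of the pair's current neighbours of
size ℓ = 0, 1, 2, … renders it independent at α (default 0.01);
separating sets are stored; traits are processed in lexicographic
order so the run is deterministic. PC's order-dependence is real but
mild at these sizes.

Orientation uses significant mQTL (q < 0.10 FDR) as upstream causal
anchors with instrumental-variable logic: an anchor q of trait yi that
is *not* an anchor of yj votes for yi → yj when q is marginally
associated with yj (p < α_orient, default 0.05) **and** independent of
yj given yi (p ≥ α_orient) — association flowing only through yi is
the signature of yi being upstream. Each undirected edge is oriented
to the strict-majority direction; ties or no votes leave it
undirected; an orientation that would close a directed cycle among
traits is rejected and logged. SNP → trait edges are always directed
and weighted by p_G; trait–trait edges carry the pairwise Pearson r.
The vote/veto scheme is this package's concrete instantiation of
QTL-supervised orientation; published descriptions of such heuristics
leave the scoring unspecified.

**Known limitation — measurement error.** The conditional-independence
veto assumes the conditioning parent is measured (nearly) without
error. When trait values are noisy (low-heritability BLUEs), the
anchor→child path leaks through the residual of the parent and vetoes
correct orientations; with enough samples the leak is *significant*
and orientation recall drops. The orientation-recovery tests therefore
use low replicate noise; on real low-H² traits orientations should be
read as conservative (edges stay undirected rather than flip).

## Synthetic-data generator

Genotypes: each of `n_families` families has two founder haplotypes
with allele frequencies drawn uniformly from `maf_range`; a line's
allele at each locus comes from one of its family's founders. This is
the simplest mechanism that yields the within-family > between-family
relatedness gradient a kinship correction must absorb. There is no
linkage disequilibrium decay, no selection, no epistasis.

Phenotypes: trait genetic values are built in topological order of a
linear causal DAG — QTL contributions (effects in genetic-SD units per
standardized dosage, so an effect b explains b²/(1+b²) of the trait's
direct genotypic variance), plus path-weighted parent values, plus a
polygenic deviate with variance `var_G`. The polygenic deviate is by
default *genomic* (u ~ N(0, var_G·K) built from the panel's own
markers, optionally a held-out index range) so that family structure
confounds naive association tests; an `iid` mode draws line effects
independently of the genome, which is the regime in which the
variance-component estimators' truth values are defined and in which
marker-test power is measured without the kinship term absorbing part
of the causal marker itself (proximal contamination). Observations add
an environment main effect (SD 3.0 — environments dominate, as is
typical for field metabolite data), a G×E deviate (`var_GxE`, default
2.0 = twice the genotypic variance), a cyclically allocated
incomplete-block effect (SD 0.5) and replicate noise (`var_resid`,
default 1.0). Heading dates are drawn independently of all trait
values. One integer seed drives three deterministic substreams
(genotypes, phenotypes, heading dates); fixed seed ⇒ byte-identical
tables.

What the generator does **not** emulate: chromatographic drift and
batch effects beyond a generic per-batch reference ratio, peak-picking
artefacts, LD structure, non-Gaussian trait distributions (the Box–Cox
stage is therefore exercised on lognormal unit tests, not on the
generator), and heterogeneous per-environment error variances. Passing
tests demonstrate the estimators are correct under the stated model,
not that real GC-MS data meet the model.

## Test problem sizes

The statistical acceptance tests run at the design scale of the study
the package targets — 135 lines × 3 environments × 2 replicates — with
marker counts of 500–1000 and 20–50 seed replicates per check, sizes
chosen so the whole suite completes in a few minutes while keeping
Monte-Carlo error well inside the asserted tolerances. The GWAS
calibration check uses a 500-SNP held-out null panel against a
500-SNP genomic background; skeleton-oracle equivalence uses ≤6-trait
sparse SEMs at n = 1500 where the exhaustive-search oracle is itself
reliable (conditioning on common children can cancel a true edge in
dense graphs — an oracle failure, not a PC failure).

## Numerical conventions

* Box–Cox: λ on the grid −2…2 step 0.1 by profile likelihood; ties
  break toward λ = 1, then λ = 0; shift 1e-6 − min(x) only when
  non-positive values occur; fitted per trait on replicate-level data
  pooled across environments.
* MAF counts heterozygotes as one copy of each allele; monomorphic =
  zero non-missing variance. QC rules are independent, so evaluation
  order cannot change the kept set.
* Wald denominator df = observations − fixed-effect rank.
* BH q-values from statsmodels; flags strict (`q < threshold`).
* Genotype TSV: lines as rows, SNP-id header, missing = `NA`;
  map positions as (chromosome label, cM). VCF GT → dosage
  (0/0→0, 0/1→1, 1/1→2, ./.→missing); multi-allelic records rejected.
* All writers round-trip within 1e-12 relative; manifests record
  SHA-256 of every artifact and of the config, so identical
  config + seed ⇒ identical hashes.
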