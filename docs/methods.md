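# Methods

`hapgp` implements annotation-aware, haplotype-based genomic prediction
for quantitative traits in diploid populations with phased genotypes. This
note documents the statistical models, the numerical choices, and what the
synthetic cohorts the test suite relies on do and do not emulate.

## Model overview

All prediction models are variants of the univariate animal model

    y = 1 μ + a + e,    a ~ N(0, σ²ₐ K),    e ~ N(0, σ²ₑ I)

applied to phenotypes pre-adjusted for environmental fixed effects. The
models differ only in the relatedness kernel **K**, which is built from
one of three representations of the marker data:

1. **SNP dosages** — the 0/1/2 minor-allele counts.
2. **Haploblock dosages** — consecutive phased SNPs are grouped into
   haploblocks; each block is a multi-allelic locus whose alleles are the
   distinct SNP strings observed in the population, and each allele
   becomes a pseudo-marker column holding the 0/1/2 copy count.
3. **Categorical configurations** — the unordered pair of haplotype
   alleles at a block (or the genotype at a SNP) is a label with no
   additivity assumption.

### The nine kernels

| model | kernel | input | scaling |
|---|---|---|---|
| GBLUP | G = (M−P)(M−P)′ / 2Σpᵢ(1−pᵢ) | SNP dosages | heterozygosity sum |
| G_H BLUP | G_H = M_H M_H′ / Q_H | block dosages | # blocks, genome-wide |
| G_H BLUP\|GA | same, class-restricted | block dosages | Q_H^GA per class |
| CM | S: proportion of SNPs in identical genotype state | categorical SNPs | m |
| C_H M | S_H: proportion of blocks in identical configuration | categorical blocks | Q_H |
| C_H M\|GA | S̃: class-restricted S_H | categorical blocks | Q_H^GA |
| CE | E = 0.5·(mS)#(mS+1)/m² | from S | m |
| C_H E | E_H, same with Q_H S_H | from S_H | Q_H |
| C_H E\|GA | Ẽ, same with Q_H^GA S̃ | from S̃ | Q_H^GA |

`#` is the Hadamard product. The epistasis construction has a counting
interpretation: if c·S_ij loci share state, then E_ij is the number of
unordered locus *pairs* (self-pairs included) simultaneously in identical
state, divided by c². Its diagonal is exactly (c+1)/(2c). G_H is
deliberately uncentered — its definition carries no allele-frequency
subtraction — and the scale difference relative to G is absorbed by the
REML variance component (see below).

### Haploblock construction

Blocks are built by a greedy left-to-right scan in physical order, within
a SNP set (the markers of one annotated genome feature) or within a whole
chromosome when annotation is ignored. The current block absorbs the next
marker unless the number of distinct haplotype strings observed across
all 2n phased haplotypes would exceed `max_alleles` (default 10), in
which case the block closes and a new one starts at that marker. SNP sets
with a single marker, and singletons left at the end of a scan, keep
their 0/1/2 genotype as a single-SNP column; these count toward Q.
Allele catalogs are ordered lexicographically over the 0/1 strings so
column order is deterministic. No frequency pruning of rare alleles is
applied. Mid-scan distinct-string counting is exact (incremental
factorization of string prefixes), so greedy maximality holds by
construction and is re-verified by exhaustive recount in the tests.

### Genomic classes

A GFF3 annotation is reduced to five classes: gene, exon, CDS, UTR
(both 5′ and 3′ types merged) and IGR, the per-chromosome complement of
the merged gene intervals. Strand is ignored. Overlapping features of a
class are merged into union intervals before markers are assigned
(boundary positions are inside), so a marker contributes at most one
pseudo-marker set per class; `merge_overlaps=False` preserves
per-feature duplication for comparison. Gene and IGR tile the genome, so
every marker belongs to exactly one of the two; UTR ∪ CDS ⊆ exon ⊆ gene
holds whenever the annotation itself nests.

## Quality control

Markers failing call rate (> 0.90 required), minor-allele frequency
(> 0.01) or the Hardy–Weinberg exact test (p > 10⁻⁶), in that order of
accounting, are removed first; individuals failing call rate (> 0.90) on
the surviving markers are removed second. The HWE test is the standard
conditional-on-allele-counts exact test without mid-p correction.
Genotypes must be phased and complete downstream of QC; imputation is
out of scope by design, so missing calls are a contract violation rather
than a preprocessing step. MAF and minor-allele orientation are
recomputed after filtering.

Phenotypes are adjusted once, before any cross-validation, by an OLS fit
of the trait on sex, year, entry body weight (kg) and fattening period
(days); the residuals are the working phenotypes everywhere else, which
is why the mixed model carries an intercept only. A rank check names
aliased columns instead of silently dropping them.

## REML and prediction

With a single random effect the restricted likelihood profiles down to a
one-dimensional problem: the kernel is eigendecomposed once, the
covariance λK + I is diagonal in that basis for every variance ratio
λ = σ²ₐ/σ²ₑ, and the profiled restricted log-likelihood is maximised by
bounded Brent search over log λ (tolerance 1e-10, h² bracketed in
[1e-4, 1−1e-4]; estimates at the bracket edge are flagged as boundary,
not fatal). σ²ₑ and μ have closed forms at each λ. The standard error of
h² comes from the numerically evaluated observed information in
(σ²ₐ, σ²ₑ) via the delta method.

Kernels enter REML rescaled to mean diagonal 1 (the usual
genomic-relationship normalisation). This makes σ²ₐ an interpretable
per-unit-relationship variance and renders h² and all predictions
invariant to the arbitrary scaling constants that distinguish the nine
kernels — the property that justifies comparing them under one model. A
ridge of 1e-6 is added to the kernel diagonal at solve time only;
exported kernels match their defining formulas exactly.

DGVs for masked individuals use the BLUP identity
â = σ²ₐ K[:,T] (σ²ₐ K_TT + σ²ₑ I)⁻¹ (y_T − μ̂) with μ̂ from GLS on the
training block; the same ridged kernel appears in numerator and inverse
so the kernel-regression form K_VT K_TT⁻¹ â_T is reproduced exactly.

## Cross-validated assessment

Fivefold cross-validation, replicated 20 times with a fresh random
permutation per replicate (fold sizes differ by at most one). Variance
components are re-estimated on every training portion. The five folds'
validation predictions are pooled into one accuracy and one bias slope
per replicate:

* accuracy = cor(DGV, adjusted phenotype) / √h²;
* bias = OLS slope of adjusted phenotype on DGV (1 unbiased, > 1
  deflated, < 1 inflated predictions).

The h² in the denominator is the full-data REML estimate obtained from
the standard all-SNP G matrix — one value per trait, shared by every
model being compared. Using each kernel's own h² instead distorts
between-model comparisons, because kernels that inflate their own
heritability estimate (the uncentered G_H family does) would be
penalised twice. `run_cv` accepts the shared h² explicitly and falls
back to its own kernel's estimate only in single-kernel use. Bias
significance across replicates is a two-sided one-sample t-test of the
mean slope against 1 at α = 0.05; per-fold accuracies are retained for
diagnostics but all headline numbers pool folds first.

## Synthetic cohorts

The generator emulates the structure of a ~1300-animal beef-cattle
cohort at desk scale; its defaults are one fixed set of study conditions,
not tuning knobs.

* **Genotypes.** Each of the 2n haplotypes is a mosaic of a small founder
  pool: between consecutive markers the copied founder switches with
  probability 1 − exp(−ld_decay · distance), founders being drawn with
  Dirichlet weights so allele frequencies spread over (0, 0.5] rather
  than clumping at multiples of 1/n_founders. Defaults (4 founders,
  ld_decay 1e-5/bp) were calibrated once against the emulated cohort's
  published LD profile — r² falling below 0.2 at roughly 34 kb — giving
  mean r² ≈ 0.38 under 10 kb and ≈ 0.20 in the 25–45 kb band. Density
  defaults are 5 chromosomes × 400 markers over 2 Mb (≈ 5 kb spacing,
  the same order as the 777k-SNP bovine array's 3.4 kb). The founder
  pool is forced polymorphic at every marker so the realized marker
  count equals the configured one.
* **Annotation.** Genes are placed one per slot of an even chromosome
  tiling (guaranteed non-overlap), with 1–3 nested exons each split into
  CDS and terminal UTR parts, and written as valid GFF3.
* **Phenotypes.** trait = 100 + fixed effects + genetic value + N(0, σ²ₑ).
  Architectures: `snp_additive` (effects on SNP dosages),
  `haplotype_qtl` (effects on the distinct haplotype alleles of
  multi-SNP windows — in complete LD with the window's allele counts but
  with no single SNP), `epistatic` (effects on unordered state pairs of
  haploblock pairs, the exact configuration the categorical-epistasis
  kernel measures), and `mixed`. Effects are standard normal; σ²ₑ is set
  from the realized genetic variance so var(g)/(var(g)+σ²ₑ) equals
  `h2_target` (default 0.4, the range the emulated traits span). Fixed
  effects (sex, year, two covariates) are rescaled to explain 20% of
  phenotypic variance so the adjustment step has real work to do. Truth
  (genetic values, QTL placement and effects, realized h²) is recorded,
  never assumed.
* **What is not emulated:** demographic history, selection, pedigree,
  allele-frequency/effect-size coupling, genotyping error, unphased or
  missing data, sex chromosomes. Passing tests therefore demonstrate
  correctness of the machinery and reproduction of the method's
  qualitative behaviour under matched architectures — not performance on
  real cattle data.

## Problem sizes in the test suite

The heavy checks run at deliberately reduced scale chosen to keep the
suite quick while leaving enough signal: heritability recovery uses 20
cohorts of n = 800, m = 2000; the directional model comparisons use
n = 500, m = 2000 with 20 CV replicates and a 0.02 tolerance on mean
accuracy differences. At these sizes a full 9-kernel comparison is a
matter of seconds per kernel.

## Known limitations

* Single-kernel REML only; multi-kernel and multi-trait models are out
  of scope, as are Bayesian marker-effect models.
* The h² search bracket excludes exact 0 and 1; truly degenerate traits
  surface as flagged boundary estimates.
* The epistasis kernels model first-order (pairwise) interactions only.
* IGR derivation requires chromosome lengths; features beyond the stated
  length are an error rather than a truncation.
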