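# Methods

This note documents the statistical models, the synthetic-data generators
that stand in for real single-cell, snATAC and GWAS inputs, the numerical
choices, and the limits of what the package's tests demonstrate.

## Expression specificity and gene sets

Counts are normalized per cell to 10 000 (CP10K) before per-type
averaging, which makes the specificity score exactly invariant to per-cell
sequencing depth; whether to average raw or normalized expression is a
config switch (`SpecificityScorer(normalize=...)`, default normalized,
since the ratio is otherwise dominated by deeply sequenced cells).
The uninformative-gene filter retains genes expressed (count ≥ 1) in at
least `min_cells = 10` cells with total count ≥ `min_total = 50`; both are
plain, transparent thresholds chosen in place of the external filtering
procedure real analyses cite, and both are configurable. Genes overlapping
the excluded region (the MHC role, 1-based inclusive interval; hg38
chr6:28,510,120–33,480,577 in real data) are dropped for their extreme LD.
Decile ranks are stable: ties break by gene order, decile sizes differ by
at most one, and decile 10 is the most specific. Down-sampling equalizes
populations to the smallest one and is the identity when sizes are already
equal, avoiding gratuitous randomness.

## Gene-level association and the competitive test

The gene statistic is the mean χ² over SNPs in the strand-oriented
extended window (+35 kb upstream / −10 kb downstream; the windowing used
with the competitive-test family). Under the null, the sum of correlated
1-df χ² variables is the eigenvalue mixture `Σ λ_i χ²₁`, λ from the SNP
correlation matrix estimated on the same panel. The upper tail is
approximated by a scaled χ² matched to the mixture's first three cumulants
(`κ_r = 2^(r−1)(r−1)! Σλ^r`). A two-moment (Satterthwaite) gamma was
evaluated first and rejected: at three-sigma totals its relative error
against a 10⁶-draw Monte-Carlo mixture oracle reaches ~24 % for long
AR-type spectra, while the three-cumulant fit stays within ~8 % everywhere
tested (and is exact for one SNP and for independent SNPs). Mean-χ² is the
only implemented gene model (the cited tool's default; top-SNP and
multi-model variants are not reproduced).

The competitive regression is OLS of `Z = Φ⁻¹(1−p)` on an intercept, the
focal-set indicator, any conditioning-set indicators, log window length
and log SNP count (a deliberately small covariate set; SNP density and
inverse-MAC refinements are untestable at this scale). Significance is the
upper tail of the focal t statistic. Degenerate designs — empty or
all-gene focal sets, a conditioning set equal to the focal set, collinear
indicators — raise errors rather than returning numbers.

## Stratified LD-score regression

The model is `E[χ²_j] = N Σ_c τ_c ℓ(j,c) + intercept`, intercept always
free so attenuation and confounding are absorbed. LD scores sum the
bias-adjusted `r̃² = r² − (1−r²)/(n−2)` over SNPs within a 1 Mb physical
window (the synthetic genome has no genetic map, so bp stands in for cM);
the self pair is included. Regression weights are the single-step proxy
`1/max(1, ℓ_base)²` — the reference method's iterated
heteroskedasticity-and-overcounting weighting is deliberately simplified,
and calibration of the simplification is established by simulation (null
intercept within CI of 1, τ CIs covering 0, h² CI coverage 0.94–1.00 at
the tested scale). Standard errors come from a delete-one contiguous-block
jackknife (default 200 blocks, clamped to ≥ 2 SNPs per block); annotation
counts are constants, so h², per-category h² proportions and enrichment
are recomputed per delete from the jackknifed coefficients. Enrichment of
the base category is identically 1. One-tailed category p-values use the
upper normal tail of τ/SE. The joint OCR analysis fits the focal cell
type's peaks together with the synthetic baseline and the union of all
cell types' peaks, after removing SNPs in the excluded region.

The baseline is a small synthetic stand-in for the 53-annotation v1.2
baseline of real analyses: the all-SNPs base, a genic ±35 kb category and
two random contiguous-interval categories (~15 % of SNPs each). Real
baseline files are external data and out of scope.

One measurable consequence of the adjusted estimator: `ℓ(j, base)` can
fall below a subcategory's score by a small zero-mean noise margin
(observed ≲ 0.15), because complement-SNP terms are noise around zero.
The dominance invariant holds exactly in expectation and for population
scores.

## Open chromatin

Peak calling aggregates a cell type's pseudo-cell fragment counts per
200 bp bin and tests each bin against a Poisson null whose rate is the
maximum of the genome-wide mean and centered local-window means (5 kb and
10 kb), the local-background logic of fragment-pileup callers, then
applies BH across bins and merges adjacent significant bins. Peaks carry
−log₁₀ of their best bin p and the minimum bin q. Context annotation uses
precedence promoter > exonic > intronic > distal, with the promoter the
strand-oriented −1000/+100 bp window around the TSS; without an exon table
the gene body collapses into the intronic context (supply `exons=` for the
full four-way split on a real GTF). Peaks from different cell types are
"shared" on ≥ 1 bp overlap. Credible-set SNP rows carry the list of cell
types whose peaks contain the SNP — one row per SNP, not per (SNP, type).
Co-accessibility normalizes pseudo-cell peak counts to 10 000, applies
log1p, and computes Pearson correlations for every distal–promoter pair
with midpoint distance ≤ 100 kb on one chromosome, BH-corrected over
tested pairs; zero-variance peaks are skipped with a warning. Pseudo-cell
aggregates are taken as given (the reference k-NN metacell construction is
not reproduced), and the correlation estimator is this package's recorded
definition, since upstream tools do not document theirs.

## Trajectory (Moran's I)

The cell graph is a union-symmetrized binary k-NN graph (default k = 15)
on any embedding — a deliberate stand-in for principal-graph
neighborhoods; the statistic is unchanged, only the graph differs. The
analytic null uses the randomization-assumption mean `−1/(n−1)` and
variance, but the plain normal tail is not used: on sparse graphs at
n ≈ 60 the null of I is right-skewed (skewness ≈ 0.7) and a normal tail
misses a 10⁴-permutation oracle by up to 0.05. The implemented tail is a
Pearson-III (three-moment) approximation whose skewness comes from the
exact moments of the quadratic-form ratio `z'Az/z'z` for spherical normal
z (A the doubly-centered, scaled weight matrix) — a graph property,
computed once per graph — bringing agreement with permutation to ≲ 0.005.
The permutation null remains available as the always-valid oracle. The
test is one-sided for positive autocorrelation; zero-variance genes are
flagged and excluded from the BH correction, and all tested genes enter
BH (no pre-filtering).

## Synthetic data: what it emulates, and what it does not

*Genome*: equal-length chromosomes with uniformly placed, possibly
overlapping genes (1-based inclusive coordinates); no exon structure by
default.

*LD panel*: latent-Gaussian AR(1) within fixed-length blocks, thresholded
at each SNP's MAF quantile (MAF uniform in (0.05, 0.5]); blocks
independent. Each block draws its own autoregression parameter from a
range (default 0.4–0.98): real genomes mix weak- and strong-LD regions,
and heterogeneous LD gives LD scores the spread the regression needs —
with homogeneous LD their spread is comparable to estimation noise and
errors-in-variables attenuation swamps τ. The generator also computes the
model's *population* block correlations analytically (bivariate-normal
orthant probabilities via Owen's T); GWAS simulation treats these as
generative truth, so the haplotype sample plays its real role of a noisy
reference that the bias-adjusted r̃² estimator targets. Monomorphic draws
are repaired by a single deterministic haplotype flip.

*GWAS*: per-SNP effects Gaussian with variance proportional to the causal
annotation (and optional per-SNP weights planting a target enrichment:
inside/outside variance ratio `E(1−f)/(1−Ef)` for annotation fraction f);
marginal z per block is `√N·Rβ + MVN(0, R)`. The drawn effect vector is
rescaled so the realized total marginal signal equals its expectation —
the usual variance-reduction step in heritability simulators; without it
the realized signal is heavy-tailed under strong LD (near-rank-1 blocks
contribute ~χ²₁-scaled draws) and jackknife CIs undercover on low draws.
No phenotype-level simulation, population structure, or imputation error.

*Expression*: gamma-Poisson (negative binomial, size 2.0) counts with a
lognormal gene-mean profile scaled to ~2000 UMI/cell, gamma library-size
multipliers with CV 0.3, disjoint marker sets per type at fold-change 8,
two subtypes per type (level-2 labels) and alternating batch labels.
Real data's batch effects, ambient RNA, doublets and label noise are not
modeled, so passing tests show the statistics behave as designed on clean
structure — not robustness to those artifacts.

*ATAC*: Poisson bin counts, background rate 2/bin, planted bin-aligned
non-overlapping truth peaks at 10× background, a stated fraction shared by
all types; optional planted co-accessible pairs place a promoter-adjacent
and a distal peak (20–80 kb away) whose rates share a gamma latent
activity per pseudo-cell (CV 0.8). Fragment-length structure, Tn5 bias
and doublets are not modeled.

*Credible sets*: nearest-SNP sets around a lead SNP, symmetric
Dirichlet(1) posteriors sorted so the lead carries the largest mass (no
generative fine-mapping model exists to copy); a stated fraction of leads
is seeded inside truth peaks.

*Trajectory*: a 1-D latent pseudotime embedded with small orthogonal
noise; gradient genes vary linearly along it.

## Study scales and determinism

Every generator is a pure function of its parameters and an integer seed.
Default pipeline conditions: 2 × 12.5 Mb chromosomes, 200 genes, 5000
SNPs, 500 haplotypes, 50 kb LD blocks (1000 independent blocks keep
block-level signals in the CLT regime for the jackknife), 6 cell types ×
60 cells, GWAS N = 50 000 with h² = 0.4, 4 ATAC cell types × 20
pseudo-cells with 120 peaks each. Statistical acceptance checks use 20–50
seeds per claim and 500 replicates for test calibration; Monte-Carlo
oracles use 10⁶ draws (gene p) and 10⁴ permutations (Moran's I). A full
pipeline run takes a few seconds; the whole test suite runs in about two
minutes on one CPU.

## Known limitations

- LD is blockwise-independent and map-free; nothing is claimed about
  cross-block LD leakage, genetic-map windows, or real 1000G panels.
- The regression weights are a calibrated simplification, not the
  reference implementation's iterated scheme; absolute τ SEs differ from
  that scheme even where calibration matches.
- Allele munging is strict identity: no strand flips, no allele matching
  beyond the panel's own tables.
- The peak caller works on binned coverage; fragment-level effects
  (duplicates, insert-size structure) are out of scope.
- Level-2 (subtype) labels exist in the generator but carry no extra
  marker structure by default; subtype-resolution claims are exercised
  only through label plumbing.
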