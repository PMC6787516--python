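# Methods

This note records the models and procedures `coexnet` implements, the
defaults and why they are set as they are, what the synthetic benchmark
does and does not emulate, and the numerical conventions used throughout.

## Data model

The universal input is a complete, log-scale genes × samples matrix with a
two-level phenotype label per sample and optional clinical trait columns
(binary indicators or ordered scores). Probe-level matrices are collapsed
to gene level by per-sample arithmetic means over each gene's probes.
Probe rows with under 10% missing cells are mean-imputed per row; rows
with more are dropped — downstream correlation requires complete data, and
row-mean imputation at that rate perturbs correlations negligibly.
Categorical traits are one-hot encoded per level (e.g. `GOLD_4`,
`DLCO_S`), because module–trait analysis correlates eigengenes with
individual levels, not with an assumed linear coding of the category.

## Rank-product differential expression

The filter contrasts the two phenotype groups with the rank-product
statistic: K between-group sample pairs are drawn, the per-gene log-ratio
of each pair is ranked across genes (ascending for down-, descending for
up-regulation, ties averaged), and RP_g is the geometric mean of a gene's
ranks. The permutation null shuffles gene labels independently within each
comparison and pools the permuted RP values; p is the pooled fraction at
or below the observed RP, and the two-sided p doubles the smaller
one-sided p.

The comparisons are a seeded **disjoint** pairing — each sample appears in
at most one pair, K = min(n1, n2, cap) with cap 50. This is deliberate:
with all n1·n2 pairs, comparisons share samples and a gene's ranks are
strongly correlated across comparisons, while the within-comparison
permutation null treats them as independent; the resulting false-positive
rate at α = .05 was measured at ~0.29 under a global null. With disjoint
pairs the independence assumption actually holds and the measured null
false-positive rate falls inside the 99% binomial band around 0.05
(0.036–0.068 across replicates), with essentially full power for 2-SD
mean shifts at 30+30 samples. The pairing is derived from the two sample
*sets*, not from which label comes first, so relabelling the groups swaps
(RP_up, p_up) with (RP_down, p_down) exactly. Default 1000 permutations;
a seed is mandatory.

The filter applies the raw two-sided P < .05 rule. The
false-prediction-percentage layer of the wider rank-product literature is
intentionally out of scope.

## Coexpression arm

**Soft threshold.** Unsigned adjacency a_ij = |cor|^β. Candidate powers
1–20 are scanned on a seeded subsample of up to 5000 genes; for each β the
connectivity k_i = Σ_{j≠i} a_ij is binned into 10 equal-count bins, the
log10 frequency *density* (count / (N · bin width)) is regressed on the
log10 mean connectivity per bin, and the signed fit is −sign(slope)·R².
Density rather than raw frequency is used because equal-count bins have
constant counts by construction; for an exact power law the density is
exactly log-log linear, so the fit reaches 1. The chosen power is the
smallest candidate with fit ≥ 0.85 (the conventional target); if none
reaches it the pipeline falls back to the best-fitting power with a
warning. Bins with fewer than 2 points or zero width are skipped; fewer
than 3 usable bins marks the fit undefined for that power.

**TOM and clustering.** TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij),
computed by matrix multiplication with the diagonal excluded and the
denominator guarded at 1e-12; genes are clustered by average linkage on
1 − TOM (scipy implementation).

**Module detection** is a hybrid dynamic cut in four steps: (1) cut the
tree at a height (default 99% of the maximum merge height — the dynamic
tree cut convention; the differential arm instead uses its fixed published
height); (2) dissolve branches below the minimum size (50) to grey;
(3) reassign each grey gene to the module with the nearest medoid if that
dissimilarity is under the cut height; (4) membership cleanup: a gene
stays in its module only if |kME| ≥ 0.5 with the module eigengene, i.e. it
shares at least a quarter of its variance with the module's summary
profile, and modules that fall below the minimum size dissolve to grey.
Step 4 exists because height-based branches and medoid reassignment are
deliberately permissive and pick up weakly attached background genes;
membership is ultimately a kME notion, and the 0.5 core threshold is the
established convention in the reference implementation of this style of
analysis. Correctness of the whole procedure is defined by
planted-partition recovery on the benchmark, not by label-for-label
equality with any particular implementation.

**Eigengenes** are the unit-norm first right singular vectors of the
row-standardized module submatrix, sign-oriented so the mean correlation
with member genes is non-negative; zero-variance genes are excluded from
the decomposition. Modules whose eigengene dissimilarity 1 − cor(ME) is
at most the merge height (default 0.25) are iteratively unioned, and
undersized modules are absorbed into the module with the most correlated
eigengene, recomputing eigengenes after every merge until stable.

**Statistics.** All correlation p-values use the Student-t transform
t = r√(n−2)/√(1−r²) with df = n−2, two-sided; this closed form reproduces
the printed reference pairs (r=0.28, n=70 → P=.02; r=0.31 → .009;
r=0.34 → .004). Hub genes are ranked within modules by intramodular
connectivity with lexicographic tie-breaks. No exact permutation option is
provided in this arm.

## Differential-coexpression arm

Within-group Pearson correlation matrices feed the sign-aware
squared-correlation change d_ij = [½|sign(c¹)c¹² − sign(c²)c²²|]^(β/2),
which is treated as an adjacency, converted to TOM, and clustered by
average linkage with the hybrid cut at the published parameters: height
0.93, minimum size 20, eigengene merge height 0.2 (merging uses
pooled-sample eigengenes, since a differential module need not be coherent
in either single condition).

The softening exponent defaults to **β = 2**, i.e. the raw
half-absolute-difference of signed squared correlations. Large β values
(6 is common in applications at the scale of thousands of co-changing
genes) suppress all but near-maximal changes; TOM values scale with the
number of genes sharing a change, so at the scale of this package's
benchmark — a single 60-gene module changing among 2000 genes — a β of 6
pushes the within-block tree height to ≈0.98, above the 0.93 cut, making
any such module undetectable in principle. β stays configurable for
studies where a large differential fraction is expected.

Module significance: T_M = √(mean over member pairs of (c¹_ij − c²_ij)²),
with a null from randomly re-partitioning samples into groups of the
original sizes; p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm) (add-one
smoothing, so p is never 0). Modules under 3 genes are skipped. Gene-pair
output: all pairs with |δR| = ||R₁| − |R₂|| ≥ 0.7 (both signs, so a viewer
can colour by direction), by default restricted to genes in non-grey
modules, in canonical gene order.

## Enrichment

Upper-tail hypergeometric over-representation against GMT gene sets, with
sets intersected with the background first. The default background is the
set of genes that entered the network analysis, not the whole array; this
matches the question actually asked (is this module enriched relative to
what was analysed?). Raw p drives the top-20-at-P<.05 reporting rule;
BH q-values are reported alongside. GO graph propagation and annotation
retrieval are out of scope — gene sets are user-supplied.

## Synthetic benchmark

Each planted module m has a latent factor z per condition and per sample;
member genes are a·z + √(1−a²)·ε with ε standard normal, so the expected
within-module correlation is a² where the module is active and 0 where it
is not (a `cond1_only` module contributes pure noise in condition 2).
Traits are w·z + noise (noise SD defaults to √(1−w²), giving a
unit-variance trait); DE genes are background genes mean-shifted in
condition 2 in SD units. The standard benchmark (2000 genes, 35+35
samples, shared modules of 150/120/100/80 at loading 0.8, one 60-gene
condition-1-only module at loading 0.85, one trait coupled to module 1 at
weight 0.6, 50 genes shifted +1.5 SD) mirrors a two-phenotype microarray
study at desk scale: tens of samples per group, thousands of genes.

What it does **not** emulate: probe-level noise, batch effects,
normalization artifacts, correlated module factors (an extension point,
off by default), heavy-tailed expression, or overlapping modules. Passing
recovery tests therefore shows the machinery is correct under the model's
own assumptions — not that real tissue data will yield modules this clean.
Two practical notes from the benchmark itself: the pooled-sample
coexpression arm sees a condition-specific module only at pooled
correlation ≈ a²/2 and may legitimately leave it grey (the differential
arm is the instrument for it, and recovers it with Jaccard ≥ 0.8 and
dispersion p ≈ 0.005); and mean-shifted DE genes acquire pooled
correlation δ²/4 /(1+δ²/4) and can surface as a genuine pooled-data
module. Because the planted modules carry no mean shift, the benchmark's
network arms run on the unfiltered matrix; the DE filter precedes the
network arms in the pipeline's default (real-data) flow.

At a small scale the finite-sample null correlation matters: E|r| ≈
√(2/(π n)), about 0.135 at n = 35, so "near zero" claims about inactive
conditions are asserted at larger n in the tests.

## Determinism and numerics

One global seed drives every stochastic step; per-purpose generators are
derived as `default_rng([seed, tag])` with fixed tags so toggling one
stage does not shift another's stream. All TSV output uses a fixed float
format, making identical configurations byte-identical. Correlations are
clipped to [−1, 1]; zero-variance genes get correlation 0 with a warning;
TOM denominators are floored at 1e-12; p-values are floored at the
smallest positive double and capped at 1. Ties are broken
lexicographically by gene id everywhere a ranking is exported.

## Problem sizes

The shipped tests and the acceptance script run the benchmark at 2000
genes and 70 samples, calibration at 500 genes with 200 permutations, and
oracle checks at 25–50 genes — sizes chosen so the full validation suite
completes in well under a minute per arm on a single core while keeping
every statistical check adequately powered.
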