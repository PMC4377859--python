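# Methods

`isletkit` analyzes replicated knockout-vs-control bulk RNA-seq count
matrices from several mouse Cre strains — the motivating design is three
LKB1-null and two AMPK-null β-cell-targeted strains — and asks which genes
and gene programs each kinase represses in the β cell.  This note records
the models, the tunable parameters, and the design choices made where the
design was genuinely open.

## Expression quantification

Expression is reported as RPKM, `1e9 · C / (N · L)`, with `C` reads mapped
to the gene, `N` the sample's total mapped reads (column sum of the count
matrix) and `L` the transcript length in bp.  No between-sample
normalization (TMM, median-of-ratios) is applied: the pipeline works on
plain RPKM and on transcriptome proportions.

Fold changes are ratios of condition-mean RPKM with a pseudocount (default
0.5 RPKM; `fold_change(a, b, ε)·fold_change(b, a, ε) = 1` holds for any
ε > 0).  The pseudocount bounds log fold changes for genes detected in only
one condition.  A proportion-based fold change (pooled counts with a 0.5
count offset) is available via `de_table(..., fc_source="proportions")`;
RPKM means are the default.

Genes whose mean RPKM is below 1 in both conditions are flagged
low-expressed and excluded from testing and ranking by default
(`min_rpkm` is configurable).  Without a filter, pseudocount-dominated fold
changes of barely detected genes would produce unstable ranks.

## Differential expression

Each replicate count is modelled as beta-binomial: `C_s ~ BB(N_s, π, ρ_g)`
with `π` the gene's transcriptome proportion and `ρ_g` a per-gene beta
intra-class correlation.  The test is a likelihood-ratio test of a shared
`π` against free per-condition proportions, referred to χ²(1); with
`ρ = 0` it reduces exactly to the two-proportion binomial LRT (a property
the test suite verifies against an independent numeric maximizer on an
exhaustive grid of totals ≤ 50).

**Dispersion parameterization.**  Between-replicate biological variability
is summarized by a single study-level dispersion φ defined as the *squared
biological coefficient of variation* of a gene's relative abundance
(φ = 0.05 ⇒ ~22% replicate-to-replicate variation, for every gene).  It
maps per gene to the beta intra-class correlation as
`ρ_g = φ · π_g / (1 − π_g)`.  The alternative — one intra-class correlation
shared across genes — was rejected because it implies relative noise
`√(ρ/π)` that grows without bound as genes get rarer: at ρ = 0.02 a gene at
π = 1e−4 would vary by ±1400% between replicates, which neither matches
replicated islet RNA-seq nor leaves any power to detect the fold changes
this analysis targets.  The constant-CV model is the beta-binomial analogue
of a shared biological CV in count-GLM practice.

**Dispersion estimation** is method-of-moments: per gene and condition, the
excess of the replicate proportion variance over its binomial expectation,
relative to the squared mean proportion, estimates φ.  Per-gene estimates
from genes with mean count ≥ 10 are pooled with precision weights
`(μ/(1 + φ₀μ))²` (μ = mean count; φ₀ a median-based pilot), then truncated
to [0, 0.99].  In simulation the estimator recovers φ = 0.05 as ≈ 0.050
and φ = 0 as < 0.005 at 2000 genes.  With a single replicate per condition
the dispersion is not identifiable; the estimator returns 0 with a warning
and the test degenerates to the binomial LRT.

**Numerics.**  Proportion MLEs under the beta-binomial are found by
golden-section search on logit(π) with a fixed 100-iteration budget,
vectorized across all genes; the log-likelihood curvature on that scale is
of order of the total count, so the budget delivers machine-level accuracy.
The binomial case uses the closed form Σc/Σn.

**Significance.**  Raw p-values come from the χ²(1) reference.  This is
slightly anti-conservative for very small counts and extreme dispersion
(the usual LRT caveat); at the design conditions used here (depth ~1e6,
3+3 replicates, φ ≤ 0.05) the measured type-I error at α = 0.05 is 0.048
and null p-values pass a Kolmogorov–Smirnov uniformity check.  The
BH-adjusted p-value is reported as the gene's **E-value** alongside the raw
P, matching the E/P vocabulary of cross-model reporting.  Genes with zero
counts in every replicate of both conditions are *absent* for that model
and carry no fold change, p or E.

## Gene set enrichment

Genes are ranked by fold change: *absolute* mode by |log2FC| descending
(up- and down-regulated genes both at the top), *signed* mode by log2FC
descending.  Metric ties break lexicographically by gene ID so rankings are
reproducible.  The running sum rises by a set member's `|metric|^w` share
(normalized over in-set genes) and falls by `1/(N − N_hit)` at non-members;
the enrichment score is the signed extremum.  `w = 1` (the standard
weighted form) is the default, `w = 0` gives the classic Kolmogorov–Smirnov
form; both are exercised in tests.  When the positive and negative extrema
tie in magnitude to numerical precision (1e−12), the positive one is
returned, deterministically.

The null distribution shuffles gene labels, implemented as drawing random
same-size gene sets from the ranked universe — mathematically identical and
much cheaper at B = 10,000 shuffles.  The empirical p uses the add-one
convention, `p = (1 + #extreme) / (B + 1)`, so p ≥ 1/(B+1) and zero
p-values cannot occur.

**Tail convention.**  A one-sided p against a *fixed* tail is exactly
uniform under an exchangeable null (measured KS distance from uniform 0.02
at B = 199 over 1000 replications).  Selecting the tail from the observed
ES's sign is the natural reading for signed rankings but is selective —
up to twofold anti-conservative under the null (measured KS 0.47).
`gsea_suite` therefore defaults to the upper tail in absolute mode (where a
negative ES means depletion of change, not enrichment) and to the
observed-sign tail in signed mode, reporting the tail per set; both are
overridable via `side=`.

Across tested sets, empirical p-values are Benjamini–Hochberg adjusted and
a set is called significant at FDR ≤ 0.30 (configurable).  A 30% FDR is
deliberately permissive; beside strongly enriched sets BH will let some
random sets through, bounded in expectation, and overlapping sets make
p-values positively dependent (BH remains valid under PRDS).  Sets with no
overlap with the ranked list are reported as skipped, not errors.

## Cross-model concordance

A gene counts as *changed* in a model when it is significant (E < 0.1 or
P < 0.05) and its fold change is ≥ 1.4 (up) or ≤ 1/1.4 ≈ 0.714 (down) —
the fold threshold is inclusive, and down-regulation is expressed as a
fractional fold.  A gene passes the filter when it is changed in the index
model and at least `min_further_models` (default 1) of the corroborating
tables show a same-direction change under the same criterion.  The same
significance-plus-fold rule is applied to the index model by symmetry
(`apply_to_index=False` disables this).  Genes absent from a model never
corroborate.  Tightening any threshold provably yields a subset of the
looser run's passers, which the suite checks.

The gene × model table of statuses and signed log2 fold changes serializes
to TSV and renders as a heat map (red up, blue down, gray absent), rows
ordered by the index model's signed log2FC (1 = most induced).
`overlap_counts` reports, for the top-k most induced index genes, their
status per other model and how many are concordant in at least m of the M
other models.

## Annotation

**Tissue classes.**  A gene's home class is the tissue class whose mean
expression exceeds the mean over all other tissues by a factor (default 5;
the max-ratio class wins when several qualify), or "none".  Fractions of a
gene list per class are reported as percentages rounded half-up to two
significant figures (27/55 → 49%, 5/55 → 9.1%).

**Promoter TFBS.**  Per transcription factor, motif hits in the submitted
promoters are compared with the genome-wide rate via a Poisson upper tail,
`p = P(X ≥ k)`, `X ~ Poisson(n_submitted · K / G)`.  A Poisson rate model
(not binomial/hypergeometric) is used because motif hits are not capped by
the region count — a factor can hit one promoter several times.  Factors
are ranked by −log10 p, ties by hit count then name.  A genome-hit count of
0 with submitted hits gets a rate floor of 1e−12 and a warning.

**Generic over-representation** of a list against an annotation term is the
one-sided hypergeometric upper tail; `mode="ease"` removes one success
(P(X ≥ k−1)), the conservative DAVID-style variant, and is never smaller
than the Fisher p.

## Synthetic data

The generator emulates the five-strain study: per model, replicated KO/WT
libraries of ~1e6 reads over 2000 genes (defaults).  Baseline abundances
are lognormal(0, σ=2) normalized to proportions — long-tailed like islet
transcriptomes, which stresses ranking code across the dynamic range.
Planted groups (defaults: 40 "neuronal" and 15 "hepatic" genes at 3-fold in
LKB1-null models; 16 "disallowed" genes at 2.5-fold in AMPK-null models; a
12-gene core at 4-fold in all models) multiply KO proportions, which are
then renormalized — so unplanted genes carry a small compositional
counter-shift, as in real data.  Absence is a per-(gene, model)
Bernoulli(0.05) event applied before sampling; absent genes are all-zero
and excluded from DE rather than treated as zero expression.  Replicate
counts are beta-binomial with the constant-CV dispersion above (default
φ = 0.05); φ = 0 degenerates to binomial.  Gene sets (planted groups plus
uniform-random null sets), a tissue atlas with known home classes
(enrichment factor 10, lognormal noise sd 0.5), and promoter hit tables
(lognormal genome-hit counts, Poisson submitted hits, planted rate
multipliers) come with ground-truth records for recovery tests.

What the generator does **not** emulate: length- or GC-dependent bias,
library-preparation batch effects, per-gene dispersion heterogeneity,
correlated gene programs beyond the planted groups, unbalanced replicate
numbers, or single-cell structure.  Passing recovery tests therefore shows
the pipeline is correct and well calibrated *under its own model
assumptions*; it does not certify performance on data violating them.

## Reproducibility and problem sizes

A single study seed feeds a deterministic per-stage seed derivation
(SHA-256 of `seed:stage-name`, reduced below 2³¹), so every stage is
reproducible in isolation and two runs of the pipeline with the same
configuration are bit-identical — the suite asserts byte equality of whole
report bundles.  Output tables are TSV with a version header comment;
manifests record configuration, derived seeds and SHA-256 checksums of
every file.

Validation problem sizes were chosen to give tight Monte-Carlo bands at
interactive runtimes: 2000 genes × 1e6 reads × 3+3 replicates per model for
recovery; 5000 genes for type-I calibration; 1000 replications at B = 199
for permutation-p uniformity; 100 seeded studies at B = 1000 for the
planted-set GSEA recovery rate; exhaustive enumeration (all subsets of
lists up to length 8; all count pairs on totals up to 50) for the oracle
equivalences.

## Known limitations

- The χ²(1) reference is asymptotic; at very low counts p-values are
  mildly discrete/conservative, and at extreme dispersion with few
  replicates the LRT can be anti-conservative.  A parametric bootstrap
  would fix both at substantial cost; calibration is instead asserted at
  the design conditions.
- One shared dispersion across genes (a single CV) ignores per-gene
  dispersion differences; genuinely hypervariable genes will be
  over-called.
- The concordance filter treats models symmetrically on a common fold
  scale and does not combine evidence across models into a joint p-value
  (no Fisher/Stouffer meta-analysis).
- Tissue classification uses a hard mean-ratio rule; partial specificity
  (e.g. a gene high in two classes) maps to the max-ratio class or "none".
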