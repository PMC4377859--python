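# isletkit

Cross-model knockout islet transcriptomics: a tested, reusable pipeline for
asking which genes and gene programs a kinase represses in the pancreatic
β cell, by comparing replicated knockout-vs-control bulk RNA-seq count
matrices across several mouse Cre strains (e.g. three LKB1-null and two
AMPK-null β-cell-targeted models).

It is a library first — `import isletkit` and the scripts in `examples/`
are the main interface — with a thin `isletkit` CLI for running stages from
a shell.  Everything is seeded and deterministic: the same configuration
reproduces a report bundle bit-for-bit.

## What it computes

- **Expression**: RPKM = 10⁹·C/(N·L) per gene and sample; fold changes on
  condition-mean RPKM with a 0.5-RPKM pseudocount; a mean-RPKM < 1
  low-expression filter.
- **Differential expression**: a beta-binomial likelihood-ratio test per
  gene (replicate counts `BB(N_s, π, ρ_g)`; H₀: shared π, χ²(1) reference;
  ρ = 0 reduces to the binomial LRT), with a method-of-moments study
  dispersion (squared biological CV of replicate abundance) and
  Benjamini–Hochberg-adjusted p-values reported as **E-values**.
- **GSEA**: genes ranked by fold change (absolute |log2FC| or signed),
  weighted running-sum enrichment score per gene set, empirical p from
  10,000 gene-label shuffles (add-one convention), BH FDR across sets,
  significance at FDR ≤ 30%.
- **Cross-model concordance**: a gene passes when it changes significantly
  (E < 0.1 or P < 0.05) by ≥ 1.4-fold in the index model and shows a
  same-direction change meeting the same criterion in ≥ 1 further strain;
  gene × model heat-map matrix with absence marked; top-k overlap counts.
- **Annotation**: tissue-class assignment from an expression atlas (class
  mean ≥ 5× the rest) with class fractions rounded to two significant
  figures; promoter TFBS over-representation via a Poisson upper tail
  ranked by −log10 P; Fisher/EASE over-representation for generic terms.
- **Synthetic data**: a seeded five-strain study generator with planted
  neuronal/hepatic/disallowed/shared gene groups, overdispersed
  beta-binomial counts, per-model gene absence, gene sets, a tissue atlas
  and promoter hit tables — each with ground truth, so the whole pipeline
  is validated end-to-end by recovery tests.

See `docs/methods.md` for the models, parameter defaults and design
rationale.

## Worked example

```sh
python examples/02_differential_expression.py
```

prints (seed 1 of the synthetic five-strain study):

```
dispersion estimate: 0.0502 from 1586 genes (simulated at 0.05 -> ~22% replicate CV)

2000 genes, 1841 tested after the low-expression filter, 96 absent

most significant genes (fc > 1 means up in KO):
  gene   fc        p        e  mean_rpkm_ko  mean_rpkm_wt
g01456 4.98 1.55e-14 2.86e-11           106          20.8
g01000 4.33 9.26e-12 8.52e-09           436           100
...
59 genes at E<0.1 and FC>=1.4; 58 of them are planted LKB1-responsive genes
```

The dispersion estimator recovers the simulated replicate variability
(0.050 vs the true 0.05); of the 59 genes called up/down at E < 0.1 with at
least a 1.4-fold change, 58 are genes the simulation actually perturbed.
`examples/04_cross_model_concordance.py` continues the analysis across all
five strains: the 12 most induced index-model genes are corroborated 12/12
and 11/12 in the other two LKB1-null strains but only ~6/12 in the
AMPK-null strains, and 60% of the concordant up-regulated genes classify as
neuronal in the synthetic tissue atlas — the planted structure, recovered.

The full pipeline runs from a YAML config:

```sh
isletkit run --config config.yaml --outdir results/run1 --seed 1
```

producing per-model DE tables, per-model GSEA tables, the concordance
table and heat map, annotation fractions, the TFBS ranking, and a manifest
with per-file checksums.

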