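# oligogrn

Molecular subgrouping of histologically classified oligodendrogliomas and
inference of the gene regulatory network behind their expression
differences.

Histology alone misclassifies a fraction of oligodendrogliomas.  Copy-number
profiles separate these tumors into three molecular subgroups: **1p/19q**
(co-deletion of chromosome arms 1p and 19q with IDH1/2 mutation), **IDHme**
(IDH-mutation-enriched, no recurrent arm lesion) and **7a10d** (chromosome-7
gain plus chromosome-10 loss — the glioblastoma-like pattern).  This package
implements the full analysis chain for such cohorts, plus a synthetic-cohort
generator with planted ground truth so every stage is testable without any
external download:

1. **Subgrouping** — hierarchical clustering (Euclidean, complete linkage)
   of copy-number log2 ratios, a three-way dendrogram cut, arm-median-based
   subgroup naming, outlier flagging, per-subgroup mutation tables.
2. **Signature** — joint voom-style normalization of tumor and normal-brain
   RNA-seq counts (log2-CPM, cyclic loess, precision weights), weighted
   moderated t-tests with empirical-Bayes variance shrinkage
   (s²\_post = (d₀s₀² + d\_g s²\_g)/(d₀ + d\_g)), Benjamini–Hochberg
   q-values, signature = genes at q < 0.01; grade II-vs-III contrasts within
   subgroups.
3. **Characterization** — Pearson correlation of tumor log-ratios against
   reference class centroids; Kaplan–Meier curves with Greenwood 95% bands;
   log-rank tests; one-sided Fisher enrichment of the signature by
   direction.
4. **Network inference** (the core) — per signature gene, LARS-lasso
   regression of expression on its own copy number plus all signature-TF
   expression, screened sequentially by the covariance test
   T\_k = (⟨y, Xβ(λ\_{k+1})⟩ − ⟨y, X\_A β̃\_A(λ\_{k+1})⟩)/σ² with
   p = exp(−T) < 5×10⁻⁵; 100 random ⅔/⅓ train/test subsamples; consensus =
   links present in ≥75% of iterations, signed by majority coefficient
   sign; per-gene test-set prediction correlations; hub TFs (out-degree
   ≥ 10), modules and HOX/SOX family tables.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on a
synthetic 193-tumor cohort (133/45/15 per subgroup, 6000 genes, 150 TFs):

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_cnv_subgroups.py
python analysis/03_expression_signature.py
python analysis/04_subtype_survival.py
python analysis/05_grn_inference.py
```

Output (seed 0):

```
cohort: 193 tumors ({'1p/19q': 133, 'IDHme': 45, '7a10d': 15}), 6000 genes,
        8873 planted links, 2290 truly DE genes
subgroup sizes: {'1p/19q': 133, 'IDHme': 45, '7a10d': 15} (0 excluded)
adjusted Rand index vs planted subgroups: 1.000
  IDH1/2 mutated in 1p/19q: 133/133 (100%)
  IDH1/2 mutated in IDHme: 39/45 (87%)
  IDH1/2 mutated in 7a10d: 5/15 (33%)
signature: 2347 genes at q<0.01 (48% up / 52% down in 1p/19q vs IDHme)
grade II vs III within 1p/19q: 0 signature genes at q<0.01
grade II vs III within IDHme: 0 signature genes at q<0.01
centroid classification: 96% of tumors correlate highest with their own
        subgroup's centroid
log-rank 1p/19q vs 7a10d: chi2=44.13, p=3.08e-11
log-rank 1p/19q vs IDHme: chi2=0.40, p=0.525
log-rank 7a10d vs IDHme: chi2=42.41, p=7.42e-11
  cnv: median test correlation 0.055 (29% genes p<0.05; 1807 never modeled)
  cnv+exp: median test correlation 0.819 (98% genes p<0.05; 41 never modeled)
consensus: 2424 retained links; 61/61 hub TFs (out-degree >= 10)
  HOX genes in network: 4 ({'down': 4})
  SOX genes in network: 4 ({'up': 4})
```

Reading the numbers: clustering on copy number alone recovers the planted
subgroups exactly (ARI 1.0), with the expected mutation gradient
(IDH1/2 universal in 1p/19q, rare in 7a10d).  The expression signature
splits roughly evenly between up- and downregulated genes, and no grade
effect exists in this cohort (none was planted).  Survival separates the
glioblastoma-like 7a10d tumors from both IDH-mutant subgroups (p ≈ 10⁻¹¹)
while 1p/19q and IDHme do not differ — matching their equal planted
hazards.  The TF-expression network predicts held-out expression far better
than gene dosage alone (median r 0.82 vs 0.06), and the planted family
pattern (all HOX down, all SOX up in 1p/19q vs IDHme) is recovered in the
consensus network.

The same pipeline runs from a YAML config via the CLI
(`oligo-grn all --config run.yaml`), or on real matrices by passing
`cnv_path`/`counts_path`/`clinical_path`/`annotation_path` instead of a
`synth` section.

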