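# irlpair

Prognostic signatures built from **immune-related lncRNA pairs** for bulk
tumor expression cohorts, aimed at computational biologists who want a
platform-independent risk score: instead of absolute expression levels, the
signature uses only the *within-sample ordering* of gene pairs, so a model
fitted on RNA-seq can score microarray or qPCR samples without any
cross-platform normalization.

## What it computes

Given a genes × samples expression matrix (linear scale), a gene annotation
(lncRNA vs protein-coding), a clinical table (overall survival) and a curated
immune-gene list, the pipeline:

1. **Screens immune-related lncRNAs** by co-expression with the immune genes
   (Pearson |r| > 0.4, p < 0.001 on log2(x+1) values).
2. **Keeps those differentially expressed** between tumor and normal samples
   (Welch t-test, |log2FC| > 1, Benjamini–Hochberg FDR < 0.05) — the
   "DEirlncRNAs".
3. **Builds the binary pair matrix**: for each unordered pair (A, B) and
   tumor sample *s*, the score is `z = 1 if expr_s(A) > expr_s(B) else 0`.
   Pairs whose score-1 frequency lies outside [20%, 80%] carry too little
   rank variation and are dropped.
4. **Selects survival-informative pairs** in three stages: univariate Cox
   (Wald p < 0.05) → 10-fold cross-validated Lasso-Cox (minimum
   partial-likelihood deviance) → bidirectional stepwise multivariate Cox
   minimizing AIC. The risk score of sample *s* is

   `risk(s) = Σ_j β_j · z_j(s)`

   over the final pairs, with β the multivariate Cox log-hazard ratios.
5. **Dichotomizes patients** at the cut value maximizing Youden's J on the
   3-year time-dependent ROC (Kaplan–Meier cumulative-case/dynamic-control
   estimator), and validates the split by Kaplan–Meier curves, the log-rank
   test and Cox models testing independence from clinical covariates.
6. **Associates risk** with any external sample × feature table (immune-cell
   fractions, checkpoint-gene expression, per-drug IC50) by Spearman
   correlation or rank-sum tests, with raw and BH-adjusted p-values.

A fully seeded synthetic-cohort generator (`irlpair.simulate`) plants known
immune-correlated lncRNAs, differential expression and prognostic pairs with
exponential survival and uniform censoring, so every stage of the pipeline
can be verified against ground truth.

## Worked example

```python
import irlpair as il

cohort = il.simulate_cohort(il.SimulationConfig(seed=11))  # 400 tumors, 50 normals
res = il.run_pipeline(cohort.expression, cohort.annotation, cohort.clinical,
                      cohort.immune_symbols, cohort.groups,
                      il.PipelineConfig(seed=1))

print(len(res.irlnc_ids), len(res.de_ids), res.pair_matrix.n_pairs)
print(len(res.univariate_retained), len(res.lasso_selected), len(res.model.pairs))
print(round(res.rocs[3.0].auc, 3), f"{res.logrank_p:.2e}")
recovered = {p.label for p in cohort.truth.planted_pairs} & set(res.model.pairs)
print(f"{len(recovered)}/5 planted pairs recovered")
```

prints

```
80 60 1770
194 66 36
0.912 6.09e-35
3/5 planted pairs recovered
```

— of 200 lncRNAs, 80 pass the immune co-expression screen (all 80 planted
immune-linked ones), 60 are differentially expressed, and their 1,770
frequency-filtered pairs shrink to 194 → 66 → 36 through the three Cox
selection stages. The signature separates risk groups decisively on the
fitting cohort (3-year AUC 0.912, log-rank p ≈ 6e-35) and contains 3 of the
5 planted pairs directly (the others are represented by strongly correlated
partner pairs that share a gene with a planted pair — an expected feature of
rank-pair signatures, discussed in `docs/methods.md`).

The same stages are available from the shell:

```bash
irlpair simulate --out cohort --seed 11
irlpair screen --expr cohort/expression.tsv --annot cohort/annotation.tsv \
    --immune-genes cohort/immune_genes.txt --groups cohort/groups.tsv --out screen_out
irlpair pair --expr cohort/expression.tsv --genes screen_out/deirlncrna_ids.txt --out pairs.tsv
irlpair fit --pairs pairs.tsv --clinical cohort/clinical.tsv --seed 1 --out fit_out
irlpair score --model fit_out/model.json --expr cohort/expression.tsv --out risk.tsv
irlpair evaluate --risk fit_out/risk.tsv --clinical cohort/clinical.tsv --out eval_out
```

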