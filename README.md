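# reopair

Rank-based gene-pair diagnostics and metabolic-reprogramming analysis for
hepatocellular carcinoma (HCC) transcriptomes.

Cross-platform diagnostic signatures are hard to build from absolute
expression values: microarray and RNA-seq cohorts need normalisation that
rarely transfers. The relative expression ordering (REO) approach sidesteps
this by using only the within-sample ordering of two genes. For genes
G<sub>i</sub>, G<sub>j</sub> and a class of *n* samples,

    P(G_i > G_j) = (1/n) · Σ_z I[X_z > Y_z]
    P(G_i < G_j) = (1/n) · Σ_z I[X_z < Y_z]

with *I* the indicator function. A pair is **stable** in a class when one of
these probabilities exceeds 0.9 (strict), and a **stable reversal pair** when
it is stable in tumor samples in one direction and stable in normal samples
in the opposite direction. Reversal pairs are binarized (1 iff
G<sub>i</sub> > G<sub>j</sub> in that sample) into features that transfer
across platforms without normalisation.

Around this core the package implements the surrounding workflow used to
derive and evaluate such signatures from single-cell and bulk data:

- **`reopair.synthetic`** — generators for every input, with planted,
  analytically calibrated structure (order-reversed pairs, CNV clones,
  gene-set activity, survival hazards).
- **`reopair.cnv`** — cell QC (mito < 10%, hemoglobin < 3%, 200–8000
  detected genes), per-cell/cluster CNV scores on inferCNV-style matrices,
  secondary k-means with elbow + between-cluster-SS cluster-count selection,
  and nomination of the most aberrant (malignant) cluster.
- **`reopair.markers`** — malignant-cluster marker genes (Wilcoxon
  rank-sum, BH adjustment) intersected with metabolic gene sets (GMT).
- **`reopair.pathway`** — per-cell pathway activity by AUCell-style
  recovery-curve AUC and ssGSEA-style weighted running sums.
- **`reopair.reo`** — order probabilities, stable/reversal pair mining,
  binarized pair profiles.
- **`reopair.models`** — a grid of selector+classifier combinations over the
  nine base learners (Enet, GBM, SVM, RF, glm, plsRglm, Ridge, Lasso,
  rpart), ranked by mean AUC over training (out-of-fold) and validation
  cohorts.
- **`reopair.prognostic`** — univariate/multivariate Cox fits on the pair
  genes, median risk stratification, Kaplan–Meier/log-rank, Harrell's
  C-index, co-expression.
- **`reopair.pipeline` / `reopair.cli`** — end-to-end orchestration with a
  checksum manifest; the `reopair` command exposes each stage.

## Worked example

```sh
python examples/01_reversal_pairs.py
```

```
reversal pairs found: 42
planted pairs recovered: 10/10
gene_i gene_j tumor_direction  p_gt_tumor  p_lt_tumor  p_gt_normal  p_lt_normal
 G0000  G0001              gt        1.00        0.00         0.00         1.00
 G0000  G0005              gt        1.00        0.00         0.05         0.95
 ...
pair profile: 42 pairs x 200 samples (entries are 1 iff gene_i > gene_j)
```

All ten planted pairs are recovered at the 0.9 threshold (the extra pairs
are genuine reversals that form between planted genes with nearby
baselines). Feeding the binarized profile into the model grid
(`examples/04_diagnostic_grid.py`) ranks combinations by mean AUC:

```
        combo  rank  mean_auc  n_selected  auc_training  auc_validation1  auc_validation2
    Ridge+glm     1  1.000000           5        1.0000              1.0              1.0
plsRglm+Ridge     2  1.000000           6        1.0000              1.0              1.0
...
top combination: Ridge+glm with mean AUC 1.000
```

and `examples/05_prognostic.py` fits Cox models on the pair genes
(planted log-hazards +0.7/−0.5):

```
multivariate C-index: 0.702
median-split log-rank chi2 = 50.36, p = 1.28e-12
```

The remaining examples cover CNV clustering (`02`), pathway activity
(`03`), and the full pipeline with its checksum manifest (`06`), which is
also available from the shell:

```sh
reopair run --synthetic --seed 11 --outdir demo_run
```

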