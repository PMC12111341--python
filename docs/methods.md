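# Methods

## Relative expression ordering

For two genes and a class of samples the order probabilities are the
empirical frequencies of strict inequalities; ties contribute to neither
probability, so `p_gt + p_lt ≤ 1` with equality only in the absence of
ties. The stability cutoff is strict: a pair whose ordering holds in
exactly 90% of samples is *not* stable. Binarization maps ties to 0,
consistent with "1 iff G_i > G_j". These tie and boundary conventions are
deliberate fixed choices — the inequality-only definition of the indicator
leaves them open, and downstream results should not hinge on them because
ties have measure zero for continuous expression.

Pairs are stored in canonical orientation (gene_i lexicographically before
gene_j) with an explicit `tumor_direction` field, so (A,B) and (B,A) are a
single feature. Mining is done on pooled class samples; when multiple
cohorts are concatenated no cross-cohort normalisation is required because
only within-sample orderings enter the statistics.

When a validation cohort lacks one gene of a pair, the binary feature is
imputed with the majority value the pair takes across the pooled training
samples and the imputation is logged; this keeps a fitted model applicable
across platforms with incomplete gene coverage.

## Synthetic data

The generators produce the statistical structure each stage assumes, not
realistic sequencing data. Expression values are continuous log-scale
intensities (Gaussian noise around per-gene baselines drawn uniformly from
4–10); counts, UMI structure, dropout, doublets and batch effects are not
simulated. Consequently, passing tests demonstrate correctness of the
algorithms under their stated assumptions, not robustness to real-data
artefacts.

*Planted reversal pairs.* Within a pair the two genes share a baseline and
are offset by ±δ/2 with the sign flipped between classes, where
δ = √2·σ·Φ⁻¹(strength) calibrates the within-class order probability to the
target through the Gaussian difference CDF. The default strength 0.98 with
σ = 1 and 100+100 samples makes each planted pair detectable at the 0.9
threshold with probability ≈ 0.99. Because planted genes with nearby
baselines also reverse against each other, the mined set is typically
larger than the planted set; sensitivity is measured against the planted
pairs only.

*CNV matrices.* Each tumor clone carries one contiguous block of
`segment_length` genes shifted by ± its amplitude around the diploid
baseline 1, plus Gaussian noise; reference cells are pure noise. Block
starts are drawn uniformly but resampled toward pairwise-disjoint segments
(different clones aberrate different chromosomal regions); when the gene
axis is too short for disjoint blocks the draw falls back to the last
sample. Defaults (600 genes, segment 100, amplitudes 0.30/0.35/0.40, noise
0.01) put the clones at comparable pairwise distances — the regime in which
the elbow rule below identifies the true clone count — with amplitude gaps
of five noise standard deviations.

*Pathway cells and survival.* A chosen fraction of cells has the gene-set
genes up-shifted by a fixed effect. Survival times are exponential with
rate `baseline_rate·exp(Σ β_g z_g)` on z-scored expression and independent
exponential censoring; the default censoring rate used in the recovery
analyses (0.045 against baseline 0.1) yields ≈ 30% censoring.

## CNV scoring and cluster-count selection

A cell's CNV score is the mean squared deviation of its profile from 1,
and a cluster's score the mean over member cells; the highest-scoring
cluster is nominated as most malignant (ties break to the lowest cluster
ID). The squared-deviation form is the dominant convention for summarising
inferCNV-style output; it is quadratic in aberration amplitude and
invariant to gene order.

Cluster count: k-means (Lloyd, k-means++, 10 restarts, seeded) runs for
k = 1..k_max on tumor-cell profiles, recording within-cluster (WSS) and
between-cluster (BSS) sums of squares, which partition the total SS (the
suite verifies this to 1e-6 relative). k* maximises the WSS second
difference over interior k — the discrete elbow — with exact ties broken
toward the smaller k whose BSS share is within 0.01 of the next k's share.
A second-difference elbow identifies the true k when cluster separations
are comparable; with strongly unequal separations it conservatively merges
the two closest clusters, which is why the generator defaults place clones
near-equidistantly. Degenerate inputs (total SS ≈ 0) return k = 1 with a
warning.

## Pathway activity

Both scorers consume only within-cell rankings (1 = highest expression),
so they are invariant to monotone per-cell transforms. Rank ties are broken
by one random permutation drawn per run from the seeded generator —
deterministic, and unbiased across genes.

AUCell-style: the recovery curve counts set genes within the top
x = 1..T ranks, T = ⌈0.05·N⌉ by default; the score is the curve's area
normalised by the maximum achievable area, hence in [0, 1]. ssGSEA-style:
a walk down the ranking adds r^α (r the descending rank weight N..1,
α = 0.25) normalised by the in-set total at set genes and subtracts
1/(N−|set|) elsewhere; the enrichment score integrates the running sum over
all N positions. No cross-sample normalisation is applied because the
pipeline only compares scores between cell groups within one dataset. The
defaults (top 5%, α = 0.25) are the widely used ones; neither is sharply
critical for the group comparisons made here.

## Diagnostic model grid

Features are the binarized pair profiles (samples × pairs). The grid
contains each of the nine base learners alone plus every ordered
(selector, classifier) pair whose selector exposes usable coefficients or
importances (all but SVM): 9 + 8×8 = 73 combinations by default, and the
universe/grid mode are configurable. The selector is fit on training data
only; features surviving its importance threshold (non-zero coefficients
for L1 models, importance ≥ mean otherwise) are passed on, with a fallback
to all features if a selector eliminates everything. The PLS-GLM member is
implemented as PLS regression on the 0/1 label, with a component-count
back-off when deflation degenerates on separable binary features.

AUC is the normalised Mann–Whitney rank statistic (midranks for ties).
Training-cohort AUC is computed from out-of-fold predictions under a seeded
stratified 5-fold split — refitting selector and classifier inside each
fold — to avoid resubstitution optimism; validation cohorts are scored by
the model refit on the full training data, with pair features always
recomputed from each cohort's own within-sample orderings. Combinations
are ranked by the mean AUC over all defined cohort AUCs; exact ties break
by fewer selected features, then lexicographic name. All stochastic
fitters receive the run seed; hyperparameters are fixed library defaults.

## Prognostics

Binary pair features are unsuited to hazard modelling, so the genes
composing the reversal pairs enter the Cox models directly, z-scored,
with Efron tie handling. Constant genes are dropped with a warning;
univariate mode fits each gene separately and reports no model-level
C-index. The multivariate linear predictor is the risk score; samples
above its median are "high" risk (ties at the median go to "low", and an
all-equal score vector is an error). Groups are compared by Kaplan–Meier
curves and the k-group log-rank chi-square (k−1 df). Harrell's C counts
concordant usable pairs under right censoring with 0.5 credit for score
ties; the suite verifies it equals a brute-force pair enumeration and that
the model C-index equals C applied to the fitted risk scores. Each cohort
is split at its own median. Co-expression defaults to Spearman
correlation, with Pearson behind a flag.

## Pipeline and reproducibility

The synthetic pipeline chains QC → CNV clustering → markers ∩ metabolic
sets → reversal pairs → diagnostic grid → prognostics. One top-level seed
fans out to per-stage seeds via a SHA-256 hash of `"{seed}:{stage}"`
(truncated below 2³¹), so stages can be rerun in isolation. All artifacts
are plain text with floats at 10 significant digits; the manifest records a
config hash and per-file SHA-256 checksums, and two runs with the same seed
are byte-identical.

Problem sizes in the test and acceptance analyses (100+100 training
samples, 80+80 validation cohorts, 300-cell CNV matrices, 200 scored
cells, 300–500 survival samples, 10–20 replicate seeds) were chosen so each
planted effect is comfortably detectable while a full run of the suite
stays in the minutes range.

## Known limitations

- The grid's 73-combination default is one reasonable catalog over the nine
  learners; other selector/classifier compositions are expressible through
  configuration but not enumerated here.
- Training AUC is cross-validated by construction; pipelines that report
  resubstitution AUC will show higher training values on the same data.
- The elbow rule inherits the second-difference bias toward merging the two
  closest clusters when separations are strongly unequal.
- The marker test (Wilcoxon + BH, lfc > 0.25) is a standard single-cell
  default, not a tuned choice; with heavy-tailed real data its error
  control is approximate.
- Scores from the ssGSEA-style scorer are unnormalised enrichment sums and
  are comparable only within one dataset and gene-set size.
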