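"""Relative expression ordering (REO) of gene pairs.

The REO approach compares, within each individual sample, the expression of
two genes ``G_i`` and ``G_j``.  Because only the within-sample ordering is
used, the resulting features are invariant to any monotone per-sample
transform and therefore transfer across microarray and RNA-seq platforms
without normalisation.

For a class of samples (tumor or normal) the order probabilities are

    P(G_i > G_j) = (1/n) * sum_z I[x_z > y_z]
    P(G_i < G_j) = (1/n) * sum_z I[x_z < y_z]

where ``n`` is the number of samples in the class and ``I`` the indicator
function; ties contribute to neither probability.  A pair is *stable* in a
class when one of the two probabilities exceeds a threshold (default 0.9,
strict), and a *stable reversal pair* when it is stable in the tumor class in
one direction and stable in the normal class in the opposite direction.
Reversal pairs are binarized into a pairs x samples 0/1 profile
(1 iff ``G_i > G_j`` in that sample) which downstream classifiers consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


class InputError(ValueError):
    """Raised when an input matrix or vector violates a precondition."""


@dataclass
class LabeledExpressionMatrix:
    """Genes x samples expression with a tumor/normal label per sample.

    ``values`` is a DataFrame indexed by gene ID with sample IDs as columns;
    ``labels`` is a Series aligned to the columns with values in
    ``{"tumor", "normal"}``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InputError(f"duplicate gene ID: {dup!r}")
        if not self.values.columns.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise InputError("every sample needs a class label")
        bad = set(self.labels.unique()) - {TUMOR, NORMAL}
        if bad:
            raise InputError(f"unknown class labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def class_matrix(self, label: str) -> pd.DataFrame:
        """Columns belonging to one class."""
        return self.values.loc[:, self.labels == label]


@dataclass
class GenePairStat:
    """Order probabilities of one gene pair, per class.

    ``p_gt[c]`` is P(gene_i > gene_j) in class ``c``; ``p_lt`` the reverse.
    """

    gene_i: str
    gene_j: str
    p_gt: dict[str, float]
    p_lt: dict[str, float]
    tumor_direction: str = "gt"  # "gt": G_i > G_j in tumor; "lt": opposite


@dataclass
class ReversalPairSet:
    """Stable reversal gene pairs at a given probability threshold."""

    pairs: list[GenePairStat]
    threshold: float = 0.9

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_ids(self) -> list[str]:
        return [f"{p.gene_i}|{p.gene_j}" for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_i": p.gene_i,
                "gene_j": p.gene_j,
                "tumor_direction": p.tumor_direction,
                "p_gt_tumor": p.p_gt.get(TUMOR, np.nan),
                "p_lt_tumor": p.p_lt.get(TUMOR, np.nan),
                "p_gt_normal": p.p_gt.get(NORMAL, np.nan),
                "p_lt_normal": p.p_lt.get(NORMAL, np.nan),
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_i",
                "gene_j",
                "tumor_direction",
                "p_gt_tumor",
                "p_lt_tumor",
                "p_gt_normal",
                "p_lt_normal",
            ],
        )


@dataclass
class PairProfile:
    """Binary pairs x samples matrix: 1 iff expr(gene_i) > expr(gene_j)."""

    values: pd.DataFrame  # index: "gene_i|gene_j" pair IDs, columns: samples
    imputed: dict[str, int] = field(default_factory=dict)  # pair ID -> value used

    @property
    def pairs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def order_probability(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Empirical order probabilities (P(x>y), P(x<y)) over paired samples.

    Ties contribute to neither probability, so the two need not sum to 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and cover the same samples")
    n = x.size
    if n == 0:
        raise InputError("need at least one sample")
    p_gt = float(np.count_nonzero(x > y)) / n
    p_lt = float(np.count_nonzero(x < y)) / n
    return p_gt, p_lt


def _pair_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For a genes x samples block, count samples with row_i > row_j.

    Returns (gt, lt) integer matrices of shape (g, g); gt[i, j] counts samples
    where gene i exceeds gene j.  O(g^2 * n) by broadcasting; adequate for the
    candidate-gene universes this pipeline produces (hundreds of genes).
    """
    diff = values[:, None, :] - values[None, :, :]
    gt = np.count_nonzero(diff > 0, axis=2)
    return gt, gt.T


def find_stable_pairs(
    matrix: LabeledExpressionMatrix,
    class_label: str,
    candidate_genes: list[str] | None = None,
    threshold: float = 0.9,
) -> list[tuple[tuple[str, str], str]]:
    """Unordered candidate pairs whose within-class order holds in > threshold
    of samples; strict inequality at the threshold.

    Returns ``((gene_i, gene_j), direction)`` with genes in canonical
    (lexicographic) orientation; direction "gt" means gene_i > gene_j.
    """
    genes = _resolve_candidates(matrix, candidate_genes)
    block = matrix.class_matrix(class_label).loc[genes]
    if block.shape[1] == 0:
        raise InputError(f"no samples in class {class_label!r}")
    n = block.shape[1]
    gt, lt = _pair_counts(block.to_numpy())
    out: list[tuple[tuple[str, str], str]] = []
    g = len(genes)
    for a in range(g):
        for b in range(a + 1, g):
            if gt[a, b] / n > threshold:
                out.append(((genes[a], genes[b]), "gt"))
            elif lt[a, b] / n > threshold:
                out.append(((genes[a], genes[b]), "lt"))
    return out


def find_reversal_pairs(
    matrix: LabeledExpressionMatrix,
    candidate_genes: list[str] | None = None,
    threshold: float = 0.9,
) -> ReversalPairSet:
    """Mine stable reversal gene pairs.

    A pair qualifies when its ordering holds in more than ``threshold`` of
    tumor samples and the *opposite* ordering holds in more than ``threshold``
    of normal samples.  Pairs are reported in canonical orientation with both
    class probabilities attached.
    """
    genes = _resolve_candidates(matrix, candidate_genes)
    tum = matrix.class_matrix(TUMOR).loc[genes]
    nor = matrix.class_matrix(NORMAL).loc[genes]
    if tum.shape[1] == 0 or nor.shape[1] == 0:
        raise InputError("both tumor and normal samples are required")
    n_t, n_n = tum.shape[1], nor.shape[1]
    gt_t, lt_t = _pair_counts(tum.to_numpy())
    gt_n, lt_n = _pair_counts(nor.to_numpy())

    pairs: list[GenePairStat] = []
    g = len(genes)
    for a in range(g):
        for b in range(a + 1, g):
            pgt_t, plt_t = gt_t[a, b] / n_t, lt_t[a, b] / n_t
            pgt_n, plt_n = gt_n[a, b] / n_n, lt_n[a, b] / n_n
            if pgt_t > threshold and plt_n > threshold:
                direction = "gt"
            elif plt_t > threshold and pgt_n > threshold:
                direction = "lt"
            else:
                continue
            pairs.append(
                GenePairStat(
                    gene_i=genes[a],
                    gene_j=genes[b],
                    p_gt={TUMOR: pgt_t, NORMAL: pgt_n},
                    p_lt={TUMOR: plt_t, NORMAL: plt_n},
                    tumor_direction=direction,
                )
            )
    return ReversalPairSet(pairs=pairs, threshold=threshold)


def binarize(
    expression: pd.DataFrame,
    pairs: ReversalPairSet,
    training: LabeledExpressionMatrix | None = None,
) -> PairProfile:
    """Binarized pair profile of an expression matrix (genes x samples).

    Entry(pair, sample) is 1 when expr(gene_i) > expr(gene_j), else 0 (ties
    map to 0).  A pair whose genes are absent from ``expression`` is imputed
    with the majority binary value it takes across the training samples (both
    classes pooled) when ``training`` is given, else 0; each imputation is
    logged and recorded on the returned profile.
    """
    if len(pairs) == 0:
        raise InputError("no usable features: empty reversal pair set")
    rows: dict[str, np.ndarray] = {}
    imputed: dict[str, int] = {}
    n = expression.shape[1]
    usable = 0
    for p in pairs.pairs:
        pid = f"{p.gene_i}|{p.gene_j}"
        if p.gene_i in expression.index and p.gene_j in expression.index:
            xi = expression.loc[p.gene_i].to_numpy(dtype=float)
            xj = expression.loc[p.gene_j].to_numpy(dtype=float)
            rows[pid] = (xi > xj).astype(np.int8)
            usable += 1
        else:
            fill = _training_majority(p, training)
            logger.warning(
                "pair %s missing from matrix; imputing constant %d", pid, fill
            )
            imputed[pid] = fill
            rows[pid] = np.full(n, fill, dtype=np.int8)
    if usable == 0:
        raise InputError("no usable features: all pair genes missing")
    values = pd.DataFrame(rows, index=expression.columns).T
    values.index.name = "pair"
    return PairProfile(values=values, imputed=imputed)


def _training_majority(p: GenePairStat, training: LabeledExpressionMatrix | None) -> int:
    if training is None or p.gene_i not in training.genes or p.gene_j not in training.genes:
        return 0
    xi = training.values.loc[p.gene_i].to_numpy(dtype=float)
    xj = training.values.loc[p.gene_j].to_numpy(dtype=float)
    frac = float(np.mean(xi > xj))
    return int(frac > 0.5)


def _resolve_candidates(
    matrix: LabeledExpressionMatrix, candidate_genes: list[str] | None
) -> list[str]:
    if candidate_genes is None:
        genes = list(matrix.genes)
    else:
        missing = [g for g in candidate_genes if g not in matrix.genes]
        if missing:
            raise InputError(f"candidate genes absent from matrix: {missing[:5]}")
        # dedupe, preserve order
        genes = list(dict.fromkeys(candidate_genes))
    if len(genes) < 2:
        raise InputError("need at least two candidate genes")
    # canonical lexicographic orientation for pair enumeration
    return sorted(genes)
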