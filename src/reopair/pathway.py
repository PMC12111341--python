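"""Per-cell gene-set activity: ssGSEA-style and AUCell-style scorers.

Both scorers consume only the within-cell ranking of genes, so they are
invariant to any monotone per-cell transform of expression.

AUCell: rank genes by descending expression, build the set-gene recovery
curve over the top ``ceil(top_fraction * N)`` positions and normalise its
area by the maximum achievable area; scores lie in [0, 1].

ssGSEA: a weighted Kolmogorov-Smirnov-style running sum over the full
descending-expression ordering.  In-set genes add ``r^alpha`` (r the
descending-order rank weight N..1) normalised by the in-set total; out-of-set
genes subtract ``1/(N - |set|)``.  The enrichment score is the integrated
running sum over all N positions; no cross-sample normalisation is applied
because only within-dataset comparisons between cell groups are made.

Rank ties are broken by one random permutation drawn per run from the seeded
generator, making runs reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Pathways x cells activity scores for one method."""

    values: pd.DataFrame
    method: str  # "ssgsea" or "aucell"


def rank_genes_per_cell(expression: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per-cell ranks, 1 = highest expression.

    ``expression`` is cells x genes.  Ties are broken by a single seeded
    random permutation of the gene order, fixed for the whole run, so equal
    values get a deterministic but unbiased ordering.
    """
    if expression.shape[1] < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expression.shape[1])
    vals = expression.to_numpy(dtype=float)
    # lexsort: primary descending value, secondary the tie-break permutation
    order = np.lexsort((np.broadcast_to(perm, vals.shape), -vals), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(vals.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, vals.shape[1] + 1)
    return pd.DataFrame(ranks, index=expression.index, columns=expression.columns)


def aucell_score(
    ranks: pd.Series | dict[str, int], gene_set: list[str], top_fraction: float = 0.05
) -> float:
    """Normalised area under the set-gene recovery curve in the top ranks.

    ``ranks`` maps every universe gene to its rank (1 best) in one cell.
    With T = ceil(top_fraction * N), hits(x) counts set genes at rank <= x for
    x = 1..T; the raw area sum(hits) is divided by the maximum area
    sum(min(x, m)) with m the effective set size.
    """
    if isinstance(ranks, dict):
        ranks = pd.Series(ranks)
    n = len(ranks)
    eff = [g for g in gene_set if g in ranks.index]
    if not eff:
        raise ValueError("gene set has no overlap with the rank universe")
    t = math.ceil(top_fraction * n)
    if t < 1:
        raise ValueError("top_fraction too small: top window is empty")
    set_ranks = np.sort(ranks.loc[eff].to_numpy())
    xs = np.arange(1, t + 1)
    hits = np.searchsorted(set_ranks, xs, side="right")
    raw = float(hits.sum())
    m = len(eff)
    max_auc = float(np.minimum(xs, m).sum())
    return raw / max_auc


def ssgsea_score(
    ranks: pd.Series | dict[str, int], gene_set: list[str], alpha: float = 0.25
) -> float:
    """Integrated weighted-KS enrichment score for one cell.

    See the module docstring for the walk definition.  Errors when the set
    covers the whole universe (the out-of-set decrement is undefined).
    """
    if isinstance(ranks, dict):
        ranks = pd.Series(ranks)
    n = len(ranks)
    in_set = ranks.index.isin(set(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has no overlap with the rank universe")
    if m == n:
        raise ValueError("gene set equals the universe; out-of-set step undefined")
    order = np.argsort(ranks.to_numpy())  # positions walked best-rank first
    in_set_walk = in_set[order]
    weights = np.arange(n, 0, -1, dtype=float) ** alpha  # rank weight N..1
    inc = np.where(in_set_walk, weights, 0.0)
    denom = inc.sum()
    steps = np.where(in_set_walk, inc / denom, -1.0 / (n - m))
    return float(np.cumsum(steps).sum())


def score_all(
    expression: pd.DataFrame,
    collection: GeneSetCollection,
    method: str = "aucell",
    seed: int = 0,
    top_fraction: float = 0.05,
    alpha: float = 0.25,
) -> ActivityMatrix:
    """Score every cell x pathway with the chosen scorer.

    ``expression`` is cells x genes.  Genes absent from the expression
    universe are dropped from each set (count logged); a set with zero
    overlap is scored as missing with a warning.
    """
    if method not in ("ssgsea", "aucell"):
        raise ValueError(f"unknown method {method!r}")
    ranks = rank_genes_per_cell(expression, seed=seed)
    universe = set(expression.columns)
    out = np.full((len(collection.sets), expression.shape[0]), np.nan)
    for i, (name, genes) in enumerate(collection.sets.items()):
        eff = [g for g in genes if g in universe]
        dropped = len(genes) - len(eff)
        if dropped:
            logger.info("set %s: dropped %d genes absent from universe", name, dropped)
        if not eff:
            logger.warning("set %s has no overlap with expression; scored missing", name)
            continue
        for j in range(expression.shape[0]):
            cell_ranks = ranks.iloc[j]
            if method == "aucell":
                out[i, j] = aucell_score(cell_ranks, eff, top_fraction=top_fraction)
            else:
                out[i, j] = ssgsea_score(cell_ranks, eff, alpha=alpha)
    values = pd.DataFrame(out, index=list(collection.sets), columns=expression.index)
    return ActivityMatrix(values=values, method=method)


def cluster_mean_activity(
    activity: ActivityMatrix, assignment: pd.Series
) -> pd.DataFrame:
    """Mean activity per pathway x cluster (the per-cluster comparison table)."""
    assign = assignment.reindex(activity.values.columns)
    return activity.values.T.groupby(assign).mean().T
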