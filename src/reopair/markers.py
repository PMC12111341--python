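"""Cluster marker selection and intersection with metabolic gene sets.

The candidate gene universe for pair mining is built by taking the marker
genes of the nominated malignant cell cluster and keeping those that appear
in any metabolic gene set (KEGG/Reactome-style collections read from GMT).
Markers are called with a two-sided Wilcoxon rank-sum test of the target
cluster against all other tumor cells, Benjamini-Hochberg adjusted, with a
log-fold-change floor — the common single-cell default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets; genes unique within each set."""

    sets: dict[str, list[str]]
    source: str = ""

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


@dataclass
class MarkerResult:
    gene: str
    log_fold_change: float
    p_value: float
    adjusted_p: float
    cluster: str


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Parse a standard GMT file: name <tab> description <tab> genes...

    Duplicate genes within a set are removed (first occurrence kept); a line
    with fewer than three fields is a parse error reported with its line
    number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def select_cluster_markers(
    expression: pd.DataFrame,
    cluster_labels: pd.Series,
    target_cluster: str,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
) -> list[MarkerResult]:
    """Marker genes of one cluster vs all other cells.

    ``expression`` is cells x genes on a log-like scale; the log fold change
    is the difference of class means.  Per-gene two-sided rank-sum test,
    Benjamini-Hochberg adjustment over all genes, then the filters
    ``adjusted_p < alpha`` and ``log_fold_change > min_lfc``.  Sorted by
    adjusted p, then by |lfc| descending.
    """
    labels = cluster_labels.reindex(expression.index)
    in_target = (labels == target_cluster).to_numpy()
    if in_target.sum() < 3:
        raise ValueError(
            f"target cluster {target_cluster!r} absent or has fewer than 3 cells"
        )
    if (~in_target).sum() < 3:
        raise ValueError("need at least 3 cells outside the target cluster")

    tgt = expression.loc[in_target].to_numpy(dtype=float)
    rest = expression.loc[~in_target].to_numpy(dtype=float)
    lfc = tgt.mean(axis=0) - rest.mean(axis=0)
    # mannwhitneyu is vectorized along axis 0 columns
    pvals = stats.mannwhitneyu(tgt, rest, alternative="two-sided", axis=0).pvalue
    pvals = np.nan_to_num(np.asarray(pvals, dtype=float), nan=1.0)
    adj = stats.false_discovery_control(pvals, method="bh")

    results = [
        MarkerResult(
            gene=str(g),
            log_fold_change=float(l),
            p_value=float(p),
            adjusted_p=float(a),
            cluster=target_cluster,
        )
        for g, l, p, a in zip(expression.columns, lfc, pvals, adj)
        if a < alpha and l > min_lfc
    ]
    results.sort(key=lambda m: (m.adjusted_p, -abs(m.log_fold_change)))
    return results


def intersect_with_metabolic(
    markers: list[MarkerResult] | list[str], collection: GeneSetCollection
) -> list[str]:
    """Marker genes present in the union of the metabolic sets.

    Order-preserving and deduplicated; an empty intersection is returned as
    an empty list with a warning (downstream pair mining will then error).
    """
    names = [m.gene if isinstance(m, MarkerResult) else m for m in markers]
    universe = collection.union()
    out = list(dict.fromkeys(g for g in names if g in universe))
    if not out:
        logger.warning("marker/metabolic intersection is empty")
    return out


def markers_to_frame(markers: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": m.gene,
                "log_fold_change": m.log_fold_change,
                "p_value": m.p_value,
                "adjusted_p": m.adjusted_p,
                "cluster": m.cluster,
            }
            for m in markers
        ],
        columns=["gene", "log_fold_change", "p_value", "adjusted_p", "cluster"],
    )
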