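"""CNV-profile post-processing: QC, per-cell scores, secondary clustering.

Consumes inferCNV-style matrices (genes x cells, modified expression centered
at 1; reference cells excluded from clustering).  A cell's CNV score is the
mean squared deviation of its profile from the diploid baseline 1 — the
dominant convention for summarising inferCNV output — and a cluster's score
is the mean over its member cells.  The cluster count for the secondary
k-means step is chosen from the within-cluster sum-of-squares (WSS) curve by
the elbow rule (largest second difference), with the between-cluster sum of
squares (BSS) share acting as a plateau check; the highest-scoring cluster is
nominated as the most aberrant (malignant) one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

REFERENCE = "reference"


@dataclass
class CnvMatrix:
    """Genes x cells CNV values centered at 1, with per-cell origin."""

    values: pd.DataFrame
    cell_origin: pd.Series  # per-cell, "tumor" or "reference"

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.cell_origin.index):
            self.cell_origin = self.cell_origin.reindex(self.values.columns)
        if self.cell_origin.isna().any():
            raise ValueError("every cell needs an origin (tumor/reference)")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("CNV values must be finite")

    def tumor_cells(self) -> pd.DataFrame:
        return self.values.loc[:, self.cell_origin != REFERENCE]


@dataclass
class CnvClustering:
    """Result of secondary k-means on tumor-cell CNV profiles."""

    assignment: pd.Series  # per tumor cell, cluster id "1".."k"
    k: int
    wss: dict[int, float]  # per candidate k
    bss: dict[int, float]
    scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    nominated: str | None = None


def qc_filter(
    counts: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    mito_max: float = 0.10,
    hb_max: float = 0.03,
    min_genes: int = 200,
    max_genes: int = 8000,
) -> tuple[list[str], pd.DataFrame]:
    """Cell quality filter on a cells x genes count matrix.

    ``gene_annotation`` must index the genes and carry boolean columns
    ``mito`` and ``hemoglobin``.  A cell is kept when its mitochondrial count
    fraction is below ``mito_max``, its hemoglobin fraction below ``hb_max``,
    and its detected-gene count lies in ``[min_genes, max_genes]`` inclusive.
    Returns the kept-cell list and a per-cell report with each statistic and
    the failure reasons.
    """
    for col in ("mito", "hemoglobin"):
        if col not in gene_annotation.columns:
            raise ValueError(f"gene annotation lacks required column {col!r}")
    ann = gene_annotation.reindex(counts.columns)
    if ann["mito"].isna().any() or ann["hemoglobin"].isna().any():
        raise ValueError("gene annotation does not cover all genes")

    mat = counts.to_numpy(dtype=float)
    total = mat.sum(axis=1)
    safe_total = np.where(total > 0, total, 1.0)
    mito_frac = mat[:, ann["mito"].to_numpy(dtype=bool)].sum(axis=1) / safe_total
    hb_frac = mat[:, ann["hemoglobin"].to_numpy(dtype=bool)].sum(axis=1) / safe_total
    n_detected = (mat > 0).sum(axis=1)

    reasons = []
    for m, h, n in zip(mito_frac, hb_frac, n_detected):
        r = []
        if not m < mito_max:
            r.append("mito")
        if not h < hb_max:
            r.append("hemoglobin")
        if n < min_genes:
            r.append("min_genes")
        if n > max_genes:
            r.append("max_genes")
        reasons.append(",".join(r))
    report = pd.DataFrame(
        {
            "mito_frac": mito_frac,
            "hb_frac": hb_frac,
            "n_genes": n_detected,
            "keep": [r == "" for r in reasons],
            "fail_reason": reasons,
        },
        index=counts.index,
    )
    kept = list(report.index[report["keep"]])
    return kept, report


def cnv_cell_score(profile: np.ndarray | pd.Series) -> float:
    """Mean squared deviation from the diploid baseline 1."""
    v = np.asarray(profile, dtype=float)
    if v.size == 0:
        raise ValueError("empty CNV profile")
    if not np.isfinite(v).all():
        raise ValueError("CNV profile must be finite")
    return float(np.mean((v - 1.0) ** 2))


def cnv_cluster_scores(
    matrix: CnvMatrix, assignment: pd.Series
) -> tuple[pd.Series, str]:
    """Mean member-cell CNV score per cluster, plus the nominated cluster.

    Nomination is the argmax score; exact ties break toward the lowest
    cluster ID (sorted order).
    """
    tumor = matrix.tumor_cells()
    assign = assignment.reindex(tumor.columns)
    if assign.isna().any():
        raise ValueError("assignment does not cover all tumor cells")
    cell_scores = ((tumor.to_numpy(dtype=float) - 1.0) ** 2).mean(axis=0)
    scores = (
        pd.Series(cell_scores, index=tumor.columns)
        .groupby(assign)
        .mean()
        .sort_index()
    )
    if scores.isna().any() or len(scores) == 0:
        raise ValueError("empty cluster in assignment")
    # stable argmax: first index at the max after sorting by cluster id
    nominated = str(scores.index[int(np.argmax(scores.to_numpy()))])
    return scores, nominated


def select_k_from_wss(
    wss: dict[int, float], bss: dict[int, float], total_ss: float
) -> int:
    """Elbow rule on the WSS curve with a BSS plateau check.

    k* maximises the WSS second difference over interior k; an exact
    second-difference tie breaks toward the smaller k whose BSS share is
    within 0.01 of the next k's share (plateau).  Degenerate curves (total SS
    ~ 0) return k = 1 with a warning.
    """
    ks = sorted(wss)
    if total_ss <= 1e-12 or wss[ks[0]] <= 1e-12 * max(total_ss, 1.0):
        warnings.warn("degenerate CNV matrix: all cells identical; k = 1")
        return 1
    interior = ks[1:-1]
    if not interior:
        raise ValueError("need k_max >= 3 candidate k values for the elbow rule")
    second_diff = {
        k: (wss[k - 1] - wss[k]) - (wss[k] - wss[k + 1]) for k in interior
    }
    best = max(second_diff.values())
    tied = sorted(k for k, v in second_diff.items() if v == best)
    for k in tied:
        nxt = k + 1
        if nxt not in bss or bss[k] / total_ss >= bss[nxt] / total_ss - 0.01:
            return k
    return tied[0]


def kmeans_select_k(
    matrix: CnvMatrix,
    k_max: int = 6,
    n_restarts: int = 10,
    seed: int = 0,
) -> CnvClustering:
    """Secondary k-means over tumor-cell CNV profiles with k selection.

    Runs Lloyd k-means (k-means++ init, ``n_restarts`` restarts, seeded) for
    k = 1..k_max, records WSS/BSS, picks k* by `select_k_from_wss`, and
    attaches cluster CNV scores and the nominated malignant cluster.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    tumor = matrix.tumor_cells()
    X = tumor.to_numpy(dtype=float).T  # cells x genes
    if X.shape[0] < k_max:
        raise ValueError("fewer tumor cells than k_max")
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())

    wss: dict[int, float] = {}
    bss: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            algorithm="lloyd",
            random_state=seed,
        ).fit(X)
        wss[k] = float(km.inertia_)
        bss[k] = total_ss - wss[k]
        fits[k] = km.labels_

    k_star = select_k_from_wss(wss, bss, total_ss)
    assignment = pd.Series(
        [str(lbl + 1) for lbl in fits[k_star]], index=tumor.columns, name="cluster"
    )
    clustering = CnvClustering(assignment=assignment, k=k_star, wss=wss, bss=bss)
    clustering.scores, clustering.nominated = cnv_cluster_scores(matrix, assignment)
    return clustering


def elbow_table(clustering: CnvClustering) -> pd.DataFrame:
    ks = sorted(clustering.wss)
    return pd.DataFrame(
        {
            "k": ks,
            "wss": [clustering.wss[k] for k in ks],
            "bss": [clustering.bss[k] for k in ks],
        }
    )


def plot_elbow(clustering: CnvClustering, path: str) -> None:
    """Optional WSS/BSS elbow curve (PNG or SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = elbow_table(clustering)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(tab["k"], tab["wss"], "o-", label="within-cluster SS")
    ax.plot(tab["k"], tab["bss"], "s--", label="between-cluster SS")
    ax.axvline(clustering.k, color="grey", lw=0.8)
    ax.set_xlabel("k")
    ax.set_ylabel("sum of squares")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
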