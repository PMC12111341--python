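"""Synthetic data with planted structure for every pipeline stage.

Each generator emulates the statistical shape of one input the analysis
consumes: two-class expression with planted order-reversed gene pairs,
inferCNV-style copy-number matrices with cluster-specific aberration
amplitude, single cells with planted gene-set upregulation, and survival
times with planted log-hazard effects.  All randomness flows from one
`numpy.random.Generator` seeded per call; identical config + seed gives
bit-identical output.

Expression values are continuous log-scale intensities rather than counts:
the REO method consumes only within-sample orderings, and continuous values
keep the planted order probability analytically controlled.  For a planted
pair the class-dependent mean offset ``delta`` between the two genes is
calibrated through the Gaussian difference CDF,

    P(G_i > G_j) = Phi(delta / (sqrt(2) * noise_sd))  =>
    delta = sqrt(2) * noise_sd * Phi^{-1}(strength),

so the within-class order probability of a planted pair has the requested
expectation in tumor samples and the mirrored one in normal samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reo import NORMAL, TUMOR, LabeledExpressionMatrix


class ConfigError(ValueError):
    """A synthetic-data configuration field is out of its allowed range."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass
class SyntheticExprConfig:
    """Two-class bulk expression with planted reversal pairs.

    ``reversal_strength`` is the target within-class order probability of each
    planted pair and must exceed 0.9 so planted pairs are detectable at the
    mining threshold.
    """

    n_genes: int = 200
    n_tumor: int = 100
    n_normal: int = 100
    n_planted_pairs: int = 10
    reversal_strength: float = 0.98
    noise_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be positive")
        _check(self.n_tumor >= 1, "n_tumor", "must be positive")
        _check(self.n_normal >= 1, "n_normal", "must be positive")
        _check(self.n_planted_pairs >= 0, "n_planted_pairs", "must be non-negative")
        _check(
            self.n_planted_pairs <= self.n_genes // 2,
            "n_planted_pairs",
            "planted pairs use disjoint genes (need n_planted_pairs <= n_genes/2)",
        )
        _check(
            0.9 < self.reversal_strength <= 1.0,
            "reversal_strength",
            "must lie in (0.9, 1]",
        )
        _check(self.noise_sd > 0, "noise_sd", "must be positive")
        lo, hi = self.baseline_mean_range
        _check(lo <= hi, "baseline_mean_range", "lower bound exceeds upper")


@dataclass
class SyntheticCnvConfig:
    """inferCNV-style matrix: values centered at 1, per-cluster aberration.

    Each tumor cluster carries one contiguous block of ``segment_length``
    genes shifted by +/- its amplitude (mimicking a chromosomal segment);
    reference cells are pure noise around 1.
    """

    n_genes: int = 600
    n_cells_per_cluster: tuple[int, ...] = (100, 100, 100)
    amplitudes: tuple[float, ...] = (0.3, 0.35, 0.4)
    segment_length: int = 100
    noise_sd: float = 0.01
    n_reference_cells: int = 0
    seed: int = 0

    def validate(self) -> None:
        _check(len(self.n_cells_per_cluster) >= 1, "n_cells_per_cluster", "zero clusters")
        _check(
            len(self.amplitudes) == len(self.n_cells_per_cluster),
            "amplitudes",
            "must match n_cells_per_cluster length",
        )
        _check(all(n >= 1 for n in self.n_cells_per_cluster), "n_cells_per_cluster", "positive")
        _check(all(a >= 0 for a in self.amplitudes), "amplitudes", "non-negative")
        _check(
            len(set(self.amplitudes)) == len(self.amplitudes),
            "amplitudes",
            "must be distinct so cluster score ranking is well-defined",
        )
        _check(self.segment_length >= 1, "segment_length", "must be positive")
        _check(self.segment_length <= self.n_genes, "segment_length", "exceeds n_genes")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")
        _check(self.n_reference_cells >= 0, "n_reference_cells", "non-negative")


@dataclass
class SyntheticSurvivalConfig:
    """Exponential event times with planted per-gene log-hazard effects."""

    n_samples: int = 300
    betas: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_samples >= 1, "n_samples", "must be positive")
        _check(self.baseline_rate > 0, "baseline_rate", "must be positive")
        _check(self.censor_rate >= 0, "censor_rate", "must be non-negative")


def gen_labeled_expression(config: SyntheticExprConfig) -> LabeledExpressionMatrix:
    """Two-class expression matrix with planted reversal pairs.

    Genes 2p and 2p+1 form planted pair p.  Within a planted pair the first
    gene sits ``delta/2`` above the shared baseline in tumor samples and
    ``delta/2`` below it in normal samples (the partner mirrored), with
    ``delta`` calibrated to ``reversal_strength``.  All other genes draw one
    baseline mean and keep it in both classes, so they carry no class signal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, nt, nn = config.n_genes, config.n_tumor, config.n_normal
    lo, hi = config.baseline_mean_range

    means_t = rng.uniform(lo, hi, size=g)
    means_n = means_t.copy()
    delta = np.sqrt(2.0) * config.noise_sd * stats.norm.ppf(config.reversal_strength)
    for p in range(config.n_planted_pairs):
        i, j = 2 * p, 2 * p + 1
        base = means_t[i]
        means_t[i], means_t[j] = base + delta / 2, base - delta / 2
        means_n[i], means_n[j] = base - delta / 2, base + delta / 2

    tumor = means_t[:, None] + rng.normal(0.0, config.noise_sd, size=(g, nt))
    normal = means_n[:, None] + rng.normal(0.0, config.noise_sd, size=(g, nn))

    genes = [f"G{i:04d}" for i in range(g)]
    samples = [f"T{i:03d}" for i in range(nt)] + [f"N{i:03d}" for i in range(nn)]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=genes, columns=samples)
    labels = pd.Series([TUMOR] * nt + [NORMAL] * nn, index=samples, name="label")
    return LabeledExpressionMatrix(values=values, labels=labels)


def planted_pair_ids(config: SyntheticExprConfig) -> list[tuple[str, str]]:
    """Gene-ID tuples of the planted pairs, in canonical orientation."""
    return [
        (f"G{2 * p:04d}", f"G{2 * p + 1:04d}") for p in range(config.n_planted_pairs)
    ]


def _disjoint_starts(
    rng: np.random.Generator, k: int, n_genes: int, seg_len: int, max_tries: int = 200
) -> list[int]:
    """Uniform block starts, resampled toward pairwise-disjoint segments.

    Falls back to the last draw when the gene axis cannot host k disjoint
    segments (or rejection keeps failing), so short universes still work.
    """
    starts: list[int] = []
    for _ in range(k):
        pick = int(rng.integers(0, n_genes - seg_len + 1))
        for _ in range(max_tries):
            if all(abs(pick - s) >= seg_len for s in starts):
                break
            pick = int(rng.integers(0, n_genes - seg_len + 1))
        starts.append(pick)
    return starts


def gen_cnv_matrix(config: SyntheticCnvConfig) -> tuple[pd.DataFrame, pd.Series]:
    """CNV matrix (genes x cells, centered at 1) plus true cell labels.

    Tumor cells of cluster ``c`` have one contiguous block of genes shifted by
    ``+/- amplitudes[c]``; sign and block start are drawn once per cluster
    from the seeded generator.  Block starts are resampled so clusters occupy
    disjoint segments whenever the gene axis is long enough (different
    chromosomal segments aberrate in different clones); reference cells
    (label ``"reference"``) are noise around 1 and are appended after the
    tumor cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    starts = _disjoint_starts(
        rng, len(config.n_cells_per_cluster), g, config.segment_length
    )
    blocks = []
    labels = []
    for c, (n_cells, amp) in enumerate(
        zip(config.n_cells_per_cluster, config.amplitudes), start=1
    ):
        start = starts[c - 1]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mean = np.ones(g)
        mean[start : start + config.segment_length] += sign * amp
        blocks.append(mean[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n_cells)))
        labels += [f"cluster{c}"] * n_cells
    if config.n_reference_cells:
        blocks.append(
            1.0 + rng.normal(0.0, config.noise_sd, size=(g, config.n_reference_cells))
        )
        labels += ["reference"] * config.n_reference_cells

    genes = [f"G{i:04d}" for i in range(g)]
    cells = [f"C{i:05d}" for i in range(len(labels))]
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    return values, pd.Series(labels, index=cells, name="true_label")


def gen_pathway_cells(
    n_cells: int,
    n_genes: int,
    gene_set: list[str],
    effect: float,
    frac_active: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x genes expression where a fraction of cells has the gene set
    up-shifted by ``effect``; returns (expression, active-cell labels).

    Gene universe is ``G0000..`` and ``gene_set`` must be a subset of it.
    """
    if not gene_set:
        raise ConfigError("gene_set: must be non-empty")
    if effect < 0:
        raise ConfigError("effect: must be non-negative")
    if not 0.0 <= frac_active <= 1.0:
        raise ConfigError("frac_active: must lie in [0, 1]")
    genes = [f"G{i:04d}" for i in range(n_genes)]
    missing = set(gene_set) - set(genes)
    if missing:
        raise ConfigError(f"gene_set: genes outside universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    n_active = int(round(frac_active * n_cells))
    active = np.zeros(n_cells, dtype=bool)
    active[rng.choice(n_cells, size=n_active, replace=False)] = True

    base = rng.uniform(2.0, 8.0, size=n_genes)
    expr = base[None, :] + rng.normal(0.0, noise_sd, size=(n_cells, n_genes))
    set_idx = [genes.index(gid) for gid in gene_set]
    expr[np.ix_(active, set_idx)] += effect

    cells = [f"C{i:05d}" for i in range(n_cells)]
    df = pd.DataFrame(expr, index=cells, columns=genes)
    labels = pd.Series(np.where(active, "active", "inactive"), index=cells, name="label")
    return df, labels


def gen_survival(
    config: SyntheticSurvivalConfig, expression: pd.DataFrame
) -> pd.DataFrame:
    """Survival table (sample, time, event) driven by planted hazards.

    Event times are exponential with per-sample rate
    ``baseline_rate * exp(sum_g beta_g * z_g)`` on z-scored expression;
    censoring times are exponential with ``censor_rate`` (no censoring when
    the rate is 0).  Only the first ``n_samples`` columns of ``expression``
    are used; it must provide every gene named in ``betas``.
    """
    config.validate()
    missing = [g for g in config.betas if g not in expression.index]
    if missing:
        raise ConfigError(f"betas: genes absent from expression: {missing[:5]}")
    samples = list(expression.columns[: config.n_samples])
    if len(samples) < config.n_samples:
        raise ConfigError("n_samples: exceeds available expression columns")
    rng = np.random.default_rng(config.seed)

    linpred = np.zeros(len(samples))
    for gene, beta in config.betas.items():
        x = expression.loc[gene, samples].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        linpred += beta * z

    rate = config.baseline_rate * np.exp(linpred)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / config.censor_rate, size=len(samples))
    else:
        t_censor = np.full(len(samples), np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({"sample": samples, "time": time, "event": event})


def gen_qc_counts(
    n_cells: int = 200,
    n_genes: int = 300,
    frac_fail_mito: float = 0.05,
    frac_fail_genes: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells x genes count matrix plus a mito/hemoglobin gene annotation.

    The first 10 genes are mitochondrial, the next 5 hemoglobin.  A fraction
    of cells gets mitochondrial counts inflated past the 10% QC limit and
    another fraction has most genes zeroed so they fall below the
    detected-gene floor; everything else passes the standard filters.
    """
    _check(n_genes >= 215, "n_genes", "need >= 215 genes for a meaningful QC fixture")
    rng = np.random.default_rng(seed)
    genes = (
        [f"MT-{i}" for i in range(10)]
        + [f"HB{i}" for i in range(5)]
        + [f"G{i:04d}" for i in range(n_genes - 15)]
    )
    counts = rng.poisson(5.0, size=(n_cells, n_genes)).astype(float)
    counts[counts < 1] = 1.0  # keep detected-gene count at n_genes baseline

    n_mito_fail = int(round(frac_fail_mito * n_cells))
    n_gene_fail = int(round(frac_fail_genes * n_cells))
    fail_idx = rng.choice(n_cells, size=n_mito_fail + n_gene_fail, replace=False)
    counts[fail_idx[:n_mito_fail], :10] *= 30.0  # mito fraction >> 10%
    for ci in fail_idx[n_mito_fail:]:
        keep = rng.choice(n_genes, size=150, replace=False)  # below min_genes=200
        mask = np.ones(n_genes, dtype=bool)
        mask[keep] = False
        counts[ci, mask] = 0.0

    cells = [f"C{i:05d}" for i in range(n_cells)]
    df = pd.DataFrame(counts, index=cells, columns=genes)
    ann = pd.DataFrame(
        {
            "mito": [g.startswith("MT-") for g in genes],
            "hemoglobin": [g.startswith("HB") for g in genes],
        },
        index=genes,
    )
    return df, ann


def gen_metabolic_collection(
    universe: list[str],
    planted: list[str],
    n_sets: int = 4,
    set_size: int = 25,
    seed: int = 0,
):
    """A small GMT-style collection whose union covers the planted genes.

    Planted genes are spread across the sets; the remainder of each set is
    drawn from the universe at random, emulating KEGG/Reactome metabolic
    pathway gene sets.
    """
    from .markers import GeneSetCollection

    _check(n_sets >= 1, "n_sets", "must be positive")
    rng = np.random.default_rng(seed)
    pool = [g for g in universe if g not in set(planted)]
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        members = list(planted[s::n_sets])
        n_fill = max(0, set_size - len(members))
        members += list(rng.choice(pool, size=min(n_fill, len(pool)), replace=False))
        sets[f"METABOLIC_PATHWAY_{s + 1}"] = members
    return GeneSetCollection(sets=sets, source="synthetic")
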