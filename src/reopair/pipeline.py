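"""End-to-end orchestration of the analysis stages.

The synthetic pipeline chains the stages in the order the analysis uses
them: cell QC -> CNV clustering and scoring -> malignant-cluster markers
intersected with metabolic gene sets -> stable reversal pair mining and
binarization -> diagnostic model grid -> prognostic Cox analysis.  Every
stage writes its artifacts as plain text and the run closes with a manifest
(config hash, seed, per-file SHA-256 checksums) so reruns are verifiable.

One top-level seed fans out to per-stage seeds through a stage-name hash so
any stage can be rerun in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, io, markers, models, prognostic, reo, synthetic

logger = logging.getLogger(__name__)

STAGES = ("qc", "cnv", "markers", "pairs", "diagnose", "prognose")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Thresholds, grid settings and synthetic-data sizes for one run."""

    seed: int = 0
    outdir: str = "reopair_run"
    reo_threshold: float = 0.9
    qc_mito_max: float = 0.10
    qc_hb_max: float = 0.03
    qc_min_genes: int = 200
    qc_max_genes: int = 8000
    marker_alpha: float = 0.05
    marker_min_lfc: float = 0.25
    aucell_top_fraction: float = 0.05
    ssgsea_alpha: float = 0.25
    model_universe: tuple[str, ...] = models.METHOD_UNIVERSE
    grid_mode: str = "default"
    cv_folds: int = 5
    # synthetic-mode sizes
    n_genes: int = 200
    n_planted_pairs: int = 10
    reversal_strength: float = 0.98
    n_tumor: int = 100
    n_normal: int = 100
    n_validation_cohorts: int = 2
    n_val_tumor: int = 80
    n_val_normal: int = 80
    survival_n: int = 300
    survival_betas: tuple[float, ...] = (0.7, -0.5)
    censor_rate: float = 0.05

    def validate(self) -> None:
        if not 0 < self.reo_threshold < 1:
            raise ValueError("reo_threshold must lie in (0, 1)")
        if not 0 < self.qc_mito_max < 1 or not 0 < self.qc_hb_max < 1:
            raise ValueError("QC fractions must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Any stage failure raises `PipelineError` naming the stage; artifacts
    written before the failure are retained in ``outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in asdict(config).items() if k != "outdir"},
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        try:
            files = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            _write_manifest(manifest, outdir)
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in sorted(files)}
        }
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_qc(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    counts, ann = synthetic.gen_qc_counts(seed=stage_seed(config.seed, "qc"))
    kept, report = cnv.qc_filter(
        counts,
        ann,
        mito_max=config.qc_mito_max,
        hb_max=config.qc_hb_max,
        min_genes=config.qc_min_genes,
        max_genes=config.qc_max_genes,
    )
    p = outdir / "qc_report.tsv"
    io.write_table_tsv(report.rename_axis("cell").reset_index(), p)
    state["qc_kept"] = kept
    return [p]


def _stage_cnv(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "cnv")
    cnv_cfg = synthetic.SyntheticCnvConfig(seed=seed)
    values, true_labels = synthetic.gen_cnv_matrix(cnv_cfg)
    origin = pd.Series(
        np.where(true_labels == "reference", "reference", "tumor"),
        index=values.columns,
    )
    matrix = cnv.CnvMatrix(values=values, cell_origin=origin)
    clustering = cnv.kmeans_select_k(matrix, k_max=6, seed=seed)
    state["cnv_clustering"] = clustering

    f_assign = outdir / "cnv_assignment.tsv"
    io.write_series_tsv(clustering.assignment, f_assign, index_name="cell")
    f_elbow = outdir / "cnv_elbow.tsv"
    io.write_table_tsv(cnv.elbow_table(clustering), f_elbow)
    f_scores = outdir / "cnv_scores.tsv"
    io.write_series_tsv(clustering.scores.rename("cnv_score"), f_scores, index_name="cluster")
    return [f_assign, f_elbow, f_scores]


def _stage_markers(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "markers")
    rng = np.random.default_rng(seed)
    clustering: cnv.CnvClustering = state["cnv_clustering"]
    cells = list(clustering.assignment.index)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    # single-cell expression for the clustered tumor cells; the nominated
    # malignant cluster over-expresses the planted marker genes
    planted_markers = genes[: 2 * config.n_planted_pairs + 10]
    expr = rng.uniform(2.0, 8.0, size=len(genes))[None, :] + rng.normal(
        0.0, 1.0, size=(len(cells), len(genes))
    )
    in_nominated = (clustering.assignment == clustering.nominated).to_numpy()
    idx = [genes.index(g) for g in planted_markers]
    expr[np.ix_(in_nominated, idx)] += 2.0
    sc_expr = pd.DataFrame(expr, index=cells, columns=genes)

    marker_list = markers.select_cluster_markers(
        sc_expr,
        clustering.assignment,
        clustering.nominated,
        min_lfc=config.marker_min_lfc,
        alpha=config.marker_alpha,
    )
    collection = synthetic.gen_metabolic_collection(
        genes, planted_markers, seed=seed
    )
    candidates = markers.intersect_with_metabolic(marker_list, collection)
    state["candidates"] = candidates
    state["collection"] = collection

    f_markers = outdir / "markers.tsv"
    io.write_table_tsv(markers.markers_to_frame(marker_list), f_markers)
    f_gmt = outdir / "metabolic_sets.gmt"
    markers.write_gmt(collection, f_gmt)
    f_cand = outdir / "candidate_genes.txt"
    f_cand.write_text("\n".join(candidates) + "\n")
    return [f_markers, f_gmt, f_cand]


def _expr_config(config: PipelineConfig, n_tumor: int, n_normal: int, seed: int):
    return synthetic.SyntheticExprConfig(
        n_genes=config.n_genes,
        n_tumor=n_tumor,
        n_normal=n_normal,
        n_planted_pairs=config.n_planted_pairs,
        reversal_strength=config.reversal_strength,
        seed=seed,
    )


def _stage_pairs(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "pairs")
    train = synthetic.gen_labeled_expression(
        _expr_config(config, config.n_tumor, config.n_normal, seed)
    )
    candidates = [g for g in state["candidates"] if g in train.genes]
    pairs = reo.find_reversal_pairs(train, candidates, threshold=config.reo_threshold)
    if len(pairs) == 0:
        raise ValueError("no reversal pairs found in the training group")
    profile = reo.binarize(train.values, pairs, training=train)
    state["train"] = train
    state["pairs"] = pairs
    state["train_profile"] = profile

    f_expr = outdir / "train_expression.tsv"
    io.write_matrix_tsv(train.values, f_expr)
    f_lab = outdir / "train_labels.tsv"
    io.write_series_tsv(train.labels, f_lab, index_name="sample")
    f_pairs = outdir / "reversal_pairs.tsv"
    io.write_table_tsv(pairs.to_frame(), f_pairs)
    f_prof = outdir / "train_pair_profile.tsv"
    io.write_matrix_tsv(profile.values, f_prof, index_name="pair")
    return [f_expr, f_lab, f_pairs, f_prof]


def _stage_diagnose(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "diagnose")
    pairs: reo.ReversalPairSet = state["pairs"]
    train: reo.LabeledExpressionMatrix = state["train"]
    cohorts: dict[str, tuple[reo.PairProfile, pd.Series]] = {}
    for v in range(config.n_validation_cohorts):
        cohort = synthetic.gen_labeled_expression(
            _expr_config(config, config.n_val_tumor, config.n_val_normal, seed + 1 + v)
        )
        cohorts[f"validation{v + 1}"] = (
            reo.binarize(cohort.values, pairs, training=train),
            cohort.labels,
        )
    ranked, fitted = models.run_grid(
        state["train_profile"],
        train.labels,
        cohorts,
        universe=tuple(config.model_universe),
        mode=config.grid_mode,
        cv_folds=config.cv_folds,
        seed=seed,
    )
    state["ranked"] = ranked
    f_grid = outdir / "model_grid.tsv"
    io.write_table_tsv(models.results_to_frame(ranked), f_grid)
    top = ranked[0]
    f_top = outdir / "top_model.json"
    f_top.write_text(
        json.dumps(
            {
                "combo": top.combo.name,
                "mean_auc": round(top.mean_auc, 10),
                "auc_per_cohort": {k: round(v, 10) for k, v in top.auc_per_cohort.items()},
                "pairs": pairs.pair_ids(),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [f_grid, f_top]


def _stage_prognose(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "prognose")
    pairs: reo.ReversalPairSet = state["pairs"]
    pair_genes = sorted({g for p in pairs.pairs for g in (p.gene_i, p.gene_j)})
    # an independent tumor cohort with planted log-hazard effects on the
    # first pair genes
    cohort = synthetic.gen_labeled_expression(
        _expr_config(config, config.survival_n, 1, seed)
    )
    tumor_expr = cohort.class_matrix(reo.TUMOR)
    betas = {
        g: b for g, b in zip(pair_genes, config.survival_betas)
    }
    surv_cfg = synthetic.SyntheticSurvivalConfig(
        n_samples=config.survival_n,
        betas=betas,
        censor_rate=config.censor_rate,
        seed=seed,
    )
    survival = synthetic.gen_survival(surv_cfg, tumor_expr)

    uni = prognostic.fit_cox(tumor_expr.loc[pair_genes], survival, mode="univariate")
    multi = prognostic.fit_cox(tumor_expr.loc[pair_genes], survival, mode="multivariate")
    groups = prognostic.risk_stratify(multi)
    curves, stat, pval = prognostic.km_logrank(groups, survival)
    corr = prognostic.coexpression(tumor_expr.loc[pair_genes])
    state["cox"] = multi
    state["logrank_p"] = pval

    files = []
    f_surv = outdir / "survival.tsv"
    io.write_table_tsv(survival, f_surv)
    files.append(f_surv)
    for name, fit in (("univariate", uni), ("multivariate", multi)):
        f = outdir / f"cox_{name}.tsv"
        io.write_table_tsv(fit.table.reset_index(), f)
        files.append(f)
    f_groups = outdir / "risk_groups.tsv"
    io.write_series_tsv(groups, f_groups, index_name="sample")
    files.append(f_groups)
    for gname, curve in curves.items():
        f = outdir / f"km_{gname}.tsv"
        io.write_table_tsv(curve, f)
        files.append(f)
    f_sum = outdir / "prognostic_summary.json"
    f_sum.write_text(
        json.dumps(
            {
                "c_index": round(multi.c_index, 10),
                "logrank_statistic": round(stat, 10),
                "logrank_p": round(pval, 10),
            },
            indent=2,
            sort_keys=True,
        )
    )
    files.append(f_sum)
    f_corr = outdir / "coexpression.tsv"
    io.write_matrix_tsv(corr, f_corr, index_name="gene")
    files.append(f_corr)
    return files


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "cnv": _stage_cnv,
    "markers": _stage_markers,
    "pairs": _stage_pairs,
    "diagnose": _stage_diagnose,
    "prognose": _stage_prognose,
}
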