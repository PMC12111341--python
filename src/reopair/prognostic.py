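"""Prognostic analysis of reversal-pair genes: Cox models, risk groups,
Kaplan-Meier/log-rank, concordance, co-expression.

Binarized pair features are not suited to hazard modelling, so the genes
composing the reversal pairs are used directly as covariates.  Expression is
z-scored before fitting; partial-likelihood maximisation uses Efron tie
handling.  Patients are stratified into high/low risk at the median of the
multivariate linear predictor (ties at the median go to "low"), and the
groups are compared by Kaplan-Meier curves with a log-rank test.  Model
discrimination is Harrell's concordance index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

logger = logging.getLogger(__name__)


@dataclass
class CoxFit:
    """Per-gene coefficients, hazard ratios and CIs, plus model-level stats."""

    table: pd.DataFrame  # index gene; coef, hr, hr_lower, hr_upper, p
    model: str  # "univariate" or "multivariate"
    c_index: float
    risk_scores: pd.Series  # per-sample linear predictor (multivariate only)


def _validate_survival(survival: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "time", "event"}
    if not required <= set(survival.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if survival["sample"].duplicated().any():
        raise ValueError("duplicate samples in survival table")
    if (survival["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not survival["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return survival


def _zscore_drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score genes across samples, dropping constant genes with a warning."""
    sd = expr.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("dropping constant genes from Cox fit: %s", list(constant))
        expr = expr.drop(index=constant)
        sd = sd.drop(index=constant)
    return expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)


def fit_cox(
    expression: pd.DataFrame, survival: pd.DataFrame, mode: str = "multivariate"
) -> CoxFit:
    """Cox proportional-hazards fit on genes x samples expression.

    Univariate mode fits each gene separately (C-index reported is that of
    the last single-gene model, per-gene stats in the table); multivariate
    fits all genes jointly and exposes the per-sample risk score (linear
    predictor).  Fewer than 10 events triggers a stability warning.
    """
    survival = _validate_survival(survival)
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    if int(survival["event"].sum()) == 0:
        raise ValueError("zero events: Cox model undefined")
    if int(survival["event"].sum()) < 10:
        warnings.warn("fewer than 10 events; multivariate fit may be unstable")

    samples = [s for s in survival["sample"] if s in expression.columns]
    if len(samples) < len(survival):
        raise ValueError("survival samples missing from expression matrix")
    expr = _zscore_drop_constant(expression.loc[:, samples])
    if expr.shape[0] == 0:
        raise ValueError("no non-constant genes to fit")
    surv = survival.set_index("sample").loc[samples, ["time", "event"]]

    def _fit(genes: list[str]) -> CoxPHFitter:
        df = pd.concat([expr.loc[genes].T, surv], axis=1)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        return cph

    if mode == "univariate":
        rows = []
        for gene in expr.index:
            cph = _fit([gene])
            s = cph.summary.loc[gene]
            rows.append(_summary_row(gene, s))
        table = pd.DataFrame(rows).set_index("gene")
        # per-gene models have no joint score; use the last gene's C as a
        # placeholder-free per-gene table and report NaN at model level
        return CoxFit(table=table, model="univariate", c_index=float("nan"),
                      risk_scores=pd.Series(dtype=float))

    cph = _fit(list(expr.index))
    table = pd.DataFrame(
        [_summary_row(g, cph.summary.loc[g]) for g in expr.index]
    ).set_index("gene")
    lp = cph.predict_partial_hazard(expr.T)  # exp(linear predictor)
    risk = pd.Series(np.log(lp.to_numpy(dtype=float).ravel()), index=samples,
                     name="risk_score")
    c = concordance_index(risk.to_numpy(), surv.reset_index())
    return CoxFit(table=table, model="multivariate", c_index=c, risk_scores=risk)


def _summary_row(gene: str, s: pd.Series) -> dict:
    return {
        "gene": gene,
        "coef": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "hr_lower": float(s["exp(coef) lower 95%"]),
        "hr_upper": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
    }


def risk_stratify(fit: CoxFit) -> pd.Series:
    """High/low risk split at the median risk score (ties at median -> low)."""
    if fit.model != "multivariate" or fit.risk_scores.empty:
        raise ValueError("risk stratification needs a multivariate fit")
    scores = fit.risk_scores
    if scores.nunique() == 1:
        raise ValueError("degenerate stratification: all risk scores identical")
    med = float(scores.median())
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="risk_group"
    )


def km_logrank(
    groups: pd.Series, survival: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns ({group: KM table(time, at_risk, survival)}, chi2 statistic,
    p-value); the chi-square has k-1 degrees of freedom.
    """
    survival = _validate_survival(survival)
    surv = survival.set_index("sample")
    groups = groups.reindex(surv.index).dropna()
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if int(surv.loc[groups.index, "event"].sum()) == 0:
        raise ValueError("no events observed; log-rank statistic undefined")

    curves: dict[str, pd.DataFrame] = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = surv.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"group {name!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        curves[str(name)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
            }
        )
    res = multivariate_logrank_test(
        surv.loc[groups.index, "time"], groups, surv.loc[groups.index, "event"]
    )
    return curves, float(res.test_statistic), float(res.p_value)


def concordance_index(scores: np.ndarray, survival: pd.DataFrame) -> float:
    """Harrell's C for risk scores: higher score should mean earlier event.

    c = (concordant + 0.5 * score-ties) / comparable over pairs whose event
    ordering is determinable under right censoring.
    """
    survival = _validate_survival(survival)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(survival):
        raise ValueError("scores and survival table must align")
    # Harrell's C with risk scores = concordance of (-score) with time
    try:
        return float(
            _lifelines_cindex(
                survival["time"].to_numpy(),
                -scores,
                survival["event"].to_numpy(),
            )
        )
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs; C-index undefined") from exc


def coexpression(expression: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Gene x gene correlation matrix (unit diagonal, symmetric).

    Constant genes yield missing correlations with a warning.  ``method`` is
    "spearman" (default) or "pearson".
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = expression.std(axis=1, ddof=0)
    if (sd == 0).any():
        logger.warning(
            "constant genes have undefined correlations: %s", list(sd[sd == 0].index)
        )
    corr = expression.T.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr
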