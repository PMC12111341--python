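"""Diagnostic model grid over binarized gene-pair profiles.

Nine base learners (Enet, GBM, SVM, RF, glm, plsRglm, Ridge, Lasso, rpart)
are combined into a grid of single-classifier models plus ordered
(selector, classifier) pairs, where the selector is fit on training data only
and passes its surviving pair features to the classifier.  Every combination
is scored by AUC on each cohort — the training cohort via out-of-fold
cross-validated predictions to avoid resubstitution optimism — and the grid
is ranked by the mean AUC across cohorts.

The grid is configuration-driven: the default universe yields 9 single
models plus 8 selection-capable selectors x 8 alternative classifiers = 73
combinations.  Hyperparameters are fixed, widely used defaults; every
stochastic fitter receives the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectFromModel
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .reo import TUMOR, PairProfile

logger = logging.getLogger(__name__)

METHOD_UNIVERSE = (
    "Enet",
    "GBM",
    "SVM",
    "RF",
    "glm",
    "plsRglm",
    "Ridge",
    "Lasso",
    "rpart",
)
# every method with usable coefficients/importances can act as a selector
SELECTION_CAPABLE = frozenset(METHOD_UNIVERSE) - {"SVM"}


@dataclass(frozen=True)
class ModelCombo:
    """A first-stage selector (optional) plus a second-stage classifier."""

    classifier: str
    selector: str | None = None

    @property
    def name(self) -> str:
        return self.classifier if self.selector is None else f"{self.selector}+{self.classifier}"


@dataclass
class ComboResult:
    combo: ModelCombo
    auc_per_cohort: dict[str, float]
    mean_auc: float = float("nan")
    rank: int = 0
    n_selected: int = 0

    def finalize(self) -> "ComboResult":
        defined = [a for a in self.auc_per_cohort.values() if not np.isnan(a)]
        self.mean_auc = float(np.mean(defined)) if defined else float("nan")
        return self


class _PLSClassifier:
    """PLS regression on the 0/1 label, used both as scorer and selector.

    Continuous PLS predictions serve as decision scores; the regression
    coefficients expose `coef_` for importance-based feature selection.
    """

    def __init__(self, n_components: int = 2, random_state: int | None = None):
        self.n_components = n_components
        self.random_state = random_state  # unused; PLS is deterministic

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "random_state": self.random_state}

    def set_params(self, **params) -> "_PLSClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        yf = np.asarray(y, dtype=float)
        top = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        self._pls = None
        # deflation can zero out the residual on separable binary features;
        # back off to fewer components until the coefficients are finite
        for ncomp in range(top, 0, -1):
            pls = PLSRegression(n_components=ncomp, scale=False)
            with np.errstate(divide="ignore", invalid="ignore"):
                try:
                    pls.fit(X, yf)
                except (ValueError, np.linalg.LinAlgError):
                    continue
            coef = pls.coef_.reshape(1, -1)
            if np.isfinite(coef).all():
                self._pls = pls
                self.coef_ = coef
                break
        if self._pls is None:  # constant X: predict the label mean
            self.coef_ = np.zeros((1, X.shape[1]))
            self._intercept = float(yf.mean())
        self.classes_ = np.unique(y)
        return self

    def decision_function(self, X):
        if self._pls is None:
            return np.full(X.shape[0], self._intercept)
        with np.errstate(invalid="ignore"):
            return self._pls.predict(X).ravel()


def _make_estimator(name: str, seed: int):
    if name == "Enet":
        return LogisticRegression(
            solver="saga", l1_ratio=0.5, C=1.0, max_iter=5000, random_state=seed
        )
    if name == "GBM":
        return GradientBoostingClassifier(random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "glm":
        return LogisticRegression(C=np.inf, max_iter=5000)
    if name == "plsRglm":
        return _PLSClassifier(random_state=seed)
    if name == "Ridge":
        return LogisticRegression(C=1.0, max_iter=5000)
    if name == "Lasso":
        return LogisticRegression(
            solver="saga", l1_ratio=1.0, C=1.0, max_iter=5000, random_state=seed
        )
    if name == "rpart":
        return DecisionTreeClassifier(max_depth=4, random_state=seed)
    raise ValueError(f"unknown method {name!r}")


def enumerate_combos(
    universe: tuple[str, ...] = METHOD_UNIVERSE, mode: str = "default"
) -> list[ModelCombo]:
    """The model grid: single classifiers plus ordered selector/classifier
    pairs with selection-capable selectors (selector != classifier)."""
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty method universe")
    unknown = [m for m in uni if m not in METHOD_UNIVERSE]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    combos = [ModelCombo(classifier=c) for c in uni]
    if mode == "classifier_only":
        return combos
    if mode != "default":
        raise ValueError(f"unknown grid mode {mode!r}")
    for sel in uni:
        if sel not in SELECTION_CAPABLE:
            continue
        for clf in uni:
            if clf != sel:
                combos.append(ModelCombo(classifier=clf, selector=sel))
    return combos


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney rank statistic.

    ``labels`` is boolean/0-1 with 1 the positive (tumor) class; tied scores
    contribute 1/2 per tied positive-negative pair via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: cohort has a single class")
    r = rankdata(scores)
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _select_features(selector_name: str, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Boolean mask of surviving features; falls back to all features when a
    selector eliminates everything."""
    est = _make_estimator(selector_name, seed)
    sfm = SelectFromModel(est)
    sfm.fit(X, y)
    mask = sfm.get_support()
    if not mask.any():
        logger.warning("selector %s kept no features; falling back to all", selector_name)
        return np.ones(X.shape[1], dtype=bool)
    return mask


@dataclass
class FittedCombo:
    """A fitted combination, applicable to new cohorts on the same pair space."""

    combo: ModelCombo
    estimator: object
    feature_mask: np.ndarray
    pair_ids: list[str]

    def score_profile(self, profile: PairProfile) -> np.ndarray:
        X = profile.values.reindex(self.pair_ids).to_numpy(dtype=float).T
        if np.isnan(X).any():
            raise ValueError("cohort profile lacks required pair features")
        return _scores(self.estimator, X[:, self.feature_mask])


def fit_combo(
    combo: ModelCombo, X: np.ndarray, y: np.ndarray, pair_ids: list[str], seed: int
) -> FittedCombo:
    if combo.selector is not None:
        mask = _select_features(combo.selector, X, y, seed)
    else:
        mask = np.ones(X.shape[1], dtype=bool)
    est = _make_estimator(combo.classifier, seed)
    est.fit(X[:, mask], y)
    return FittedCombo(combo=combo, estimator=est, feature_mask=mask, pair_ids=pair_ids)


def fit_eval_combo(
    combo: ModelCombo,
    train: PairProfile,
    train_labels: pd.Series,
    cohorts: dict[str, tuple[PairProfile, pd.Series]],
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[ComboResult, FittedCombo]:
    """Fit one combination and compute its per-cohort AUCs.

    The training AUC comes from out-of-fold predictions under a seeded
    stratified k-fold split (selector and classifier refit inside each
    fold); validation cohorts are scored by the model fit on the full
    training profile.  A single-class cohort yields a missing AUC with a
    warning.
    """
    pair_ids = list(train.pairs)
    X = train.values.to_numpy(dtype=float).T
    y = (train_labels.reindex(train.samples) == TUMOR).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training profile needs both classes")

    oof = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(X, y):
        if combo.selector is not None:
            mask = _select_features(combo.selector, X[tr_idx], y[tr_idx], seed)
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        est = _make_estimator(combo.classifier, seed)
        est.fit(X[np.ix_(tr_idx, mask)], y[tr_idx])
        oof[te_idx] = _scores(est, X[np.ix_(te_idx, mask)])

    aucs: dict[str, float] = {"training": roc_auc(oof, y)}
    fitted = fit_combo(combo, X, y, pair_ids, seed)
    for name, (profile, labels) in cohorts.items():
        yv = (labels.reindex(profile.samples) == TUMOR).to_numpy(dtype=int)
        try:
            aucs[name] = roc_auc(fitted.score_profile(profile), yv)
        except ValueError as exc:
            logger.warning("cohort %s: AUC undefined (%s)", name, exc)
            aucs[name] = float("nan")
    result = ComboResult(
        combo=combo, auc_per_cohort=aucs, n_selected=int(fitted.feature_mask.sum())
    ).finalize()
    return result, fitted


def rank_models(results: list[ComboResult]) -> list[ComboResult]:
    """Sort descending by mean AUC; ties break by fewer selected features
    then lexicographic combo name.  Populates the rank field."""
    defined = [r for r in results if not np.isnan(r.mean_auc)]
    if not defined:
        raise ValueError("no result with a defined AUC")
    ordered = sorted(
        results,
        key=lambda r: (
            -(r.mean_auc if not np.isnan(r.mean_auc) else -np.inf),
            r.n_selected,
            r.combo.name,
        ),
    )
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def run_grid(
    train: PairProfile,
    train_labels: pd.Series,
    cohorts: dict[str, tuple[PairProfile, pd.Series]],
    universe: tuple[str, ...] = METHOD_UNIVERSE,
    mode: str = "default",
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[list[ComboResult], dict[str, FittedCombo]]:
    """Fit and rank the whole grid; returns ranked results and fitted models."""
    results = []
    fitted: dict[str, FittedCombo] = {}
    for combo in enumerate_combos(universe, mode=mode):
        res, fc = fit_eval_combo(
            combo, train, train_labels, cohorts, cv_folds=cv_folds, seed=seed
        )
        results.append(res)
        fitted[combo.name] = fc
    return rank_models(results), fitted


def results_to_frame(results: list[ComboResult]) -> pd.DataFrame:
    cohort_names = sorted({c for r in results for c in r.auc_per_cohort})
    rows = []
    for r in results:
        row = {"combo": r.combo.name, "rank": r.rank, "mean_auc": r.mean_auc,
               "n_selected": r.n_selected}
        for c in cohort_names:
            row[f"auc_{c}"] = r.auc_per_cohort.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
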