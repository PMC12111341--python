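"""Cox fits, risk stratification, KM/log-rank, C-index, co-expression."""

import numpy as np
import pandas as pd
import pytest

from oracles import bf_concordance, bf_km_survival, bf_logrank
from reopair import prognostic, reo, synthetic
from reopair.prognostic import CoxFit


def _tumor_expression(n, n_genes=5, seed=0):
    cfg = synthetic.SyntheticExprConfig(
        n_genes=n_genes, n_planted_pairs=0, n_tumor=n, n_normal=1, seed=seed
    )
    return synthetic.gen_labeled_expression(cfg).class_matrix(reo.TUMOR)


def _survival_for(expr, betas, seed, censor_rate=0.045):
    cfg = synthetic.SyntheticSurvivalConfig(
        n_samples=expr.shape[1], betas=betas, censor_rate=censor_rate, seed=seed
    )
    return synthetic.gen_survival(cfg, expr)


class TestFitCox:
    def test_null_betas_give_chance_discrimination(self):
        expr = _tumor_expression(300, seed=1)
        surv = _survival_for(expr, {}, seed=1)
        fit = prognostic.fit_cox(expr, surv, mode="multivariate")
        assert abs(fit.c_index - 0.5) < 0.08
        assert (fit.table["hr_lower"] <= fit.table["hr"]).all()
        assert (fit.table["hr"] <= fit.table["hr_upper"]).all()
        assert np.allclose(fit.table["hr"], np.exp(fit.table["coef"]))

    def test_planted_beta_recovered(self):
        expr = _tumor_expression(500, seed=2)
        surv = _survival_for(expr, {"G0000": 0.7}, seed=2)
        fit = prognostic.fit_cox(expr.loc[["G0000"]], surv, mode="multivariate")
        assert fit.table.loc["G0000", "coef"] == pytest.approx(0.7, abs=0.15)

    def test_univariate_fits_each_gene_separately(self):
        expr = _tumor_expression(200, seed=3)
        surv = _survival_for(expr, {"G0001": 0.8}, seed=3)
        fit = prognostic.fit_cox(expr, surv, mode="univariate")
        assert fit.model == "univariate"
        assert fit.table.loc["G0001", "p"] < 0.05
        assert set(fit.table.index) == set(expr.index)

    def test_constant_gene_dropped_with_warning(self, caplog):
        expr = _tumor_expression(100, seed=4)
        expr.loc["G0000"] = 7.0
        surv = _survival_for(expr, {}, seed=4)
        with caplog.at_level("WARNING"):
            fit = prognostic.fit_cox(expr, surv, mode="multivariate")
        assert "G0000" not in fit.table.index

    def test_zero_events_errors(self):
        expr = _tumor_expression(50, seed=5)
        surv = _survival_for(expr, {}, seed=5)
        surv["event"] = 0
        with pytest.raises(ValueError, match="zero events"):
            prognostic.fit_cox(expr, surv)


class TestRiskStratify:
    def _fit_with_scores(self, scores):
        return CoxFit(
            table=pd.DataFrame(),
            model="multivariate",
            c_index=0.5,
            risk_scores=pd.Series(scores, index=[f"s{i}" for i in range(len(scores))]),
        )

    def test_even_split(self):
        groups = prognostic.risk_stratify(self._fit_with_scores([1.0, 2.0, 3.0, 4.0]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        groups = prognostic.risk_stratify(self._fit_with_scores([1.0, 2.0, 3.0]))
        assert list(groups) == ["low", "low", "high"]

    def test_degenerate_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            prognostic.risk_stratify(self._fit_with_scores([2.0, 2.0, 2.0]))

    def test_planted_effect_separates_survival(self):
        expr = _tumor_expression(300, seed=6)
        surv = _survival_for(expr, {"G0000": 0.9, "G0001": -0.6}, seed=6)
        fit = prognostic.fit_cox(expr.loc[["G0000", "G0001"]], surv)
        groups = prognostic.risk_stratify(fit)
        _, stat, p = prognostic.km_logrank(groups, surv)
        assert p < 0.05
        # high-risk group dies earlier
        med = surv.set_index("sample").groupby(groups)["time"].median()
        assert med["high"] < med["low"]


class TestKmLogrank:
    def test_exchangeable_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 0]
        surv = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(10)],
                "time": times + times,
                "event": events + events,
            }
        )
        groups = pd.Series(
            ["a"] * 5 + ["b"] * 5, index=surv["sample"], name="group"
        )
        _, stat, p = prognostic.km_logrank(groups, surv)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_complete_separation_matches_oracle_o_minus_e(self):
        """Six subjects, no censoring, group a exhausted before any b event;
        the chi-square must equal the hand-computed O-E table value."""
        surv = pd.DataFrame(
            {
                "sample": list("abcdef"),
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1] * 6,
            }
        )
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=surv["sample"])
        chi2, p = bf_logrank([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        _, stat, pval = prognostic.km_logrank(groups, surv)
        assert stat == pytest.approx(chi2, rel=1e-9)
        assert pval == pytest.approx(p, rel=1e-9)
        assert p < 0.05

    def test_km_equals_empirical_survival_without_censoring(self):
        times = [1.0, 1.0, 2.0, 3.0, 5.0, 8.0]
        surv = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(6)],
                "time": times,
                "event": [1] * 6,
            }
        )
        groups = pd.Series(["g"] * 6 + ["h"] * 0, index=surv["sample"])
        groups.iloc[3:] = "h"
        curves, _, _ = prognostic.km_logrank(groups, surv)
        km = curves["g"].set_index("time")["survival"]
        oracle = bf_km_survival(times[:3], [1, 1, 1])
        for t, s in oracle.items():
            assert km.loc[t] == pytest.approx(s)

    def test_all_censored_errors(self):
        surv = pd.DataFrame(
            {"sample": ["a", "b"], "time": [1.0, 2.0], "event": [0, 0]}
        )
        groups = pd.Series(["g1", "g2"], index=surv["sample"])
        with pytest.raises(ValueError, match="no events"):
            prognostic.km_logrank(groups, surv)


class TestConcordance:
    def _surv(self, times, events):
        return pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(len(times))],
                "time": times,
                "event": events,
            }
        )

    def test_perfect_concordance(self):
        assert prognostic.concordance_index(
            np.array([2.0, 1.0]), self._surv([1.0, 2.0], [1, 1])
        ) == 1.0

    def test_perfect_anticoncordance(self):
        assert prognostic.concordance_index(
            np.array([1.0, 2.0]), self._surv([1.0, 2.0], [1, 1])
        ) == 0.0

    def test_three_subject_enumeration(self):
        assert prognostic.concordance_index(
            np.array([3.0, 1.0, 2.0]), self._surv([1.0, 3.0, 2.0], [1, 1, 1])
        ) == 1.0

    def test_matches_bruteforce_under_censoring(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            scores = rng.normal(size=n)
            times = rng.exponential(5.0, size=n).round(1) + 0.1
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            ours = prognostic.concordance_index(scores, self._surv(times, events))
            assert ours == pytest.approx(
                bf_concordance(scores, times, events), abs=1e-12
            )

    def test_model_c_index_consistent_with_risk_scores(self):
        expr = _tumor_expression(200, seed=8)
        surv = _survival_for(expr, {"G0002": 0.8}, seed=8)
        fit = prognostic.fit_cox(expr, surv)
        recomputed = prognostic.concordance_index(
            fit.risk_scores.to_numpy(), surv
        )
        assert fit.c_index == pytest.approx(recomputed, abs=1e-12)


class TestCoexpression:
    def test_diagonal_and_antiperfect(self):
        x = np.arange(10.0)
        expr = pd.DataFrame({"s%d" % i: [x[i], -x[i]] for i in range(10)},
                            index=["a", "b"])
        corr = prognostic.coexpression(expr)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.equals(corr.T)

    def test_independent_genes_have_small_correlation(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.normal(size=(15, 200)),
            index=[f"g{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(200)],
        )
        corr = prognostic.coexpression(expr)
        off = corr.to_numpy()[~np.eye(15, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.15

    def test_too_few_samples_errors(self):
        expr = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            prognostic.coexpression(expr)
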