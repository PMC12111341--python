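"""AUCell and ssGSEA scorers: worked examples, oracle agreement, invariances."""

import numpy as np
import pandas as pd
import pytest

from oracles import bf_aucell, bf_ssgsea
from reopair import pathway, synthetic
from reopair.markers import GeneSetCollection
from reopair.models import roc_auc


def _ranks(n, positions):
    """Rank series for an n-gene universe; positions maps gene -> rank."""
    genes = [f"g{i}" for i in range(n)]
    remaining = [r for r in range(1, n + 1) if r not in positions.values()]
    ranks = {}
    it = iter(remaining)
    for g in genes:
        ranks[g] = positions[g] if g in positions else next(it)
    return pd.Series(ranks)


class TestRanks:
    def test_simple_ordering(self):
        expr = pd.DataFrame([[5.0, 3.0, 1.0]], index=["c"], columns=["a", "b", "d"])
        r = pathway.rank_genes_per_cell(expr, seed=0)
        assert list(r.loc["c"]) == [1, 2, 3]

    def test_tie_break_is_seeded_permutation(self):
        expr = pd.DataFrame([[2.0] * 6], index=["c"], columns=list("abcdef"))
        r1 = pathway.rank_genes_per_cell(expr, seed=5)
        r2 = pathway.rank_genes_per_cell(expr, seed=5)
        assert r1.equals(r2)
        assert sorted(r1.loc["c"]) == [1, 2, 3, 4, 5, 6]

    def test_different_seeds_can_reorder_ties(self):
        expr = pd.DataFrame([[2.0] * 20], index=["c"], columns=[f"g{i}" for i in range(20)])
        r1 = pathway.rank_genes_per_cell(expr, seed=1)
        r2 = pathway.rank_genes_per_cell(expr, seed=2)
        assert not r1.equals(r2)


class TestAucell:
    def test_maximal_recovery(self):
        ranks = _ranks(100, {f"g{i}": i + 1 for i in range(5)})
        assert pathway.aucell_score(ranks, [f"g{i}" for i in range(5)]) == 1.0

    def test_worked_example_eight_ninths(self):
        ranks = _ranks(100, {"g0": 1, "g1": 3})
        assert pathway.aucell_score(ranks, ["g0", "g1"]) == pytest.approx(8 / 9)

    def test_set_outside_top_window_scores_zero(self):
        ranks = _ranks(100, {"g0": 50, "g1": 99})
        assert pathway.aucell_score(ranks, ["g0", "g1"]) == 0.0

    def test_no_overlap_errors(self):
        ranks = _ranks(10, {})
        with pytest.raises(ValueError):
            pathway.aucell_score(ranks, ["nope"])

    def test_improving_a_rank_never_decreases_score(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 40
            perm = rng.permutation(n) + 1
            ranks = pd.Series(perm, index=[f"g{i}" for i in range(n)])
            gene_set = [f"g{i}" for i in rng.choice(n, 5, replace=False)]
            base = pathway.aucell_score(ranks, gene_set, top_fraction=0.25)
            g = gene_set[0]
            target = ranks[g]
            if target == 1:
                continue
            swapped = ranks.copy()
            other = swapped.index[swapped == target - 1][0]
            swapped[g], swapped[other] = target - 1, target
            assert pathway.aucell_score(swapped, gene_set, top_fraction=0.25) >= base


class TestSsgsea:
    def test_worked_example_top_gene(self):
        ranks = _ranks(4, {"g0": 1})
        assert pathway.ssgsea_score(ranks, ["g0"]) == pytest.approx(2.0)

    def test_bottom_gene_negative(self):
        ranks = _ranks(10, {"g0": 10})
        assert pathway.ssgsea_score(ranks, ["g0"]) < 0

    def test_set_equals_universe_errors(self):
        ranks = _ranks(5, {})
        with pytest.raises(ValueError):
            pathway.ssgsea_score(ranks, [f"g{i}" for i in range(5)])


@pytest.mark.parametrize("method", ["aucell", "ssgsea"])
def test_scorers_match_bruteforce_on_random_instances(method):
    rng = np.random.default_rng(8)
    for _ in range(25):
        n = 20
        perm = rng.permutation(n) + 1
        ranks = pd.Series(perm, index=[f"g{i}" for i in range(n)])
        k = int(rng.integers(1, 8))
        gene_set = [f"g{i}" for i in rng.choice(n, k, replace=False)]
        rd = dict(ranks)
        if method == "aucell":
            ours = pathway.aucell_score(ranks, gene_set, top_fraction=0.3)
            assert ours == bf_aucell(rd, gene_set, 0.3)
        else:
            ours = pathway.ssgsea_score(ranks, gene_set, alpha=0.25)
            assert ours == pytest.approx(bf_ssgsea(rd, gene_set, 0.25), abs=1e-9)


class TestScoreAll:
    def test_shape_one_set_three_cells(self):
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 30)),
            index=["c1", "c2", "c3"],
            columns=[f"g{i}" for i in range(30)],
        )
        coll = GeneSetCollection(sets={"S": ["g0", "g1", "g2"]})
        act = pathway.score_all(expr, coll, method="aucell", top_fraction=0.2)
        assert act.values.shape == (1, 3)
        assert ((act.values >= 0) & (act.values <= 1)).all().all()

    def test_zero_overlap_set_scored_missing(self):
        expr = pd.DataFrame(
            np.random.default_rng(1).normal(size=(2, 10)),
            index=["c1", "c2"],
            columns=[f"g{i}" for i in range(10)],
        )
        coll = GeneSetCollection(sets={"S": ["absent"]})
        act = pathway.score_all(expr, coll, method="aucell")
        assert act.values.isna().all().all()

    @pytest.mark.parametrize("method", ["aucell", "ssgsea"])
    def test_monotone_per_cell_transform_invariance(self, method):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(size=(5, 40)),
            index=[f"c{i}" for i in range(5)],
            columns=[f"g{i}" for i in range(40)],
        )
        coll = GeneSetCollection(sets={"S": [f"g{i}" for i in range(6)]})
        transformed = expr.copy()
        for i, idx in enumerate(transformed.index):
            transformed.loc[idx] = np.exp(transformed.loc[idx] * (0.5 + i))
        a = pathway.score_all(expr, coll, method=method, seed=3)
        b = pathway.score_all(transformed, coll, method=method, seed=3)
        assert a.values.equals(b.values)

    @pytest.mark.parametrize("method", ["aucell", "ssgsea"])
    def test_planted_activity_separates_cells(self, method):
        gene_set = [f"G{i:04d}" for i in range(10)]
        expr, labels = synthetic.gen_pathway_cells(
            150, 300, gene_set, effect=3.0, frac_active=0.5, seed=4
        )
        coll = GeneSetCollection(sets={"S": gene_set})
        act = pathway.score_all(expr, coll, method=method, seed=4)
        auc = roc_auc(act.values.loc["S"].to_numpy(), (labels == "active").to_numpy())
        assert auc >= 0.9

    def test_null_effect_gives_chance_auc(self):
        gene_set = [f"G{i:04d}" for i in range(10)]
        expr, labels = synthetic.gen_pathway_cells(
            200, 200, gene_set, effect=0.0, frac_active=0.5, seed=5
        )
        coll = GeneSetCollection(sets={"S": gene_set})
        act = pathway.score_all(expr, coll, method="aucell", seed=5)
        auc = roc_auc(act.values.loc["S"].to_numpy(), (labels == "active").to_numpy())
        assert abs(auc - 0.5) < 0.12


def test_cluster_mean_activity_table():
    vals = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["S"], columns=list("abcd"))
    act = pathway.ActivityMatrix(values=vals, method="aucell")
    assign = pd.Series(["1", "1", "2", "2"], index=list("abcd"))
    tab = pathway.cluster_mean_activity(act, assign)
    assert tab.loc["S", "1"] == 1.5 and tab.loc["S", "2"] == 3.5
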