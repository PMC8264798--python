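"""Co-expression annotation, ORA, preranked GSEA and ssGSEA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernet.io import GeneSetCollection
from cernet.de import run_de, de_gene_sets
from cernet.enrichment import (
    bh_adjust,
    coexpression_partners,
    compare_group_scores,
    module_pathway_correlation,
    ora_collection,
    ora_hypergeometric,
    preranked_gsea,
    ssgsea_scores,
)


class TestCoexpressionPartners:
    def test_identical_mrna_ranks_first(self):
        rng = np.random.default_rng(0)
        nc = pd.DataFrame([rng.normal(size=10)], index=["NC1"])
        mr = pd.DataFrame(
            np.vstack([nc.iloc[0], rng.normal(size=(4, 10))]),
            index=["TWIN", "A", "B", "C", "D"],
        )
        nc.columns = mr.columns = [f"s{i}" for i in range(10)]
        top = coexpression_partners(nc, mr, top_n=3)
        assert top.index[0] == "TWIN"
        assert top.iloc[0] == pytest.approx(1.0)

    def test_short_pool_returned_whole(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(8)]
        nc = pd.DataFrame(rng.normal(size=(2, 8)), index=["N1", "N2"], columns=cols)
        mr = pd.DataFrame(rng.normal(size=(5, 8)), index=list("ABCDE"), columns=cols)
        with pytest.warns(UserWarning, match="top_n"):
            top = coexpression_partners(nc, mr, top_n=500)
        assert len(top) == 5

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(15)]
        nc = pd.DataFrame(rng.normal(size=(3, 15)), index=["N1", "N2", "N3"], columns=cols)
        mr = pd.DataFrame(rng.normal(size=(10, 15)), index=[f"G{i}" for i in range(10)], columns=cols)
        top = coexpression_partners(nc, mr, top_n=10)
        ref = {}
        for g in mr.index:
            rs = [np.corrcoef(nc.loc[n], mr.loc[g])[0, 1] for n in nc.index]
            ref[g] = np.mean(rs)
        ref_order = sorted(ref, key=lambda g: (-ref[g], g))
        assert list(top.index) == ref_order
        for g in top.index:
            assert top[g] == pytest.approx(ref[g], abs=1e-12)


class TestOra:
    def test_exact_combinatorial_example(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}  # overlap k = 4
        res = ora_hypergeometric(query, gene_set, universe)
        assert res.k == 4
        assert res.p == pytest.approx(76 / 15504, rel=1e-12)

    def test_zero_overlap_full_mass(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_hypergeometric({"g0", "g1"}, {"g8", "g9"}, universe - set())
        assert res.p <= 1.0
        res0 = ora_hypergeometric({"g0"}, {"g9"}, universe)
        assert res0.k == 0 and res0.p == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = {f"g{i}" for i in range(6)}
        res = ora_hypergeometric(universe, {"g0", "g1"}, universe)
        assert res.k == res.K and res.p == pytest.approx(1.0)

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"g"}, set())

    def test_matches_exhaustive_enumeration_small_universe(self):
        """p equals the fraction of n-subsets with overlap >= k, N <= 12."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            N = int(rng.integers(4, 13))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            gene_set = set(rng.choice(universe, size=K, replace=False))
            query = set(rng.choice(universe, size=n, replace=False))
            k = len(gene_set & query)
            count = sum(
                1
                for draw in itertools.combinations(universe, n)
                if len(set(draw) & gene_set) >= k
            )
            p_ref = count / math.comb(N, n)
            res = ora_hypergeometric(query, gene_set, set(universe))
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_planted_sets_beat_random_sets(self, default_cohort, de_by_class):
        _, _, _, gene_sets, truth = default_cohort
        query = de_gene_sets(de_by_class["mRNA"])["all"]
        universe = set(de_by_class["mRNA"]["gene_id"])
        table = ora_collection(query, gene_sets, universe).set_index("set_name")
        planted_p = table.loc[list(truth.enriched_sets), "p"].max()
        random_p = table.drop(index=truth.enriched_sets)["p"].min()
        assert planted_p < random_p
        # BH keeps the ordering and q >= p
        assert (table["q"] + 1e-15 >= table["p"]).all()


def test_bh_matches_hand_step_up():
    """BH against a direct step-up implementation on random p-vectors."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        ref = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            ref[i] = prev
        assert np.allclose(q, ref, atol=1e-12)
        assert (q >= p - 1e-12).all()


def _brute_preranked_es(ranked, weights, members):
    run, best = 0.0, 0.0
    in_sum = sum(abs(w) for g, w in zip(ranked, weights) if g in members) or None
    n_out = sum(1 for g in ranked if g not in members)
    if in_sum is None:
        in_sum = sum(1 for g in ranked if g in members)
        weights = [1.0] * len(ranked)
    for g, w in zip(ranked, weights):
        run += abs(w) / in_sum if g in members else -1.0 / n_out
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankedGsea:
    def test_top_two_of_ten(self):
        ranked = [f"g{i}" for i in range(10)]
        res = preranked_gsea(ranked, [1.0] * 10, {"g0", "g1"}, n_perm=200, seed=0)
        # brute-force walk: +1/2, +1/2 then -1/8 steps; peak after both members
        assert res.es == pytest.approx(1.0)
        assert 1 / 201 <= res.p_perm <= 1.0

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(5)
        ranked = [f"g{i}" for i in range(20)]
        w = np.linspace(2, -2, 20)
        members = {"g0", "g3", "g5"}
        res = preranked_gsea(ranked, w, members, n_perm=50, seed=0)
        res_rev = preranked_gsea(ranked[::-1], w[::-1], members, n_perm=50, seed=0)
        assert res_rev.es == pytest.approx(-res.es)

    def test_matches_brute_force_walk(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(8, 30))
            ranked = [f"g{i}" for i in range(n)]
            w = rng.normal(size=n)
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(ranked, size=k, replace=False))
            res = preranked_gsea(ranked, w, members, n_perm=10, seed=0)
            assert res.es == pytest.approx(_brute_preranked_es(ranked, w, members), abs=1e-9)

    def test_no_overlap_error(self):
        with pytest.raises(ValueError, match="overlap"):
            preranked_gsea(["a", "b"], [1, 1], {"zzz"}, n_perm=10)


def _brute_ssgsea_es(expr_col: pd.Series, members: set, tau: float) -> float:
    """Independent walk: tie-averaged descending ranks, cumulative fractions."""
    genes = list(expr_col.index)
    from scipy.stats import rankdata

    rank_weight = rankdata(expr_col.to_numpy())  # highest value -> largest
    order = sorted(range(len(genes)), key=lambda i: (-expr_col.iloc[i], i))
    w_in = [rank_weight[i] ** tau if genes[i] in members else 0.0 for i in order]
    denom = sum(w_in)
    n_out = sum(1 for g in genes if g not in members)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        cum_in += w_in[pos] / denom
        if genes[i] not in members:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


class TestSsgsea:
    def _toy(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.lognormal(size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=list("abcd"),
        )
        sets = GeneSetCollection(
            sets={"TOP": {"g0", "g1", "g2"}, "MIX": {"g3", "g7", "g9"}},
            descriptions={},
        )
        return expr, sets

    def test_identical_rankings_identical_scores(self):
        expr, sets = self._toy()
        expr["b"] = expr["a"] * 3.0  # same within-sample ranking
        scores = ssgsea_scores(expr, sets)
        assert np.allclose(scores["a"], scores["b"])

    def test_monotone_transform_invariance(self):
        expr, sets = self._toy()
        ref = ssgsea_scores(expr, sets, normalize=False)
        expr2 = expr.copy()
        expr2["c"] = np.exp(expr2["c"])
        out = ssgsea_scores(expr2, sets, normalize=False)
        assert np.allclose(ref["c"], out["c"])

    @pytest.mark.parametrize("tau", [0.0, 0.25, 1.0])
    def test_matches_brute_force_walk(self, tau):
        expr, sets = self._toy()
        scores = ssgsea_scores(expr, sets, tau=tau, normalize=False)
        for name in sets.names():
            for col in expr.columns:
                ref = _brute_ssgsea_es(expr[col], sets[name], tau)
                assert scores.loc[name, col] == pytest.approx(ref, abs=1e-9)

    def test_unexpressed_set_warns_nan(self):
        expr, _ = self._toy()
        sets = GeneSetCollection(sets={"GHOST": {"zzz"}}, descriptions={})
        with pytest.warns(UserWarning, match="GHOST"):
            scores = ssgsea_scores(expr, sets)
        assert scores.isna().all().all()


class TestModulePathwayCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(12)]
        mod = pd.Series(rng.normal(size=12), index=samples)
        scores = pd.DataFrame([mod.to_numpy()], index=["SELF"], columns=samples)
        tab = module_pathway_correlation(mod, scores)
        assert tab.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_pathway_flagged(self):
        samples = [f"s{i}" for i in range(6)]
        mod = pd.Series(np.arange(6.0), index=samples)
        scores = pd.DataFrame([[1.0] * 6], index=["CONST"], columns=samples)
        tab = module_pathway_correlation(mod, scores)
        assert not tab.loc[0, "defined"]
        assert np.isnan(tab.loc[0, "r"])

    def test_planted_set_positively_correlated(self, default_cohort, default_modules):
        bundle, _, _, gene_sets, truth = default_cohort
        scores = ssgsea_scores(bundle.mrna, gene_sets)
        # module score over the planted prognostic module
        nodes = sorted(truth.planted_modules[truth.prognostic_module_index])
        mod_score = np.log2(bundle.stacked().loc[nodes] + 0.01).mean(axis=0)
        tab = module_pathway_correlation(mod_score, scores).set_index("set_name")
        planted_name = truth.enriched_sets[truth.prognostic_module_index]
        assert tab.loc[planted_name, "r"] > 0.3

    def test_shuffled_labels_kill_correlation(self, default_cohort):
        bundle, _, _, gene_sets, truth = default_cohort
        scores = ssgsea_scores(bundle.mrna, gene_sets)
        nodes = sorted(truth.planted_modules[0])
        mod_score = np.log2(bundle.stacked().loc[nodes] + 0.01).mean(axis=0)
        rng = np.random.default_rng(9)
        shuffled = pd.Series(
            rng.permutation(mod_score.to_numpy()), index=mod_score.index
        )
        tab = module_pathway_correlation(shuffled, scores)
        planted = tab.set_index("set_name").loc[truth.enriched_sets[0], "r"]
        assert abs(planted) < 0.3


class TestCompareGroupScores:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(40)]
        scores = pd.DataFrame(rng.normal(size=(3, 40)), index=list("XYZ"), columns=samples)
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=samples)
        tab = compare_group_scores(scores, labels)
        assert len(tab) == 3
        assert (tab["p"] > 0.01).all()

    def test_shifted_set_detected(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(80)]
        base = rng.normal(size=(2, 80))
        base[0, :40] += 2 * base[0].std()
        scores = pd.DataFrame(base, index=["SHIFTED", "NULL"], columns=samples)
        labels = pd.Series(["a"] * 40 + ["b"] * 40, index=samples)
        tab = compare_group_scores(scores, labels).set_index("set_name")
        assert tab.loc["SHIFTED", "p"] < 0.01

    def test_empty_group_error(self):
        scores = pd.DataFrame([[1.0, 2.0]], index=["X"], columns=["s1", "s2"])
        labels = pd.Series(["a", "a"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            compare_group_scores(scores, labels)


def test_tumor_vs_normal_scores_on_fixture(default_cohort):
    """Planted sets separate tumor from normal in ssGSEA score space."""
    bundle, samples, _, gene_sets, truth = default_cohort
    scores = ssgsea_scores(bundle.mrna, gene_sets)
    labels = samples.set_index("sample_id")["condition"]
    tab = compare_group_scores(scores, labels).set_index("set_name")
    assert (tab.loc[truth.enriched_sets, "q"] < 0.01).all()
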