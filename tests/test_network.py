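"""AGO filter, correlation gate and the two-step network construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.io import ExpressionBundle
from cernet.network import (
    DysregulatedNetwork,
    build_network,
    degree_summary,
    filter_ago,
    pearson_with_p,
)


def _catalog(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class", "ago_sites"])


def _de_table(genes_up):
    return pd.DataFrame({"gene_id": list(genes_up), "direction": ["up"] * len(genes_up)})


def _bundle_from_log(log_values: dict[str, np.ndarray], classes: dict[str, str]):
    """ExpressionBundle from log2-scale rows (pseudocount-free exponent)."""
    samples = [f"S{i}" for i in range(len(next(iter(log_values.values()))))]
    frames = {"mRNA": {}, "lncRNA": {}, "miRNA": {}}
    for g, v in log_values.items():
        frames[classes[g]][g] = np.exp2(np.asarray(v, dtype=float))
    def mk(cls):
        d = frames[cls]
        if not d:
            return pd.DataFrame(index=pd.Index([]), columns=samples, dtype=float)
        return pd.DataFrame(d, index=samples).T
    return ExpressionBundle(mrna=mk("mRNA"), lncrna=mk("lncRNA"), mirna=mk("miRNA"))


class TestAgoFilter:
    def test_at_least_one_site_kept(self):
        cat = _catalog([("M1", "G1", "mRNA", 1), ("M1", "G2", "mRNA", 0)])
        out = filter_ago(cat)
        assert out["target_id"].tolist() == ["G1"]

    def test_toy_counts(self):
        sites = [2, 0, 1, 0, 3]
        cat = _catalog([("M1", f"G{i}", "mRNA", s) for i, s in enumerate(sites)])
        assert len(filter_ago(cat)) == 3
        assert len(filter_ago(cat, min_sites=2)) == 2


class TestPearsonWithP:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-30
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_from_t_transform(self):
        # r ~ 0.3 at n = 10 fails the p < 0.01 gate by an order of magnitude
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, p = pearson_with_p(x, y)
            t = r * np.sqrt(8 / (1 - r * r))
            assert p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)
        assert 2 * stats.t.sf(0.3 * np.sqrt(8 / (1 - 0.09)), 8) == pytest.approx(0.3997, abs=1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])


class TestBuildNetwork:
    def test_shared_mirna_rule_drops_lncrna_free_mirna(self):
        """miRNA A (1 lncRNA + 2 mRNA edges) kept; miRNA B (mRNA only) dropped."""
        rng = np.random.default_rng(0)
        base_a = rng.normal(size=12)
        base_b = rng.normal(size=12)
        log_values = {
            "MIRA": base_a,
            "L1": -base_a + 0.01 * rng.normal(size=12),
            "G1": -base_a + 0.01 * rng.normal(size=12),
            "G2": base_a + 0.01 * rng.normal(size=12),
            "MIRB": base_b,
            "G3": base_b + 0.01 * rng.normal(size=12),
            "G4": -base_b + 0.01 * rng.normal(size=12),
        }
        classes = {"MIRA": "miRNA", "MIRB": "miRNA", "L1": "lncRNA",
                   "G1": "mRNA", "G2": "mRNA", "G3": "mRNA", "G4": "mRNA"}
        bundle = _bundle_from_log(log_values, classes)
        cat = _catalog(
            [
                ("MIRA", "L1", "lncRNA", 1),
                ("MIRA", "G1", "mRNA", 1),
                ("MIRA", "G2", "mRNA", 1),
                ("MIRB", "G3", "mRNA", 1),
                ("MIRB", "G4", "mRNA", 1),
            ]
        )
        de = {
            "mRNA": _de_table(["G1", "G2", "G3", "G4"]),
            "lncRNA": _de_table(["L1"]),
            "miRNA": _de_table(["MIRA", "MIRB"]),
        }
        net = build_network(de, cat, bundle)
        assert net.n_nodes == 4
        assert net.n_edges == 3
        assert "MIRB" not in net.graph
        net.check_invariants()

    def test_weak_correlation_excluded_regardless_of_p(self):
        """|r| = 0.25 fails the |r| > 0.3 gate even with a tiny p-value."""
        rng = np.random.default_rng(1)
        n = 2000  # p for r=0.25 at this n is << 0.01
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z2 = (z2 - z2 @ z1 / (z1 @ z1) * z1)  # orthogonalize
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = (z2 - z2.mean()) / z2.std()
        rho = 0.25
        y = rho * z1 + np.sqrt(1 - rho**2) * z2
        base = rng.normal(size=n)
        log_values = {"MIRA": z1, "G1": y, "L1": -z1 + 0.01 * rng.normal(size=n)}
        classes = {"MIRA": "miRNA", "G1": "mRNA", "L1": "lncRNA"}
        bundle = _bundle_from_log(log_values, classes)
        r_check, p_check = pearson_with_p(np.log2(bundle.mirna.loc["MIRA"] + 0.01),
                                          np.log2(bundle.mrna.loc["G1"] + 0.01))
        assert abs(r_check) < 0.3 and p_check < 0.01
        cat = _catalog([("MIRA", "G1", "mRNA", 1), ("MIRA", "L1", "lncRNA", 1)])
        de = {"mRNA": _de_table(["G1"]), "lncRNA": _de_table(["L1"]), "miRNA": _de_table(["MIRA"])}
        net = build_network(de, cat, bundle)
        assert ("MIRA", "G1") not in set(zip(net.edges.mirna_id, net.edges.target_id))

    def test_no_de_mirnas_gives_empty_network(self):
        rng = np.random.default_rng(2)
        log_values = {"MIRA": rng.normal(size=10), "G1": rng.normal(size=10),
                      "L1": rng.normal(size=10)}
        classes = {"MIRA": "miRNA", "G1": "mRNA", "L1": "lncRNA"}
        bundle = _bundle_from_log(log_values, classes)
        cat = _catalog([("MIRA", "G1", "mRNA", 1)])
        de = {"mRNA": _de_table(["G1"]), "lncRNA": _de_table(["L1"]),
              "miRNA": _de_table([])}
        with pytest.warns(UserWarning, match="empty"):
            net = build_network(de, cat, bundle)
        assert net.n_edges == 0

    def test_r_threshold_monotonicity(self, default_cohort, de_by_class):
        bundle, _, catalog, _, _ = default_cohort
        counts = []
        for r_thr in (0.2, 0.4, 0.6, 0.8):
            net = build_network(de_by_class, filter_ago(catalog), bundle, r_threshold=r_thr)
            counts.append(net.n_edges)
        assert counts == sorted(counts, reverse=True)


class TestDegreeSummary:
    def test_star(self):
        g = DysregulatedNetwork()
        import networkx as nx

        graph = nx.star_graph(12)
        nx.set_node_attributes(graph, "mRNA", "rna_class")
        g.graph = graph
        frac_lt5, frac_gt10, hist = degree_summary(g)
        assert frac_lt5 == pytest.approx(12 / 13)
        assert frac_gt10 == pytest.approx(1 / 13)
        assert hist == {12: 1, 1: 12}

    def test_single_edge(self):
        import networkx as nx

        g = DysregulatedNetwork(graph=nx.Graph([("a", "b")]))
        frac_lt5, frac_gt10, _ = degree_summary(g)
        assert frac_lt5 == 1.0 and frac_gt10 == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            degree_summary(DysregulatedNetwork())

    def test_default_cohort_mostly_low_degree(self, default_network):
        frac_lt5, _, _ = degree_summary(default_network)
        assert frac_lt5 >= 0.7
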