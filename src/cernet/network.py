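"""Construction of the dysregulated lncRNA-miRNA-mRNA network.

Starting from per-class differential-expression calls and an AGO-supported
miRNA-target catalog, the network keeps an edge only when

1. both endpoints are differentially expressed (step 0),
2. the miRNA-target expression correlation across all samples (tumor and
   normal pooled) is strong and significant (|r| > r_threshold and
   p < p_threshold, both strict), and
3. the miRNA retains at least one passing lncRNA edge *and* one passing
   mRNA edge (the shared-miRNA rule of a competing-endogenous-RNA design);
   miRNAs failing this are removed together with their edges and any target
   that becomes isolated.

Correlations are computed on log2(x + pseudocount); pooling tumor and
normal inflates |r| for pairs that are differentially expressed in
opposite directions, which is precisely the dysregulation signal this
design selects for (and a documented caveat for co-regulated pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionBundle

logger = logging.getLogger("cernet")


def filter_ago(catalog: pd.DataFrame, min_sites: int = 1) -> pd.DataFrame:
    """Keep miRNA-target pairs with at least ``min_sites`` AGO binding sites."""
    return catalog.loc[catalog["ago_sites"] >= min_sites].reset_index(drop=True)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from the t transform.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom.  Constant input raises (the caller drops such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("pearson_with_p requires n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


@dataclass
class DysregulatedNetwork:
    """Tri-class bipartite graph of correlation-validated DE interactions."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["mirna_id", "target_id", "target_class", "r", "p"]
        )
    )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, rna_class: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["rna_class"] == rna_class}

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.nodes_of_class(c)) for c in ("mRNA", "lncRNA", "miRNA")}

    def check_invariants(self) -> None:
        g = self.graph
        for node in g.nodes:
            if g.degree(node) == 0:
                raise AssertionError(f"isolated node {node}")
        for mi in self.nodes_of_class("miRNA"):
            classes = {g.nodes[nb]["rna_class"] for nb in g.neighbors(mi)}
            if not {"mRNA", "lncRNA"} <= classes:
                raise AssertionError(f"miRNA {mi} violates the shared-miRNA rule")
        for u, v in g.edges:
            cu, cv = g.nodes[u]["rna_class"], g.nodes[v]["rna_class"]
            if "miRNA" not in (cu, cv) or cu == cv:
                raise AssertionError(f"edge {u}-{v} is not miRNA-target")


def build_network(
    de_by_class: dict[str, pd.DataFrame],
    catalog: pd.DataFrame,
    bundle: ExpressionBundle,
    r_threshold: float = 0.3,
    p_threshold: float = 0.01,
    require_negative: bool = False,
    pseudocount: float = 0.01,
) -> DysregulatedNetwork:
    """Apply the two-step dysregulated-network filter.

    ``de_by_class`` maps 'mRNA'/'lncRNA'/'miRNA' to run_de output tables;
    the catalog is assumed already AGO-filtered (see :func:`filter_ago`).
    ``require_negative`` additionally restricts edges to r < 0 (canonical
    miRNA repression); off by default because the selection criterion is
    |r| alone.
    """
    de_dir: dict[str, str] = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        t = de_by_class[cls]
        de = t.loc[t["direction"] != "ns"]
        de_dir.update(dict(zip(de["gene_id"], de["direction"])))

    # step 0: restrict to DE miRNA and DE target
    cat = catalog.loc[
        catalog["mirna_id"].isin(de_dir) & catalog["target_id"].isin(de_dir)
    ]

    # step 1: correlation gate across all samples, log2 scale
    log_expr = np.log2(bundle.stacked() + pseudocount)
    kept_rows = []
    for row in cat.itertuples(index=False):
        x = log_expr.loc[row.mirna_id].to_numpy()
        y = log_expr.loc[row.target_id].to_numpy()
        try:
            r, p = pearson_with_p(x, y)
        except ValueError:
            continue
        if abs(r) > r_threshold and p < p_threshold and (not require_negative or r < 0):
            kept_rows.append((row.mirna_id, row.target_id, row.target_class, r, p))
    edges = pd.DataFrame(kept_rows, columns=["mirna_id", "target_id", "target_class", "r", "p"])

    # step 2: shared-miRNA rule, then drop orphaned targets
    classes_by_mirna = edges.groupby("mirna_id")["target_class"].agg(set)
    good_mirnas = set(classes_by_mirna.index[classes_by_mirna.apply(lambda s: {"mRNA", "lncRNA"} <= s)])
    edges = edges.loc[edges["mirna_id"].isin(good_mirnas)].reset_index(drop=True)

    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_node(row.mirna_id, rna_class="miRNA", direction=de_dir[row.mirna_id])
        graph.add_node(
            row.target_id, rna_class=row.target_class, direction=de_dir[row.target_id]
        )
        graph.add_edge(row.mirna_id, row.target_id, r=row.r, p=row.p)

    net = DysregulatedNetwork(graph=graph, edges=edges)
    if net.n_edges == 0:
        warnings.warn("dysregulated network is empty", stacklevel=2)
    else:
        net.check_invariants()
        logger.info(
            "build_network: %d edges, class counts %s", net.n_edges, net.class_counts()
        )
    return net


def degree_summary(network: DysregulatedNetwork) -> tuple[float, float, dict[int, int]]:
    """Fraction of nodes with degree < 5 and > 10, plus the degree histogram.

    The paper-style scale-free check: a dysregulated network dominated by
    low-degree RNAs with a handful of hubs.
    """
    if network.n_nodes == 0:
        raise ValueError("degree summary undefined for an empty network")
    degrees = [d for _, d in network.graph.degree()]
    n = len(degrees)
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    frac_lt5 = sum(1 for d in degrees if d < 5) / n
    frac_gt10 = sum(1 for d in degrees if d > 10) / n
    return frac_lt5, frac_gt10, hist


def write_edge_list(network: DysregulatedNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path, de_direction: dict[str, str] | None = None) -> DysregulatedNetwork:
    """Rebuild a network from the edge-list TSV written by write_edge_list."""
    edges = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str})
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        dmi = (de_direction or {}).get(row.mirna_id, "na")
        dtg = (de_direction or {}).get(row.target_id, "na")
        graph.add_node(row.mirna_id, rna_class="miRNA", direction=dmi)
        graph.add_node(row.target_id, rna_class=row.target_class, direction=dtg)
        graph.add_edge(row.mirna_id, row.target_id, r=row.r, p=row.p)
    return DysregulatedNetwork(graph=graph, edges=edges)
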