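"""Module detection on the dysregulated network.

A deterministic, size-capped agglomerative clustering over edge weights:
edges are processed in order of decreasing |r| (ties broken
lexicographically on (mirna_id, target_id)) through a union-find; two
clusters merge only when the merged node count stays within ``max_size``.
Clusters of at least ``min_size`` nodes that contain all three RNA classes
(when required) are emitted as modules, ordered by decreasing mean |r| of
their induced edges.

This is a documented surrogate for hierarchical edge-weight clustering of
interaction networks: classic common-neighbor edge scores degenerate on a
bipartite miRNA-target graph (a miRNA and its target share no neighbors),
so the correlation weight itself drives the agglomeration.  The output is
invariant to any permutation of input node or edge order, and modules are
node-disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import DysregulatedNetwork


@dataclass
class ModuleParams:
    max_size: int = 20
    min_size: int = 6
    min_edge_strength: float = 0.0
    require_all_classes: bool = True

    def validate(self) -> None:
        if not (2 <= self.min_size <= self.max_size):
            raise ValueError("need 2 <= min_size <= max_size")
        if self.min_edge_strength < 0:
            raise ValueError("min_edge_strength must be >= 0")


@dataclass
class Module:
    module_id: str
    nodes_by_class: dict[str, list[str]]
    edges: list[tuple[str, str, float]]  # (mirna, target, r)
    mean_abs_r: float

    @property
    def nodes(self) -> set[str]:
        return {n for ns in self.nodes_by_class.values() for n in ns}

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.nodes_by_class.values())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def summary(self) -> dict:
        """Per-class node counts plus interaction count."""
        return {
            "module_id": self.module_id,
            "n_mrna": len(self.nodes_by_class.get("mRNA", [])),
            "n_lncrna": len(self.nodes_by_class.get("lncRNA", [])),
            "n_mirna": len(self.nodes_by_class.get("miRNA", [])),
            "n_interactions": self.n_edges,
            "mean_abs_r": self.mean_abs_r,
        }

    def to_jsonable(self) -> dict:
        return {
            "module_id": self.module_id,
            "nodes_by_class": {c: sorted(v) for c, v in self.nodes_by_class.items()},
            "edges": [[u, v, r] for u, v, r in self.edges],
            "mean_abs_r": self.mean_abs_r,
        }


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union_capped(self, a, b, cap: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return True
        if self.size[ra] + self.size[rb] > cap:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return True


def detect_modules(network: DysregulatedNetwork, params: ModuleParams | None = None) -> list[Module]:
    params = params or ModuleParams()
    params.validate()
    g = network.graph
    if g.number_of_nodes() == 0:
        return []

    # canonical edge order: |r| descending, then lexicographic (miRNA, target)
    def edge_key(e):
        u, v, data = e
        mi, tg = (u, v) if g.nodes[u]["rna_class"] == "miRNA" else (v, u)
        return (-abs(data["r"]), mi, tg)

    edges = sorted(g.edges(data=True), key=edge_key)
    uf = _UnionFind(sorted(g.nodes))
    for u, v, data in edges:
        if abs(data["r"]) < params.min_edge_strength:
            continue
        uf.union_capped(u, v, params.max_size)

    clusters: dict[str, list[str]] = {}
    for node in g.nodes:
        clusters.setdefault(uf.find(node), []).append(node)

    modules: list[Module] = []
    for members in clusters.values():
        if len(members) < params.min_size:
            continue
        by_class: dict[str, list[str]] = {"mRNA": [], "lncRNA": [], "miRNA": []}
        for n in sorted(members):
            by_class[g.nodes[n]["rna_class"]].append(n)
        if params.require_all_classes and any(not v for v in by_class.values()):
            continue
        sub = g.subgraph(members)
        mod_edges = []
        for u, v, data in sub.edges(data=True):
            mi, tg = (u, v) if g.nodes[u]["rna_class"] == "miRNA" else (v, u)
            mod_edges.append((mi, tg, float(data["r"])))
        mod_edges.sort()
        mean_abs_r = float(np.mean([abs(r) for _, _, r in mod_edges])) if mod_edges else 0.0
        modules.append(
            Module(
                module_id="",
                nodes_by_class=by_class,
                edges=mod_edges,
                mean_abs_r=mean_abs_r,
            )
        )

    # deterministic ordering: strongest internal correlation first; node-list
    # tiebreak keeps the ordering total
    modules.sort(key=lambda m: (-m.mean_abs_r, sorted(m.nodes)))
    for i, m in enumerate(modules):
        m.module_id = f"M{i + 1}"
    return modules


def module_summary(module: Module) -> dict:
    return module.summary()


def modules_to_jsonable(modules: list[Module]) -> list[dict]:
    return [m.to_jsonable() for m in modules]


def modules_from_jsonable(obj: list[dict]) -> list[Module]:
    out = []
    for d in obj:
        edges = [(u, v, float(r)) for u, v, r in d["edges"]]
        out.append(
            Module(
                module_id=d["module_id"],
                nodes_by_class={c: list(v) for c, v in d["nodes_by_class"].items()},
                edges=edges,
                mean_abs_r=float(d["mean_abs_r"]),
            )
        )
    return out
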