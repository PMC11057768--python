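"""Module detection and core-gene extraction on the nearest-neighbor network.

Modules come from the Girvan-Newman procedure: repeatedly remove the
edge with the highest betweenness (recomputing betweenness after every
removal) on the undirected, unweighted projection of the network.  The
partition kept is either the one maximizing Newman modularity along the
removal sequence (default) or the first to reach a fixed component
count.

The core of a module is its maximal k-core: the non-empty k-core with
the largest k, computed on the undirected projection (or with total
degree in+out in directed mode).  Cores are characterized by
coordination (directed density |E| / |V|(|V|-1)) and reachability (the
fraction of network nodes with a directed path, of length >= 0, from at
least one core node).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "ModulePartition",
    "CoreResult",
    "detect_modules",
    "find_core",
    "coordination_density",
    "reachability",
    "extract_cores",
]


@dataclass
class ModulePartition:
    modules: list  # list of frozenset of gene ids, largest first
    method: str = "girvan_newman"
    stop_rule: str = "max_modularity"
    modularity: float | None = None

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self) -> dict:
        """gene -> 1-based module id (modules ordered by decreasing size)."""
        return {g: i + 1 for i, mod in enumerate(self.modules) for g in mod}


@dataclass
class CoreResult:
    module_id: int
    core_genes: frozenset
    k: int
    density: float
    reachability: float
    mode: str = "undirected"


def _most_valuable_edge(g: nx.Graph):
    """Max-betweenness edge; ties broken by lexicographically smallest label."""
    bw = nx.edge_betweenness_centrality(g, normalized=False)
    return min(bw, key=lambda e: (-bw[e], tuple(sorted(map(str, e)))))


def _sorted_partition(components) -> list:
    mods = [frozenset(c) for c in components]
    return sorted(mods, key=lambda m: (-len(m), min(map(str, m))))


def detect_modules(
    g: nx.Graph | nx.DiGraph,
    stop_rule: str = "max_modularity",
    n_modules: int | None = None,
    max_modules: int = 12,
) -> ModulePartition:
    """Girvan-Newman community detection on the undirected projection.

    Parameters
    ----------
    stop_rule : {"max_modularity", "fixed_count"}
        ``max_modularity`` scans the edge-removal sequence (up to
        `max_modules` components) and returns the partition with the
        highest Newman modularity; ``fixed_count`` stops as soon as the
        component count reaches `n_modules`.
    max_modules : int
        Search horizon for ``max_modularity``; modularity on these
        networks peaks at a handful of modules, so a small cap keeps
        the O(removals x V x E) betweenness recomputation tractable.

    Disconnected components are separate modules from the start.  Edge
    weights and directions are ignored.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if stop_rule not in ("max_modularity", "fixed_count"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    ug = nx.Graph()
    ug.add_nodes_from(g.nodes())
    ug.add_edges_from((u, v) for u, v in g.edges() if u != v)

    parts = _sorted_partition(nx.connected_components(ug))
    if stop_rule == "fixed_count":
        if n_modules is None:
            raise ValueError("fixed_count requires n_modules")
        if n_modules < len(parts):
            raise ValueError(
                f"n_modules={n_modules} below the {len(parts)} initial components"
            )

    work = ug.copy()
    best = parts
    best_q = nx.community.modularity(ug, parts) if ug.number_of_edges() else 0.0
    current = parts
    while work.number_of_edges():
        if stop_rule == "fixed_count" and len(current) >= n_modules:
            return ModulePartition(current, stop_rule=stop_rule)
        if stop_rule == "max_modularity" and len(current) >= max_modules:
            break
        edge = _most_valuable_edge(work)
        work.remove_edge(*edge)
        parts = _sorted_partition(nx.connected_components(work))
        if len(parts) > len(current):
            current = parts
            q = nx.community.modularity(ug, parts)
            if q > best_q:
                best, best_q = parts, q
    if stop_rule == "fixed_count":
        # every edge removed: components are singletons
        return ModulePartition(current, stop_rule=stop_rule)
    return ModulePartition(best, stop_rule=stop_rule, modularity=best_q)


def find_core(
    module_graph: nx.DiGraph, mode: str = "undirected", module_id: int = 1
) -> CoreResult:
    """Maximal k-core of one module.

    In undirected mode the peeling runs on the undirected projection; in
    directed mode it uses total degree (in + out) on the directed graph.
    A singleton module is its own core with k = 0.  Density and
    reachability are computed within the module subgraph; callers that
    want reachability over the whole network should recompute it there
    (see `extract_cores`).
    """
    if mode not in ("undirected", "directed"):
        raise ValueError(f"unknown mode {mode!r}")
    if module_graph.number_of_nodes() == 0:
        raise ValueError("module is empty")
    h = module_graph.copy()
    h.remove_edges_from(nx.selfloop_edges(h))
    peel = h if mode == "directed" else nx.Graph(h.to_undirected())
    core_num = nx.core_number(peel)
    k = max(core_num.values())
    core = frozenset(n for n, c in core_num.items() if c >= k)
    core_sub = module_graph.subgraph(core)
    return CoreResult(
        module_id=module_id,
        core_genes=core,
        k=k,
        density=coordination_density(core_sub),
        reachability=reachability(module_graph, core),
        mode=mode,
    )


def coordination_density(core_graph: nx.DiGraph) -> float:
    """Directed density |E| / (|V| (|V|-1)); 0 for |V| <= 1."""
    n = core_graph.number_of_nodes()
    if n <= 1:
        return 0.0
    e = sum(1 for u, v in core_graph.edges() if u != v)
    return e / (n * (n - 1))


def reachability(full_graph: nx.DiGraph, core) -> float:
    """Fraction of all nodes reachable from at least one core node.

    Paths of length 0 count: core nodes are always reached.  Returns 0
    for an empty core.
    """
    core = set(core)
    if not core:
        return 0.0
    missing = core - set(full_graph.nodes())
    if missing:
        raise KeyError(f"core nodes not in graph: {sorted(missing)}")
    reached = set(core)
    for u in core:
        reached |= nx.descendants(full_graph, u)
    return len(reached) / full_graph.number_of_nodes()


def extract_cores(
    g: nx.DiGraph, partition: ModulePartition, mode: str = "undirected"
) -> list[CoreResult]:
    """Per-module cores, with reachability measured over the whole network."""
    results = []
    for i, module in enumerate(partition.modules, start=1):
        res = find_core(g.subgraph(module).copy(), mode=mode, module_id=i)
        res.reachability = reachability(g, res.core_genes)
        results.append(res)
    return results
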