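"""Greedy nearest-neighbor network construction.

Starting from the variational genes of the perturbed-condition network,
nodes are admitted one at a time along the single highest-weight edge
(in either direction) that crosses from the current node set to the
outside, provided that edge's weight is at or above the Z-percentile
threshold tau of all off-diagonal weights.  Growth stops when no
crossing edge >= tau remains; finally every edge >= tau between admitted
nodes is included, so the subnetwork carries the highest-weight edges
among the variational genes and their neighbors.

The result is a networkx DiGraph whose nodes carry a ``role`` attribute
("variational" or "neighbor") and whose graph attributes record ``tau``
and the source condition.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .inference import InfluenceNetwork

__all__ = ["nn_edge_threshold", "build_nn_network"]


def nn_edge_threshold(net: InfluenceNetwork, z_percentile: float) -> float:
    """Linear-interpolation percentile of all N(N-1) off-diagonal weights."""
    if net.n_genes < 2:
        raise ValueError("network must have at least 2 genes")
    if not 0.0 < z_percentile < 100.0:
        raise ValueError("z_percentile must lie strictly in (0, 100)")
    return float(np.percentile(net.off_diagonal_weights(), z_percentile))


def build_nn_network(
    net: InfluenceNetwork,
    variational: set,
    z_percentile: float = 99.95,
    tau: float | None = None,
) -> nx.DiGraph:
    """Grow the nearest-neighbor network around the variational genes.

    Ties on edge weight are broken by (source gene order, target gene
    order) in the network's gene order, so repeated calls are identical.
    An explicit `tau` bypasses the percentile computation.
    """
    variational = set(variational)
    if not variational:
        raise ValueError("variational set must be non-empty")
    unknown = variational - set(net.gene_ids)
    if unknown:
        raise KeyError(f"variational genes not in network: {sorted(unknown)}")

    if tau is None:
        tau = nn_edge_threshold(net, z_percentile)
    N = net.n_genes
    W = net.W
    # candidate edges at/above threshold, best-first with the documented
    # deterministic tie-break; a zero weight is "no edge" even if tau = 0
    src, tgt = np.nonzero((W >= tau) & (W > 0))
    keep = src != tgt
    src, tgt = src[keep], tgt[keep]
    order = np.lexsort((tgt, src, -W[src, tgt]))
    edges = list(zip(src[order].tolist(), tgt[order].tolist()))

    inside = {net.index_of(g) for g in variational}
    active = edges
    grown = True
    while grown:
        grown = False
        remaining = []
        for i, (u, v) in enumerate(active):
            uin, vin = u in inside, v in inside
            if uin and vin:
                continue  # intra-set; collected at the end
            if uin or vin:
                inside.add(v if uin else u)
                remaining.extend(active[i + 1 :])
                grown = True
                break
            remaining.append((u, v))
        active = remaining

    g = nx.DiGraph(tau=tau, source_condition=net.condition, z_percentile=z_percentile)
    idx_to_gene = net.gene_ids
    for gene in sorted(variational):
        g.add_node(gene, role="variational")
    for i in sorted(inside):
        gene = idx_to_gene[i]
        if gene not in g:
            g.add_node(gene, role="neighbor")
    for u, v in edges:
        if u in inside and v in inside:
            g.add_edge(idx_to_gene[u], idx_to_gene[v], weight=float(W[u, v]))
    return g
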