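"""Readers and writers for expression matrices, networks and results.

Expression matrices are delimited text (TSV/CSV sniffed by extension)
with one header row and one id column; both orientations are supported
behind an explicit flag — there is no auto-detection, since a silently
transposed matrix is a classic failure mode.  Networks round-trip
through edge-list TSV or GraphML.
"""

from __future__ import annotations


import networkx as nx
import numpy as np
import pandas as pd

from .inference import InfluenceNetwork
from .matrix import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "write_network",
    "read_network_graphml",
    "write_influence_matrix",
]

_ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(
    path,
    orientation: str = "samples_by_genes",
    condition: str = "control",
) -> ExpressionMatrix:
    """Read a delimited expression table.

    `orientation` states how the *file* is laid out; the returned matrix
    is always samples x genes.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    sep = _sep_for(path)
    # ExpressionMatrix validates uniqueness/finiteness/non-negativity,
    # but pandas mangles duplicate column headers on read — check the
    # raw gene ids first.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    first_col = pd.read_csv(path, sep=sep, usecols=[0], dtype=str).iloc[:, 0]
    gene_axis = (
        pd.Series(header) if orientation == "samples_by_genes" else first_col
    )
    dupes = sorted(gene_axis[gene_axis.duplicated()].unique())
    if dupes:
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    try:
        return ExpressionMatrix(df.astype(float), condition=condition)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_expression(x: ExpressionMatrix, path) -> None:
    x.data.to_csv(path, sep=_sep_for(path))


def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, InfluenceNetwork):
        g = nx.DiGraph()
        g.add_nodes_from(net.gene_ids)
        src, tgt = np.nonzero(net.W)
        for u, v in zip(src, tgt):
            g.add_edge(net.gene_ids[u], net.gene_ids[v], weight=float(net.W[u, v]))
        return g
    return net


def write_network(net, path, format: str = "edge_list_tsv") -> None:
    """Write an influence network or NN graph.

    edge_list_tsv: columns source, target, weight (weights to 8
    significant digits).  graphml: round-trips node roles and weights.
    """
    g = _as_digraph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    if format == "edge_list_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.8g}\n")
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)


def write_influence_matrix(net: InfluenceNetwork, path) -> None:
    """Dense N x N weight matrix as TSV (rows influence columns)."""
    pd.DataFrame(net.W, index=net.gene_ids, columns=net.gene_ids).to_csv(
        path, sep="\t"
    )
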