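"""Multi-run integration of nearest-neighbor networks.

Tree-ensemble inference is stochastic, so the variational genes and the
nearest-neighbor network differ slightly between runs.  The ensemble
stage runs the inference -> variational -> nearest-neighbor pass
`n_runs` times with distinct child seeds, then integrates: the union of
all per-run networks is trimmed of edges supported by fewer than rho
runs, isolated nodes are dropped, and modules and cores are extracted
from the integrated network.  Per-gene frequencies of variational and
core membership across runs are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .community import CoreResult, ModulePartition, detect_modules, extract_cores
from .config import PipelineConfig
from .inference import InfluenceNetwork, infer_network
from .matrix import ExpressionMatrix
from .neighbors import build_nn_network
from .variational import VariationalScores, select_variational, variationality_scores

__all__ = ["SingleRun", "integrate_runs", "run_single_pass", "run_ensemble"]


@dataclass
class SingleRun:
    seed: int
    control_net: InfluenceNetwork
    perturbed_net: InfluenceNetwork
    scores: VariationalScores
    nn_graph: nx.DiGraph
    partition: ModulePartition | None = None
    cores: list[CoreResult] | None = None

    @property
    def core_genes(self) -> frozenset:
        if not self.cores:
            return frozenset()
        return frozenset().union(*(c.core_genes for c in self.cores))


def integrate_runs(nn_graphs: list[nx.DiGraph], rho: int) -> nx.DiGraph:
    """Union the per-run networks, keep edges seen in >= rho runs.

    Edge weights are averaged over the runs supporting the edge; nodes
    left without any edge are dropped.  A node is variational in the
    integrated network if it was variational in at least one run.
    """
    if not nn_graphs:
        raise ValueError("need at least one run")
    n_runs = len(nn_graphs)
    if not 0 <= rho <= n_runs:
        raise ValueError(f"rho must lie in [0, {n_runs}], got {rho}")

    counts: dict = {}
    weights: dict = {}
    roles: dict = {}
    for g in nn_graphs:
        for n, d in g.nodes(data=True):
            if d.get("role") == "variational":
                roles[n] = "variational"
            else:
                roles.setdefault(n, "neighbor")
        for u, v, d in g.edges(data=True):
            counts[(u, v)] = counts.get((u, v), 0) + 1
            weights[(u, v)] = weights.get((u, v), 0.0) + d.get("weight", 1.0)

    out = nx.DiGraph(rho=rho, n_runs=n_runs)
    for (u, v), c in counts.items():
        if c >= rho:
            out.add_edge(u, v, weight=weights[(u, v)] / c, support=c)
    for n in list(out.nodes()):
        out.nodes[n]["role"] = roles[n]
    return out


def run_single_pass(
    control: ExpressionMatrix,
    perturbed: ExpressionMatrix,
    cfg: PipelineConfig,
    seed: int,
    detect: bool = True,
) -> SingleRun:
    """One inference -> variational -> nearest-neighbor pass.

    The control and perturbed inferences use distinct seeds derived from
    the run seed (2*seed and 2*seed + 1).
    """
    cnet = infer_network(
        control, cfg.n_trees, seed=2 * seed, method=cfg.tree_method,
        max_features=cfg.max_features,
    )
    pnet = infer_network(
        perturbed, cfg.n_trees, seed=2 * seed + 1, method=cfg.tree_method,
        max_features=cfg.max_features,
    )
    mse = variationality_scores(cnet, pnet)
    scores = select_variational(
        mse, cfg.variational_percentile, n_variational=cfg.n_variational
    )
    nn = build_nn_network(pnet, set(scores.selected), cfg.nn_edge_percentile)
    run = SingleRun(seed, cnet, pnet, scores, nn)
    if detect and nn.number_of_nodes():
        run.partition = detect_modules(nn)
        run.cores = extract_cores(nn, run.partition, mode=cfg.core_method)
    return run


def run_ensemble(
    control: ExpressionMatrix,
    perturbed: ExpressionMatrix,
    cfg: PipelineConfig,
    per_run_cores: bool = True,
):
    """Execute all runs and integrate.

    Returns (runs, integrated_graph, partition, cores, gene_table).
    Raises if the integrated consensus network is empty.
    """
    if control.gene_ids != perturbed.gene_ids:
        raise ValueError("matrices must share one (filtered) gene universe")
    runs = [
        run_single_pass(
            control, perturbed, cfg, seed=cfg.random_seed + i, detect=per_run_cores
        )
        for i in range(cfg.n_runs)
    ]
    rho = cfg.effective_rho
    integrated = integrate_runs([r.nn_graph for r in runs], rho)
    if integrated.number_of_nodes() == 0:
        raise RuntimeError(
            f"empty consensus: no edge appears in >= rho={rho} of {cfg.n_runs} runs"
        )
    partition = detect_modules(integrated)
    cores = extract_cores(integrated, partition, mode=cfg.core_method)

    genes = control.gene_ids
    var_freq = pd.Series(0, index=genes, dtype=int)
    core_freq = pd.Series(0, index=genes, dtype=int)
    mse_sum = pd.Series(0.0, index=genes)
    for r in runs:
        var_freq[list(r.scores.selected)] += 1
        if r.cores is not None:
            cg = [g for g in r.core_genes if g in core_freq.index]
            core_freq[cg] += 1
        mse_sum = mse_sum.add(r.scores.mse, fill_value=0.0)

    module_of = partition.module_of()
    final_core = frozenset().union(*(c.core_genes for c in cores)) if cores else frozenset()
    table = pd.DataFrame(
        {
            "mean_mse": mse_sum / len(runs),
            "variational_frequency": var_freq,
            "module_id": pd.Series(
                {g: module_of.get(g) for g in genes}, dtype="Int64"
            ),
            "is_core": pd.Series({g: g in final_core for g in genes}),
            "core_frequency": core_freq,
        },
        index=pd.Index(genes, name="gene"),
    )
    return runs, integrated, partition, cores, table
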