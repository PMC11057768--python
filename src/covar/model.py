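"""Model/Results interface to the full differential-network pipeline.

`CoVar` is constructed from a control and a perturbed expression matrix
(optionally pre-filtering genes by mean expression and M-value); its
`fit()` runs the stochastic inference ensemble and returns a
`CoVarResults` holding the integrated nearest-neighbor network, its
module partition and per-module cores, per-run diagnostics, and a
per-gene table of variationality and membership frequencies.

    >>> model = CoVar(control, perturbed)           # doctest: +SKIP
    >>> res = model.fit(n_runs=5, n_trees=100, seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .community import CoreResult, ModulePartition
from .config import PipelineConfig
from .ensemble import SingleRun, run_ensemble
from .matrix import ExpressionMatrix
from .preprocess import filter_genes, gene_stats_frame

__all__ = ["CoVar", "CoVarResults"]


class CoVar:
    """Differential network model for a control/perturbed expression pair.

    Parameters
    ----------
    control, perturbed : ExpressionMatrix or pandas.DataFrame
        Samples x genes tables of non-negative normalized expression,
        sharing one gene list.
    config : PipelineConfig, optional
        Defaults follow the published evaluation settings (Table-style
        defaults: M-value 0.32, mean expression 60, 10000 trees, 97.5 /
        99.95 percentiles, 25 runs, greedy neighbors, undirected cores).
    filter : bool
        Apply the mean-expression / M-value gene filter on construction.
    keep_list : list of str, optional
        Restrict the gene universe (e.g. protein-coding genes) before
        filtering.
    """

    def __init__(
        self,
        control,
        perturbed,
        config: PipelineConfig | None = None,
        *,
        filter: bool = False,
        keep_list: list[str] | None = None,
        **overrides,
    ) -> None:
        if isinstance(control, pd.DataFrame):
            control = ExpressionMatrix(control, condition="control")
        if isinstance(perturbed, pd.DataFrame):
            perturbed = ExpressionMatrix(perturbed, condition="perturbed")
        if control.gene_ids != perturbed.gene_ids:
            raise ValueError("control and perturbed matrices must share one gene list")
        self.config = (config or PipelineConfig()).replace(**overrides)
        self.gene_stats = gene_stats_frame(control, perturbed, self.config.pseudocount)
        if filter:
            control, perturbed, retained = filter_genes(
                control, perturbed, self.config, keep_list=keep_list
            )
            self.retained_genes = retained
        else:
            self.retained_genes = control.gene_ids
        self.control = control
        self.perturbed = perturbed

    @classmethod
    def from_files(
        cls,
        control_path,
        perturbed_path,
        orientation: str = "samples_by_genes",
        **kwargs,
    ) -> "CoVar":
        from .io import read_expression

        c = read_expression(control_path, orientation, condition="control")
        p = read_expression(perturbed_path, orientation, condition="perturbed")
        return cls(c, p, **kwargs)

    def fit(
        self,
        n_runs: int | None = None,
        n_trees: int | None = None,
        seed: int | None = None,
        rho: int | None = None,
        per_run_cores: bool = True,
    ) -> "CoVarResults":
        """Run the ensemble pipeline and return the fitted results."""
        cfg = self.config
        updates = {}
        if n_runs is not None:
            updates["n_runs"] = n_runs
        if n_trees is not None:
            updates["n_trees"] = n_trees
        if seed is not None:
            updates["random_seed"] = seed
        if rho is not None:
            updates["rho"] = rho
        if updates:
            cfg = cfg.replace(**updates)
        runs, net, partition, cores, table = run_ensemble(
            self.control, self.perturbed, cfg, per_run_cores=per_run_cores
        )
        return CoVarResults(self, cfg, runs, net, partition, cores, table)


@dataclass
class CoVarResults:
    """Fitted pipeline results.

    Attributes
    ----------
    network : networkx.DiGraph
        Integrated nearest-neighbor network (node attribute ``role``,
        edge attributes ``weight`` and ``support``).
    partition : ModulePartition
    cores : list of CoreResult
    gene_table : pandas.DataFrame
        Per input gene: mean_mse, variational_frequency, module_id,
        is_core, core_frequency.
    runs : list of SingleRun
        Per-run networks, scores and (optionally) modules/cores.
    """

    model: CoVar
    config: PipelineConfig
    runs: list
    network: nx.DiGraph
    partition: ModulePartition
    cores: list
    gene_table: pd.DataFrame

    # -- derived quantities ---------------------------------------------
    @property
    def variational_genes(self) -> pd.Index:
        t = self.gene_table
        return t.index[t["variational_frequency"] > 0]

    @property
    def core_genes(self) -> frozenset:
        if not self.cores:
            return frozenset()
        return frozenset().union(*(c.core_genes for c in self.cores))

    def run_summaries(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            rows.append(
                {
                    "seed": r.seed,
                    "n_variational": len(r.scores.selected),
                    "nn_nodes": r.nn_graph.number_of_nodes(),
                    "nn_edges": r.nn_graph.number_of_edges(),
                    "n_modules": r.partition.n_modules if r.partition else np.nan,
                    "n_core": len(r.core_genes) if r.cores is not None else np.nan,
                    "mean_mse_variational": float(
                        r.scores.mse[list(r.scores.selected)].mean()
                    )
                    if r.scores.selected
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_summary_dict(self) -> dict:
        per_run = self.run_summaries()
        return {
            "config": self.config.to_dict(),
            "runs": per_run.to_dict(orient="records"),
            "integrated": {
                "n_nodes": self.network.number_of_nodes(),
                "n_edges": self.network.number_of_edges(),
                "n_modules": self.partition.n_modules,
                "module_sizes": [len(m) for m in self.partition.modules],
                "n_core_genes": len(self.core_genes),
                "cores": [
                    {
                        "module_id": c.module_id,
                        "size": len(c.core_genes),
                        "k": c.k,
                        "density": c.density,
                        "reachability": c.reachability,
                    }
                    for c in self.cores
                ],
                "mean_mse_all_genes": float(self.gene_table["mean_mse"].mean()),
            },
        }

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_summary_dict(), fh, indent=2)

    def save_gene_table(self, path) -> None:
        self.gene_table.to_csv(path, sep="\t")

    def summary(self) -> str:
        d = self.to_summary_dict()["integrated"]
        cfg = self.config
        lines = [
            "Differential network analysis (CoVar pipeline)",
            "=" * 58,
            f"genes analysed:          {self.model.control.n_genes}",
            f"samples (ctrl/pert):     {self.model.control.n_samples}/"
            f"{self.model.perturbed.n_samples}",
            f"runs x trees:            {cfg.n_runs} x {cfg.n_trees}"
            f"  (seed {cfg.random_seed}, rho {cfg.effective_rho})",
            f"variational percentile:  {cfg.variational_percentile}",
            f"NN edge percentile (Z):  {cfg.nn_edge_percentile}",
            "-" * 58,
            f"integrated network:      {d['n_nodes']} nodes, {d['n_edges']} edges",
            f"modules:                 {d['n_modules']}  sizes {d['module_sizes']}",
            f"core genes:              {d['n_core_genes']}",
        ]
        for c in d["cores"]:
            lines.append(
                f"  module {c['module_id']}: |core|={c['size']}  k={c['k']}  "
                f"density={c['density']:.3f}  reachability={c['reachability']:.3f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)
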