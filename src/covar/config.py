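"""Pipeline configuration.

Defaults reproduce the published evaluation settings: an M-value cutoff
of 0.32 and mean-expression cutoff of 60 for gene filtering, 10000 trees
per tree-ensemble fit, the 97.5th percentile for variational-gene
selection, the 99.95th percentile (Z) for nearest-neighbor edges, 25
ensemble runs with the greedy nearest-neighbor construction and the
undirected core.  Desk-scale analyses typically pass a smaller
``n_trees``/``n_runs`` explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    mean_expression_cutoff: float = 60.0
    m_value_cutoff: float = 0.32
    n_samples_control: int = 3
    n_samples_perturbed: int = 3
    n_trees: int = 10000
    variational_percentile: float = 97.5
    nn_edge_percentile: float = 99.95
    n_runs: int = 25
    rho: Optional[int] = None  # None -> majority rule ceil(n_runs / 2)
    nn_method: str = "greedy"
    core_method: str = "undirected"
    random_seed: int = 0
    pseudocount: float = 1.0
    # tree-ensemble knobs (GENIE3 conventions)
    tree_method: str = "random_forest"
    max_features: str = "sqrt"
    # optional override for the number of variational genes (rank cut
    # instead of percentile cut)
    n_variational: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("variational_percentile", "nn_edge_percentile"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must lie strictly in (0, 100), got {v}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.nn_method not in ("greedy",):
            raise ValueError(f"unknown nn_method {self.nn_method!r}")
        if self.core_method not in ("undirected", "directed"):
            raise ValueError(f"unknown core_method {self.core_method!r}")
        if self.tree_method not in ("random_forest", "extra_trees"):
            raise ValueError(f"unknown tree_method {self.tree_method!r}")
        if self.rho is not None and not 0 <= self.rho <= self.n_runs:
            raise ValueError("rho must satisfy 0 <= rho <= n_runs")

    @property
    def effective_rho(self) -> int:
        """Integration threshold; majority of runs unless set explicitly."""
        return self.rho if self.rho is not None else math.ceil(self.n_runs / 2)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        d = self.to_dict()
        d.update(kwargs)
        return PipelineConfig.from_dict(d)
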