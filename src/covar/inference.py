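"""Directed influence-network inference from one expression matrix.

Follows the GENIE3 recipe: each gene v in turn is treated as the target
of a regression problem; an ensemble of randomized regression trees
predicts v's (unit-variance standardized) expression from the expression
of all other genes, and the impurity-based importance of predictor u —
its total variance reduction across the ensemble, normalized to sum to 1
over predictors — becomes the edge weight W[u, v], the strength of the
influence of u on v.  Column normalization is what bounds the weights in
[0, 1].

Determinism: genes are canonicalised to sorted id order before fitting
and the weight matrix re-indexed to the caller's order afterwards, with
per-target seeds spawned from the master seed by sorted position.  The
result is therefore bit-identical across calls and exactly equivariant
under permutations of the input gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor

from .matrix import ExpressionMatrix

__all__ = ["InfluenceNetwork", "infer_network"]


@dataclass
class InfluenceNetwork:
    """N x N directed weight matrix; W[u, v] = influence of gene u on v."""

    gene_ids: list[str]
    W: np.ndarray
    condition: str = "control"
    n_trees: int = 0
    seed: int = 0
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        N = len(self.gene_ids)
        if self.W.shape != (N, N):
            raise ValueError(f"W must be {N}x{N}, got {self.W.shape}")
        if not np.isfinite(self.W).all():
            raise ValueError("W contains non-finite entries")
        if (np.diag(self.W) != 0).any():
            raise ValueError("W diagonal must be identically 0")
        if (self.W < 0).any() or (self.W > 1).any():
            raise ValueError("W entries must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def off_diagonal_weights(self) -> np.ndarray:
        """The N(N-1) off-diagonal entries as a flat array."""
        N = self.n_genes
        mask = ~np.eye(N, dtype=bool)
        return self.W[mask]

    def reindex(self, gene_ids: list[str]) -> "InfluenceNetwork":
        idx = [self.index_of(g) for g in gene_ids]
        return InfluenceNetwork(
            list(gene_ids),
            self.W[np.ix_(idx, idx)],
            condition=self.condition,
            n_trees=self.n_trees,
            seed=self.seed,
        )


_ESTIMATORS = {
    "random_forest": RandomForestRegressor,
    "extra_trees": ExtraTreesRegressor,
}


def infer_network(
    x: ExpressionMatrix,
    n_trees: int = 1000,
    seed: int = 0,
    method: str = "random_forest",
    max_features: str = "sqrt",
) -> InfluenceNetwork:
    """Infer the directed influence network for one condition.

    Parameters
    ----------
    x : ExpressionMatrix
        S x N expression matrix (S >= 2, N >= 2).
    n_trees : int
        Trees per target-gene ensemble.  The published evaluations use
        10000; 100-1000 is adequate at desk scale.
    seed : int
        Master seed; per-target child seeds are spawned from it.
    method : {"random_forest", "extra_trees"}
    max_features : {"sqrt", "all"}
        Candidate predictors per split; "sqrt" (K = sqrt(N-1)) is the
        GENIE3 default.

    Returns
    -------
    InfluenceNetwork
        Columns of W sum to 1 for every non-constant target; a target
        with zero expression variance yields an all-zero column.
    """
    if x.n_genes < 2:
        raise ValueError("at least 2 genes required")
    if x.n_samples < 2:
        raise ValueError("at least 2 samples required")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown method {method!r}")
    if max_features not in ("sqrt", "all"):
        raise ValueError(f"unknown max_features {max_features!r}")

    order = np.argsort(np.asarray(x.gene_ids, dtype=object))
    genes_sorted = [x.gene_ids[i] for i in order]
    V = x.values[:, order]
    N = len(genes_sorted)

    mf = "sqrt" if max_features == "sqrt" else 1.0
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(N)  # one uint32 per sorted target

    W_sorted = np.zeros((N, N))
    est_cls = _ESTIMATORS[method]
    predictors_mask = np.ones(N, dtype=bool)
    for j in range(N):
        y = V[:, j]
        sd = y.std()
        if sd == 0.0:
            continue  # constant target: all-zero column by convention
        predictors_mask[j] = False
        Xp = V[:, predictors_mask]
        est = est_cls(
            n_estimators=n_trees,
            max_features=mf,
            random_state=int(child_seeds[j]),
            n_jobs=1,
        )
        est.fit(Xp, y / sd)
        imp = est.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        W_sorted[predictors_mask, j] = imp
        predictors_mask[j] = True

    net_sorted = InfluenceNetwork(
        genes_sorted,
        np.clip(W_sorted, 0.0, 1.0),
        condition=x.condition,
        n_trees=n_trees,
        seed=seed,
    )
    return net_sorted.reindex(x.gene_ids)
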