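"""Variationality scoring: which genes' network neighborhoods change most.

A gene's neighborhood in an influence network is summarised by its
concatenated weight profile: the out-weights w(u, .) followed by the
in-weights w(., u), both in a fixed gene order (length 2N, with the two
self positions structurally zero).  Variationality is the mean squared
error between a gene's control and perturbed profiles; genes above a
percentile cutoff of the MSE distribution are "variational".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import InfluenceNetwork

__all__ = [
    "WeightProfile",
    "VariationalScores",
    "concat_weight_profile",
    "variationality_mse",
    "variationality_scores",
    "select_variational",
]


@dataclass(frozen=True)
class WeightProfile:
    gene_id: str
    vector: np.ndarray  # length 2N: [row u of W] ++ [column u of W]


@dataclass(frozen=True)
class VariationalScores:
    mse: pd.Series  # per gene
    threshold: float
    selected: frozenset


def concat_weight_profile(net: InfluenceNetwork, gene: str) -> WeightProfile:
    """Out-weights then in-weights of `gene`, in network gene order."""
    u = net.index_of(gene)
    vec = np.concatenate([net.W[u, :], net.W[:, u]])
    return WeightProfile(gene, vec)


def variationality_mse(v_control: WeightProfile, v_perturb: WeightProfile) -> float:
    """Mean squared difference of two concatenated weight profiles."""
    a, b = np.asarray(v_control.vector), np.asarray(v_perturb.vector)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def variationality_scores(
    control_net: InfluenceNetwork, perturbed_net: InfluenceNetwork
) -> pd.Series:
    """Per-gene MSE between control and perturbed weight profiles.

    The two networks must cover the same genes; the perturbed network is
    re-indexed to the control gene order so that profiles align.
    """
    if set(control_net.gene_ids) != set(perturbed_net.gene_ids):
        raise ValueError("networks must share one gene set")
    pert = (
        perturbed_net
        if perturbed_net.gene_ids == control_net.gene_ids
        else perturbed_net.reindex(control_net.gene_ids)
    )
    D = control_net.W - pert.W
    # profile MSE = mean over the 2N concatenated positions
    mse = (np.sum(D**2, axis=1) + np.sum(D**2, axis=0)) / (2 * control_net.n_genes)
    return pd.Series(mse, index=control_net.gene_ids, name="mse")


def select_variational(
    scores, percentile: float = 97.5, n_variational: int | None = None
) -> VariationalScores:
    """Select genes whose MSE strictly exceeds the percentile threshold.

    The threshold is the linear-interpolation empirical percentile of
    the scores.  With `n_variational` given, the top-n genes by MSE are
    selected instead (ties at the boundary resolved by gene id) and the
    threshold reported is the largest unselected score.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("empty score map")
    if n_variational is not None:
        if not 0 < n_variational <= len(s):
            raise ValueError("n_variational out of range")
        ranked = s.sort_values(ascending=False, kind="mergesort")
        order = np.lexsort((ranked.index.astype(str), -ranked.to_numpy()))
        chosen = [ranked.index[i] for i in order[:n_variational]]
        rest = ranked.drop(chosen)
        thr = float(rest.max()) if len(rest) else float("-inf")
        return VariationalScores(s, thr, frozenset(chosen))
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly in (0, 100)")
    thr = float(np.percentile(s.to_numpy(), percentile))
    selected = frozenset(s.index[s > thr])
    return VariationalScores(s, thr, selected)
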