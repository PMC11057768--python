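"""Gene filtering by mean expression and expression-stability M-value.

The M-value of a gene is the geNorm stability statistic: the mean, over
all partner genes, of the standard deviation of the per-sample log2
expression ratios.  Proportional genes have ratio variation 0; genes
whose expression moves independently of the rest have high M.  Filtering
keeps genes with M-value *at or above* the cutoff — the variable genes,
i.e. those affected by the perturbation — which is the opposite of the
usual geNorm use of selecting stable reference genes.

Statistics are computed on the row-concatenation of the control and
perturbed samples so that both conditions share one gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .matrix import ExpressionMatrix

__all__ = ["GeneStats", "compute_m_values", "gene_stats_frame", "filter_genes"]


@dataclass(frozen=True)
class GeneStats:
    gene_id: str
    mean_expression: float
    m_value: float


def _m_values_array(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """M-value per gene from an S x N value array.

    Uses the identity sd(log x_u - log x_v)^2 = var_u + var_v - 2 cov_uv
    (sample covariances, denominator S-1) to avoid the O(N^2 S) pair loop.
    """
    S, N = values.shape
    if S < 2:
        raise ValueError("at least 2 samples required (standard deviation undefined)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    L = np.log2(values + pseudocount)
    C = np.cov(L, rowvar=False, ddof=1)  # N x N
    C = np.atleast_2d(C)
    d = np.diag(C)
    delta_sq = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(delta_sq, 0.0)
    delta = np.sqrt(np.clip(delta_sq, 0.0, None))
    return delta.sum(axis=1) / (N - 1)


def compute_m_values(x: ExpressionMatrix, pseudocount: float = 1.0) -> list[GeneStats]:
    """Per-gene mean expression and M-value.

    The pairwise variation between genes u and v is the sample standard
    deviation (denominator S-1) over samples j of
    ``log2((X[j,u]+pseudocount) / (X[j,v]+pseudocount))``; the M-value of
    u is the mean of these over all v != u.
    """
    m = _m_values_array(x.values, pseudocount)
    means = x.values.mean(axis=0)
    return [
        GeneStats(g, float(mu), float(mv))
        for g, mu, mv in zip(x.gene_ids, means, m)
    ]


def gene_stats_frame(
    control: ExpressionMatrix,
    perturbed: ExpressionMatrix,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pooled-sample gene statistics table (gene, mean_expression, m_value)."""
    if control.gene_ids != perturbed.gene_ids:
        raise ValueError("control and perturbed matrices must share one gene list")
    pooled = np.vstack([control.values, perturbed.values])
    m = _m_values_array(pooled, pseudocount)
    return pd.DataFrame(
        {
            "gene": control.gene_ids,
            "mean_expression": pooled.mean(axis=0),
            "m_value": m,
        }
    ).set_index("gene")


def filter_genes(
    control: ExpressionMatrix,
    perturbed: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    *,
    keep_list: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Drop genes below the mean-expression or M-value cutoffs.

    Both statistics are computed on pooled control+perturbed samples; a
    gene is retained iff mean_expression >= cutoff AND m_value >= cutoff.
    `keep_list`, when given, additionally restricts the universe (e.g. to
    protein-coding genes) before the statistical filter.

    Returns the two restricted matrices (sample order unchanged) and the
    retained gene list.
    """
    cfg = cfg or PipelineConfig()
    stats = gene_stats_frame(control, perturbed, cfg.pseudocount)
    if keep_list is not None:
        keep = set(keep_list)
        stats = stats.loc[[g for g in stats.index if g in keep]]
    ok = (stats["mean_expression"] >= cfg.mean_expression_cutoff) & (
        stats["m_value"] >= cfg.m_value_cutoff
    )
    retained = list(stats.index[ok])
    if not retained:
        raise ValueError(
            "no genes pass the filters; relax mean_expression_cutoff "
            f"({cfg.mean_expression_cutoff}) or m_value_cutoff ({cfg.m_value_cutoff})"
        )
    return control.subset_genes(retained), perturbed.subset_genes(retained), retained
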