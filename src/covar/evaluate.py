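"""Validation statistics for variational genes and baselines.

Contains the correlation-change statistic S (mean absolute change of a
gene's pairwise Pearson correlations between conditions, range [0, 2]),
a pooled-gene-vector PCA condition distance, a Fisher-z differential
coexpression baseline with Benjamini-Hochberg correction, PageRank
centrality, and a helper correlating any two per-gene score mappings.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "correlation_change_S",
    "correlation_change_all",
    "pca_condition_distance",
    "fisher_z_diff_pairs",
    "diff_coexpression_network",
    "pagerank_centrality",
    "variability_degree_correlation",
    "read_deg_table",
]

_CLIP = 1.0 - 1e-7


def _corr_columns(values: np.ndarray) -> np.ndarray:
    """Gene x gene Pearson correlation; zero-variance genes give NaN rows."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(values, rowvar=False)
    return np.atleast_2d(c)


def correlation_change_S(
    control: ExpressionMatrix,
    perturbed: ExpressionMatrix,
    gene: str,
    neighbors,
) -> float:
    """Mean absolute change in Pearson correlation with `neighbors`.

    S = mean over neighbors v of |PCC_control(gene, v) - PCC_perturbed(gene, v)|,
    in [0, 2].  Pairs where either correlation is undefined (zero
    variance) are skipped; if every pair is undefined an error is raised.
    """
    neighbors = [v for v in neighbors if v != gene]
    if not neighbors:
        raise ValueError("neighbor set must be non-empty (excluding the gene itself)")
    if control.n_samples < 3 or perturbed.n_samples < 3:
        raise ValueError("each condition needs >= 3 samples")
    diffs = []
    xc = control.data[gene].to_numpy()
    xp = perturbed.data[gene].to_numpy()
    for v in neighbors:
        with np.errstate(divide="ignore", invalid="ignore"):
            rc = np.corrcoef(xc, control.data[v].to_numpy())[0, 1]
            rp = np.corrcoef(xp, perturbed.data[v].to_numpy())[0, 1]
        if np.isnan(rc) or np.isnan(rp):
            continue
        diffs.append(abs(rc - rp))
    if not diffs:
        raise ValueError(f"all correlation pairs undefined for gene {gene!r}")
    return float(np.mean(diffs))


def correlation_change_all(
    control: ExpressionMatrix, perturbed: ExpressionMatrix
) -> pd.Series:
    """S against all other genes, for every gene at once (vectorized)."""
    if control.gene_ids != perturbed.gene_ids:
        raise ValueError("matrices must share one gene list")
    rc = _corr_columns(control.values)
    rp = _corr_columns(perturbed.values)
    d = np.abs(rc - rp)
    np.fill_diagonal(d, np.nan)
    with np.errstate(invalid="ignore"):
        s = np.nanmean(d, axis=1)
    return pd.Series(s, index=control.gene_ids, name="S")


def pca_condition_distance(
    control: ExpressionMatrix, perturbed: ExpressionMatrix, genes=None
) -> pd.Series:
    """Distance each gene moves between conditions in a shared 2D PCA.

    Every gene contributes two observations of length S — its control
    and its perturbed expression vector — to one pooled 2-component PCA;
    the reported value is the Euclidean distance between a gene's two
    projected points.  Requires equal sample counts per condition.
    """
    if control.n_samples != perturbed.n_samples:
        raise ValueError("conditions must have equal sample counts")
    genes = list(genes) if genes is not None else control.gene_ids
    Xc = control.data[genes].to_numpy().T  # genes x S
    Xp = perturbed.data[genes].to_numpy().T
    pooled = np.vstack([Xc, Xp])
    proj = PCA(n_components=2, random_state=0).fit_transform(pooled)
    nc = len(genes)
    dist = np.linalg.norm(proj[:nc] - proj[nc:], axis=1)
    return pd.Series(dist, index=genes, name="pca_distance")


def fisher_z_diff_pairs(
    control: ExpressionMatrix, perturbed: ExpressionMatrix, top_n: int | None = None
) -> pd.DataFrame:
    """Differentially coexpressed gene pairs via the Fisher z-test.

    For every gene pair, z = (atanh r_control - atanh r_perturbed) /
    sqrt(1/(S_c - 3) + 1/(S_p - 3)) with correlations clipped to
    +/-(1 - 1e-7); two-sided normal p-values are Benjamini-Hochberg
    adjusted.  Returns the top_n pairs by ascending adjusted p (ties by
    |z| descending, then lexicographic pair), or all pairs if top_n is
    None.
    """
    sc, sp = control.n_samples, perturbed.n_samples
    if sc <= 3 or sp <= 3:
        raise ValueError("each condition needs more than 3 samples")
    if control.gene_ids != perturbed.gene_ids:
        raise ValueError("matrices must share one gene list")
    genes = np.asarray(control.gene_ids, dtype=object)
    rc = np.clip(_corr_columns(control.values), -_CLIP, _CLIP)
    rp = np.clip(_corr_columns(perturbed.values), -_CLIP, _CLIP)
    iu, ju = np.triu_indices(len(genes), k=1)
    zc, zp = np.arctanh(rc[iu, ju]), np.arctanh(rp[iu, ju])
    se = np.sqrt(1.0 / (sc - 3) + 1.0 / (sp - 3))
    z = (zc - zp) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    df = pd.DataFrame(
        {
            "gene_a": genes[iu],
            "gene_b": genes[ju],
            "r_control": rc[iu, ju],
            "r_perturbed": rp[iu, ju],
            "z_stat": z,
            "p_value": p,
            "adj_p": adj,
        }
    )
    df = df.sort_values(
        by=["adj_p", "z_stat", "gene_a", "gene_b"],
        key=lambda col: -col.abs() if col.name == "z_stat" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return df if top_n is None else df.head(top_n).copy()


def diff_coexpression_network(pairs: pd.DataFrame) -> nx.Graph:
    """Undirected network over differentially coexpressed pairs."""
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, z_stat=float(row.z_stat))
    return g


def pagerank_centrality(g, damping: float = 0.85) -> pd.Series:
    """Standard PageRank; scores sum to 1."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    pr = nx.pagerank(g, alpha=damping)
    return pd.Series(pr, name="pagerank")


def read_deg_table(path, alpha: float = 0.05) -> pd.DataFrame:
    """Read an externally produced differential-expression result table.

    Expects a DESeq2-style delimited file with columns ``gene`` (or the
    first column as index), ``log2FoldChange`` and ``padj``.  Returns a
    frame indexed by gene with columns log2fc, adj_p and is_deg
    (adj_p < alpha); rows with missing adjusted p are kept with
    is_deg = False.  Differential testing itself is out of scope — the
    table is consumed, never produced.
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    lfc_col = cols.get("log2foldchange") or cols.get("log2fc")
    p_col = cols.get("padj") or cols.get("adj_p")
    if lfc_col is None or p_col is None:
        raise ValueError(
            "expected columns log2FoldChange (or log2fc) and padj (or adj_p); "
            f"found {list(df.columns)}"
        )
    out = pd.DataFrame(
        {
            "log2fc": pd.to_numeric(df[lfc_col], errors="coerce").to_numpy(),
            "adj_p": pd.to_numeric(df[p_col], errors="coerce").to_numpy(),
        },
        index=pd.Index(df[gene_col].astype(str)),
    )
    out.index.name = "gene"
    out["is_deg"] = out["adj_p"] < alpha
    return out


def variability_degree_correlation(scores, network_ranks) -> float:
    """Pearson correlation of two per-gene mappings over their shared genes."""
    s1, s2 = pd.Series(scores, dtype=float), pd.Series(network_ranks, dtype=float)
    common = s1.index.intersection(s2.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared genes")
    a, b = s1[common].to_numpy(), s2[common].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: a mapping is constant")
    return float(stats.pearsonr(a, b).statistic)
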