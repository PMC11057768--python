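"""Correlation-change S, PCA distance, Fisher-z pairs, PageRank."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covar import (
    ExpressionMatrix,
    correlation_change_S,
    correlation_change_all,
    diff_coexpression_network,
    fisher_z_diff_pairs,
    pagerank_centrality,
    pca_condition_distance,
    variability_degree_correlation,
)


def _em(values, genes=None, condition="control"):
    values = np.asarray(values, dtype=float)
    S, N = values.shape
    genes = genes or [f"g{i}" for i in range(N)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"s{i}" for i in range(S)], columns=genes),
        condition=condition,
    )


def _pair(seed=0, S=10, N=6):
    rng = np.random.default_rng(seed)
    return (
        _em(rng.gamma(2, 50, (S, N))),
        _em(rng.gamma(2, 50, (S, N)), condition="perturbed"),
    )


class TestCorrelationChange:
    def test_identical_conditions_give_zero(self):
        c, _ = _pair()
        p = ExpressionMatrix(c.data.copy(), condition="perturbed")
        assert correlation_change_S(c, p, "g0", {"g1", "g2"}) == pytest.approx(0.0)

    def test_sign_flip_gives_maximum_two(self):
        x = np.linspace(1, 10, 8)
        c = _em(np.column_stack([x, x + 0.0]), ["a", "b"])
        p = _em(np.column_stack([x, 20.0 - x]), ["a", "b"], condition="perturbed")
        assert correlation_change_S(c, p, "a", {"b"}) == pytest.approx(2.0, abs=1e-9)

    def test_matches_three_neighbor_formula(self):
        c, p = _pair(seed=3, S=5, N=5)
        neighbors = ["g1", "g2", "g3"]
        expected = (
            sum(
                abs(
                    stats.pearsonr(c.data["g0"], c.data[v]).statistic
                    - stats.pearsonr(p.data["g0"], p.data[v]).statistic
                )
                for v in neighbors
            )
            / 3.0
        )
        got = correlation_change_S(c, p, "g0", set(neighbors))
        assert got == pytest.approx(expected)

    def test_bounded_between_zero_and_two(self):
        for seed in range(5):
            c, p = _pair(seed=seed)
            s = correlation_change_all(c, p)
            assert ((s >= 0) & (s <= 2)).all()

    def test_all_undefined_pairs_error(self):
        c = _em(np.column_stack([np.arange(5.0), np.full(5, 3.0)]), ["a", "b"])
        p = ExpressionMatrix(c.data.copy(), condition="perturbed")
        with pytest.raises(ValueError, match="undefined"):
            correlation_change_S(c, p, "a", {"b"})


class TestPCADistance:
    def test_identical_matrices_zero_distance(self):
        c, _ = _pair(seed=1)
        p = ExpressionMatrix(c.data.copy(), condition="perturbed")
        d = pca_condition_distance(c, p)
        assert np.allclose(d.to_numpy(), 0.0, atol=1e-9)

    def test_shifted_gene_has_max_distance(self):
        c, p = _pair(seed=2, S=8, N=6)
        p.data["g3"] = p.data["g3"] + 5000.0
        p = ExpressionMatrix(p.data, condition="perturbed")
        d = pca_condition_distance(c, p)
        assert d.idxmax() == "g3"

    def test_unequal_sample_counts_error(self):
        c, _ = _pair(seed=3, S=8)
        _, p = _pair(seed=4, S=6)
        with pytest.raises(ValueError, match="equal sample"):
            pca_condition_distance(c, p)


class TestFisherZ:
    def test_equal_correlations_give_zero_stat(self):
        c, _ = _pair(seed=5)
        p = ExpressionMatrix(c.data.copy(), condition="perturbed")
        pairs = fisher_z_diff_pairs(c, p)
        assert np.allclose(pairs["z_stat"], 0.0)
        assert np.allclose(pairs["p_value"], 1.0)

    def test_known_z_value(self):
        # r_c = 0.9, r_p = 0.0 with 15 samples each:
        # z = atanh(0.9) / sqrt(2/12) ~ 3.606
        rc, rp, n = 0.9, 0.0, 15
        expected = np.arctanh(rc) / np.sqrt(2.0 / (n - 3))
        assert expected == pytest.approx(3.606, abs=5e-3)
        # verify the implementation reproduces the formula on real data
        c, p = _pair(seed=6, S=n, N=4)
        pairs = fisher_z_diff_pairs(c, p)
        row = pairs[(pairs.gene_a == "g0") & (pairs.gene_b == "g1")].iloc[0]
        manual = (np.arctanh(row.r_control) - np.arctanh(row.r_perturbed)) / np.sqrt(
            2.0 / (n - 3)
        )
        assert row.z_stat == pytest.approx(manual)

    def test_perfect_correlation_is_clipped_finite(self):
        x = np.linspace(1, 5, 8)
        c = _em(np.column_stack([x, 2 * x, x[::-1]]), ["a", "b", "c"])
        rng = np.random.default_rng(0)
        p = _em(rng.gamma(2, 10, (8, 3)), ["a", "b", "c"], condition="perturbed")
        pairs = fisher_z_diff_pairs(c, p)
        assert np.isfinite(pairs["z_stat"]).all()

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        S, N = 20, 200
        shared = rng.normal(100, 10, size=(2 * S, N))
        c = _em(np.abs(shared[:S]))
        p = _em(np.abs(shared[S:]), condition="perturbed")
        pairs = fisher_z_diff_pairs(c, p)
        ks = stats.kstest(pairs["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_samples_error(self):
        c, p = _pair(seed=7, S=3)
        with pytest.raises(ValueError, match="3 samples"):
            fisher_z_diff_pairs(c, p)


class TestPageRank:
    def test_reciprocal_pair_is_symmetric(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        pr = pagerank_centrality(g)
        assert pr["a"] == pytest.approx(0.5)
        assert pr["b"] == pytest.approx(0.5)

    def test_star_hub_dominates(self):
        g = nx.DiGraph([(f"leaf{i}", "hub") for i in range(5)])
        pr = pagerank_centrality(g)
        assert pr["hub"] > pr.drop("hub").max()

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(5, 0.5, seed=3, directed=True)
        damping = 0.85
        pr = pagerank_centrality(g, damping=damping)
        # naive power iteration with uniform teleport and dangling mass
        nodes = list(g.nodes())
        n = len(nodes)
        x = np.full(n, 1.0 / n)
        A = np.zeros((n, n))
        for u, v in g.edges():
            A[nodes.index(u), nodes.index(v)] = 1.0
        out = A.sum(axis=1)
        for _ in range(2000):
            spread = np.zeros(n)
            for i in range(n):
                if out[i] > 0:
                    spread += damping * x[i] * A[i] / out[i]
                else:
                    spread += damping * x[i] / n
            x = spread + (1 - damping) / n
        for i, node in enumerate(nodes):
            # networkx iterates to its own 1e-6 residual tolerance
            assert pr[node] == pytest.approx(x[i], abs=1e-5)


class TestDegTable:
    def test_deseq2_style_columns(self, tmp_path):
        from covar import read_deg_table

        path = tmp_path / "deg.tsv"
        path.write_text(
            "gene\tbaseMean\tlog2FoldChange\tpadj\n"
            "g1\t100\t2.5\t0.001\n"
            "g2\t50\t-0.3\t0.8\n"
            "g3\t10\t1.0\tNA\n"
        )
        t = read_deg_table(path)
        assert t.loc["g1", "is_deg"] and not t.loc["g2", "is_deg"]
        assert not t.loc["g3", "is_deg"]  # missing padj -> not significant
        assert t.loc["g2", "log2fc"] == pytest.approx(-0.3)

    def test_missing_columns_error(self, tmp_path):
        from covar import read_deg_table

        path = tmp_path / "bad.tsv"
        path.write_text("gene\tfoo\ng1\t1\n")
        with pytest.raises(ValueError, match="log2FoldChange"):
            read_deg_table(path)


class TestScoreCorrelation:
    def test_identical_mappings_give_one(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert variability_degree_correlation(s, s) == pytest.approx(1.0)

    def test_constant_mapping_errors(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        const = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            variability_degree_correlation(s, const)

    def test_matches_direct_pcc(self):
        a = pd.Series([1.0, 4.0, 2.0, 8.0, 5.0], index=list("abcde"))
        b = pd.Series([2.0, 3.0, 1.0, 9.0, 4.0], index=list("abcde"))
        assert variability_degree_correlation(a, b) == pytest.approx(
            stats.pearsonr(a, b).statistic
        )

    def test_too_few_shared_genes_error(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        b = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="3 shared"):
            variability_degree_correlation(a, b)

    def test_degree_mapping_from_network(self):
        pairs = pd.DataFrame(
            {"gene_a": ["a", "a", "b"], "gene_b": ["b", "c", "c"],
             "z_stat": [3.0, -2.0, 1.0]}
        )
        g = diff_coexpression_network(pairs)
        assert dict(g.degree()) == {"a": 2, "b": 2, "c": 2}
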