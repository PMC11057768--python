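"""Network and expression generators, and the core-vs-random benchmark."""

import numpy as np
import pytest
from scipy import stats

from covar import (
    SimSpec,
    SmallWorldSpec,
    generate_ba_network,
    random_core_benchmark,
    simulate_expression,
)


class TestBANetwork:
    def test_node_count_and_seed_clique(self):
        g = generate_ba_network(SmallWorldSpec(20, 3, 2, seed=0))
        assert g.number_of_nodes() == 20
        for u in range(3):
            for v in range(3):
                if u != v:
                    assert g.has_edge(u, v)

    def test_single_growth_step(self):
        m = 2
        g = generate_ba_network(SmallWorldSpec(m + 2, 1, m, seed=1))
        newcomer = m + 1
        preds = list(g.predecessors(newcomer))
        assert len(preds) == m
        assert set(preds) <= set(range(m + 1))
        assert g.out_degree(newcomer) == 0

    def test_every_newcomer_has_m_parents(self):
        m = 3
        g = generate_ba_network(SmallWorldSpec(40, 2, m, seed=2))
        for n in range(m + 2, 40):
            assert g.in_degree(n) == m

    def test_attachment_probability_matches_formula(self):
        # chi-square on repeated single draws from a fixed degree state:
        # the first pick must follow P(u) = (out_deg(u) + k) / sum
        from covar.simulate import draw_attachment_targets

        out_deg = np.array([6.0, 3.0, 1.0, 0.0, 0.0])
        k = 2
        weights = out_deg + k
        expected_p = weights / weights.sum()
        rng = np.random.default_rng(99)
        n_draws = 4000
        counts = np.zeros(5)
        for _ in range(n_draws):
            first = draw_attachment_targets(out_deg, k, m=1, rng=rng)[0]
            counts[first] += 1
        chi2 = (((counts - n_draws * expected_p) ** 2)
                / (n_draws * expected_p)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_large_k_approaches_uniform_attachment(self):
        # k >> degrees: newcomer targets nearly uniform over existing nodes
        m, k, N = 2, 10**6, 25
        counts = np.zeros(N - 1)
        n_draws = 2000
        for s in range(n_draws):
            g = generate_ba_network(SmallWorldSpec(N, k, m, seed=5_000_000 + s))
            for u in g.predecessors(N - 1):
                counts[u] += 1
        expected = np.full(N - 1, counts.sum() / (N - 1))
        chi2 = ((counts - expected) ** 2 / expected).sum()
        crit = stats.chi2.ppf(0.99, df=N - 2)
        assert chi2 < crit

    def test_low_k_yields_heavier_tail_than_uniform(self):
        # hub formation: max out-degree under k=0 beats the huge-k
        # (uniform) reference in nearly all paired runs
        wins = 0
        n_pairs = 60
        for s in range(n_pairs):
            hubby = generate_ba_network(SmallWorldSpec(150, 0, 2, seed=s))
            unif = generate_ba_network(SmallWorldSpec(150, 10**6, 2, seed=s))
            dmax_h = max(d for _, d in hubby.out_degree())
            dmax_u = max(d for _, d in unif.out_degree())
            wins += dmax_h > dmax_u
        assert wins >= int(0.95 * n_pairs)

    def test_invalid_sizes_error(self):
        with pytest.raises(ValueError):
            SmallWorldSpec(3, 1, 2)
        with pytest.raises(ValueError):
            SmallWorldSpec(10, -1, 2)


class TestSimulatedExpression:
    def test_label_bookkeeping(self):
        c, p, labels = simulate_expression(SimSpec(seed=0))
        assert len(labels) == 200
        null = [g for g, m in labels.items() if m is None]
        assert len(null) == 100
        for mod in range(1, 5):
            assert sum(1 for m in labels.values() if m == mod) == 25
        assert c.gene_ids == p.gene_ids
        assert c.n_samples == p.n_samples == 15

    def test_values_non_negative(self):
        c, p, _ = simulate_expression(SimSpec(seed=1))
        assert (c.values >= 0).all() and (p.values >= 0).all()

    def test_noise_free_equal_loading_pair_correlates_perfectly(self):
        # noise-free limit (measurement noise and global factor both off):
        # module genes with equal-magnitude loadings are copies of the
        # module factor up to sign
        spec = SimSpec(
            n_genes=10, n_modules=1, genes_per_module=5, n_null=5,
            n_samples=20, sigma_noise=1e-9, sigma_condition=1e-9,
            loading_range=(1.0, 1.0), seed=3,
        )
        c, _, labels = simulate_expression(spec)
        mod_genes = [g for g, m in labels.items() if m == 1]
        r = np.corrcoef(c.data[mod_genes].to_numpy(), rowvar=False)
        assert np.all(np.abs(r[0, 1:]) > 0.999)

    def test_module_pairs_correlate_above_cross_pairs(self):
        # the contrast that makes planted modules recoverable: pairs
        # inside one module co-vary (through the shared module factor)
        # far more than module-null cross pairs, which share only the
        # weak global condition factor.  Null-null pairs are coherent by
        # design (they form their own stable background module).
        for seed in range(5):
            c, p, labels = simulate_expression(SimSpec(seed=seed))
            lab = np.array(
                [0 if labels[g] is None else labels[g] for g in c.gene_ids]
            )
            same_mod = (lab[:, None] == lab[None, :]) & (lab[:, None] > 0)
            cross = (lab[:, None] > 0) != (lab[None, :] > 0)
            triu = np.triu(np.ones_like(same_mod, dtype=bool), k=1)
            for mat in (c, p):
                r = np.abs(np.corrcoef(mat.values, rowvar=False))
                margin = r[same_mod & triu].mean() - r[cross & triu].mean()
                assert margin >= 0.25

    def test_null_structure_identical_across_conditions(self):
        # null-gene pairwise correlations agree across conditions far
        # better than module-gene ones (which are re-randomized)
        c, p, labels = simulate_expression(SimSpec(seed=7))
        rc = np.corrcoef(c.values, rowvar=False)
        rp = np.corrcoef(p.values, rowvar=False)
        genes = c.gene_ids
        idx = {g: i for i, g in enumerate(genes)}
        null = [g for g, m in labels.items() if m is None]
        mod = [g for g, m in labels.items() if m == 1]
        d_null = np.mean(
            [abs(rc[idx[a], idx[b]] - rp[idx[a], idx[b]])
             for i, a in enumerate(null[:20]) for b in null[i + 1:20]]
        )
        d_mod = np.mean(
            [abs(rc[idx[a], idx[b]] - rp[idx[a], idx[b]])
             for i, a in enumerate(mod) for b in mod[i + 1:]]
        )
        assert d_mod > d_null + 0.3

    def test_invalid_spec_errors(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimSpec(n_genes=150)


class TestRandomCoreBenchmark:
    def test_counts_are_bounded_and_ordered(self):
        res = random_core_benchmark(30, SmallWorldSpec(40, 3, 2, 0), seed=1)
        for metric in ("coordination", "reachability"):
            gt, ge = res[f"{metric}_gt"], res[f"{metric}_ge"]
            assert 0 <= gt <= ge <= 30

    def test_random_never_strictly_beats_core_coordination(self):
        res = random_core_benchmark(60, SmallWorldSpec(60, 3, 2, 0), seed=2)
        assert res["coordination_gt"] == 0
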