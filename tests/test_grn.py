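import math
import warnings

import numpy as np
import pytest

from clumpnet import (CountMatrix, TFCatalog, ValidationError, adjust_by,
                      aracne_network, discretize_equal_width, mi_miller_madow,
                      poisson_tail_p, sample_cells, select_variable_genes_vst,
                      shuffle_gene_names)
from clumpnet.grn import (_loess, _pairwise_mi, _rng, build_support,
                          consensus_grn, run_grn_ensemble, run_null_ensemble,
                          significance_table, vst_scores)
from clumpnet.io import Graph, ResamplingConfig


def _cm(values, prefix="g"):
    values = np.asarray(values)
    return CountMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                       [f"{prefix}{j}" for j in range(values.shape[1])])


class TestSampling:
    def test_full_sample_is_permutation(self, tiny_counts):
        out = sample_cells(tiny_counts, 4, np.random.default_rng(0))
        assert sorted(out.cell_ids) == sorted(tiny_counts.cell_ids)

    def test_seed_reproducibility(self, tiny_counts):
        a = sample_cells(tiny_counts, 2, np.random.default_rng(5))
        b = sample_cells(tiny_counts, 2, np.random.default_rng(5))
        assert list(a.cell_ids) == list(b.cell_ids)

    def test_uniformity_monte_carlo(self, tiny_counts):
        rng = np.random.default_rng(11)
        freq = {c: 0 for c in tiny_counts.cell_ids}
        n_draws = 10_000
        for _ in range(n_draws):
            freq[sample_cells(tiny_counts, 1, rng).cell_ids[0]] += 1
        for c, f in freq.items():
            assert abs(f / n_draws - 0.25) < 0.02

    def test_oversampling_rejected(self, tiny_counts):
        with pytest.raises(ValidationError):
            sample_cells(tiny_counts, 5, np.random.default_rng(0))

    def test_with_replacement_allows_oversampling(self, tiny_counts):
        out = sample_cells(tiny_counts, 10, np.random.default_rng(0), replace=True)
        assert out.values.shape[0] == 10


class TestShuffle:
    def test_values_untouched_names_permuted(self, tiny_counts):
        out = shuffle_gene_names(tiny_counts, np.random.default_rng(3))
        assert np.array_equal(out.values, tiny_counts.values)
        assert sorted(out.gene_ids) == sorted(tiny_counts.gene_ids)

    def test_single_gene_unchanged(self):
        cm = _cm([[1], [2]])
        out = shuffle_gene_names(cm, np.random.default_rng(0))
        assert list(out.gene_ids) == list(cm.gene_ids)

    def test_seed_reproducibility(self, tiny_counts):
        a = shuffle_gene_names(tiny_counts, np.random.default_rng(9))
        b = shuffle_gene_names(tiny_counts, np.random.default_rng(9))
        assert list(a.gene_ids) == list(b.gene_ids)


class TestVst:
    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(5.0, size=(200, 6))
        values[:, 2] = 7  # constant
        ranked = select_variable_genes_vst(_cm(values), 6)
        assert ranked[-1] == "g2"

    def test_bimodal_outranks_poisson_at_same_mean(self):
        rng = np.random.default_rng(1)
        n = 500
        # same mean ~5: bimodal (0 or 10) vs Poisson(5); plus Poisson filler
        # genes spanning the mean axis so the trend is anchored
        bimodal = rng.choice([0, 10], size=n)
        pois = rng.poisson(5.0, size=n)
        filler = rng.poisson(rng.uniform(0.5, 20, size=18)[None, :].repeat(n, 0))
        values = np.column_stack([bimodal, pois, filler])
        ranked = select_variable_genes_vst(_cm(values), 2)
        assert ranked[0] == "g0"

    def test_three_gene_ranking_matches_straight_line_oracle(self):
        rng = np.random.default_rng(2)
        n = 300
        values = np.column_stack([
            rng.poisson(1.0, n),
            rng.choice([0, 8], n),          # clearly over-dispersed
            rng.poisson(9.0, n),
        ])
        mu = values.mean(0)
        var = values.var(0, ddof=1)
        # independent oracle: unweighted degree-1 fit of log10 var on log10 mean
        slope, intercept = np.polyfit(np.log10(mu), np.log10(var), 1)
        exp_sd = np.sqrt(10 ** (slope * np.log10(mu) + intercept))
        z = np.minimum((values - mu) / exp_sd, math.sqrt(n))
        oracle_rank = np.argsort(-(z ** 2).sum(0) / (n - 1), kind="stable")
        ranked = select_variable_genes_vst(_cm(values), 3)
        assert ranked == [f"g{i}" for i in oracle_rank]

    def test_fewer_expressed_than_requested_warns(self):
        values = np.column_stack([np.random.default_rng(0).poisson(2.0, 50),
                                  np.full(50, 3)])
        with pytest.warns(UserWarning, match="positive standardized variance"):
            ranked = select_variable_genes_vst(_cm(values), 2)
        assert len(ranked) == 2

    def test_loess_recovers_smooth_trend(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 4, 400))
        y = 0.5 * x ** 2 - x + rng.normal(0, 0.05, 400)
        fit = _loess(x, y, span=0.3, degree=2)
        inner = (x > 0.5) & (x < 3.5)
        assert np.max(np.abs(fit[inner] - (0.5 * x ** 2 - x)[inner])) < 0.1


class TestDiscretize:
    def test_ten_values_two_bins(self):
        bins = discretize_equal_width(np.arange(10)[:, None], 2)
        assert bins.ravel().tolist() == [0] * 5 + [1] * 5

    def test_constant_column_all_zero(self):
        bins = discretize_equal_width(np.full((5, 1), 3.0), 4)
        assert np.all(bins == 0)

    def test_extremes_land_in_terminal_bins(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 3))
        bins = discretize_equal_width(values, 7)
        assert np.all(bins[values.argmin(0), range(3)] == 0)
        assert np.all(bins[values.argmax(0), range(3)] == 6)

    def test_b_below_two_rejected(self):
        with pytest.raises(ValidationError):
            discretize_equal_width(np.zeros((3, 1)), 1)


class TestMillerMadowMI:
    def test_balanced_binary_closed_form(self):
        x = np.array([0, 1] * 5)
        # plugin MI = ln 2; corrections: +1/20 +1/20 -1/20
        assert mi_miller_madow(x, x) == pytest.approx(math.log(2) + 0.05, abs=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.zeros(10, dtype=int)
        y = np.array([0, 1] * 5)
        assert mi_miller_madow(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 4, 10_000)
        y = rng.integers(0, 4, 10_000)
        assert abs(mi_miller_madow(x, y)) < 3e-3

    def test_matrix_kernel_matches_single_pair(self):
        rng = np.random.default_rng(5)
        bins = rng.integers(0, 5, size=(200, 4))
        mat = _pairwise_mi(bins, 5)
        for i in range(4):
            for j in range(i + 1, 4):
                assert mat[i, j] == pytest.approx(
                    mi_miller_madow(bins[:, i], bins[:, j]), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mi_miller_madow(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


class TestAracne:
    def test_chain_indirect_edge_pruned(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.4, n)
        z = y + rng.normal(0, 0.4, n)
        values = np.floor(np.column_stack([x, y, z]) * 10 + 50).astype(int)
        g = aracne_network(_cm(values), B=10)
        assert g.has_edge("g0", "g1") and g.has_edge("g1", "g2")
        assert not g.has_edge("g0", "g2")

    def test_infinite_eps_disables_pruning(self):
        rng = np.random.default_rng(7)
        values = rng.integers(0, 20, size=(300, 4))
        pruned = aracne_network(_cm(values), B=5, dpi_eps=0.0)
        unpruned = aracne_network(_cm(values), B=5, dpi_eps=np.inf)
        assert set(pruned.edges) <= set(unpruned.edges)
        # unpruned graph = thresholded MI graph: every positive-MI pair present
        mat = _pairwise_mi(discretize_equal_width(values, 5), 5)
        pos_pairs = sum(mat[i, j] > 0 for i in range(4) for j in range(i + 1, 4))
        assert unpruned.n_edges == pos_pairs

    def test_correlated_pair_survives_noise_mostly_absent(self):
        hits = 0
        noise_edges = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            shared = rng.normal(size=n)
            values = np.floor(np.column_stack([
                rng.normal(size=n), rng.normal(size=n),
                shared + rng.normal(0, 0.3, n), shared + rng.normal(0, 0.3, n),
            ]) * 5 + 30).astype(int)
            g = aracne_network(_cm(values), B=10)
            hits += g.has_edge("g2", "g3")
            noise_edges += sum(1 for e in g.edges if e != ("g2", "g3"))
        assert hits == 20                      # planted pair always detected
        assert noise_edges <= 0.5 * 20 * 5     # noise edges mostly absent

    def test_two_genes_skips_dpi_with_warning(self):
        rng = np.random.default_rng(8)
        values = rng.integers(0, 10, size=(100, 2))
        with pytest.warns(UserWarning, match="fewer than 3"):
            g = aracne_network(_cm(values), B=4)
        assert g.n_vertices == 2


class TestPoissonTail:
    def test_zero_count_gives_one(self):
        assert poisson_tail_p(0, 5.0, 10) == 1.0

    def test_closed_form_small_rate(self):
        expected = 1 - math.exp(-0.1) * (1 + 0.1)
        assert poisson_tail_p(2, 0.1, 1) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("count,lam,M", [(3, 0.2, 5), (1, 1.0, 2), (7, 0.05, 100)])
    def test_matches_series_oracle(self, count, lam, M):
        mu = lam * M
        cdf = sum(math.exp(-mu) * mu ** i / math.factorial(i) for i in range(count))
        assert poisson_tail_p(count, lam, M) == pytest.approx(1 - cdf, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            poisson_tail_p(-1, 0.1, 1)
        with pytest.raises(ValidationError):
            poisson_tail_p(1, -0.1, 1)


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert adjust_by([0.04])[0] == pytest.approx(0.04, abs=1e-15)

    def test_hand_computed_step_up(self):
        # m=3, c(3)=11/6: raw = 11/6*3*(.01/1,.02/2,.03/3) = .055 each
        q = adjust_by([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.055, 0.055, 0.055], atol=1e-12)

    def test_permutation_invariance_and_q_ge_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(1e-6, 1.0, 50)
        q = adjust_by(p)
        perm = rng.permutation(50)
        assert np.allclose(adjust_by(p[perm]), q[perm], atol=1e-14)
        assert np.all(q >= p - 1e-15)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(1e-8, 1.0, 200)
        ours = adjust_by(p)
        ref = multipletests(p, method="fdr_by")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_implicit_family_members_raise_q(self):
        q_small = adjust_by([0.001], m_total=100)
        # equivalent to padding with p=1 entries
        padded = adjust_by(np.concatenate([[0.001], np.ones(99)]))
        assert q_small[0] == pytest.approx(padded[0], abs=1e-12)


@pytest.fixture(scope="module")
def small_world():
    """A small planted dataset where the ensemble machinery can run fast."""
    from clumpnet.simulate import SimulationParams, simulate_dataset

    params = SimulationParams(n_cells=300, n_genes=120, n_types=2,
                              n_regulators=2, targets_per_regulator=4, seed=7)
    counts, emb, tfs, truth = simulate_dataset(params)
    cfg = ResamplingConfig(k=5, N=120, M=5, M_hat=5, K=4, n_hvg=30, seed=7)
    return counts, tfs, truth, cfg


class TestEnsembles:
    def test_counts_bounded_by_m_and_recountable(self, small_world):
        counts, tfs, truth, cfg = small_world
        graphs, support = run_grn_ensemble(counts, tfs, cfg)
        assert len(graphs) <= cfg.M
        assert (support["count"] <= len(graphs)).all()
        assert (support["count"] >= 1).all()
        # recount independently
        recount = build_support(graphs)
        assert recount.equals(support)

    def test_single_specimen_counts_binary(self, small_world):
        counts, tfs, truth, cfg = small_world
        one = ResamplingConfig(**{**cfg.to_dict(), "M": 1})
        graphs, support = run_grn_ensemble(counts, tfs, one)
        assert set(support["count"]) <= {1}

    def test_node_rate_is_selection_fraction(self, small_world):
        counts, tfs, truth, cfg = small_world
        lam_node, lam_edge = run_null_ensemble(counts, tfs, cfg)
        assert lam_node == pytest.approx(cfg.n_hvg / counts.n_genes)
        assert lam_edge >= 0

    def test_per_pair_rates_sum_to_pooled(self, small_world):
        counts, tfs, truth, cfg = small_world
        lam_node, lam_edge, rates = run_null_ensemble(counts, tfs, cfg, pooled=False)
        n_candidates = math.comb(len(tfs.intersect(counts.gene_ids)), 2)
        assert sum(rates.values()) / n_candidates == pytest.approx(lam_edge, rel=1e-9)

    def test_ensemble_deterministic_under_seed(self, small_world):
        counts, tfs, truth, cfg = small_world
        g1, s1 = run_grn_ensemble(counts, tfs, cfg)
        g2, s2 = run_grn_ensemble(counts, tfs, cfg)
        assert s1.equals(s2)
        assert all(a == b for a, b in zip(g1, g2))


class TestConsensus:
    def _support(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["type", "id", "count", "weight_sum",
                                           "lam", "p", "q"])

    def test_all_above_threshold_gives_empty(self):
        sup = self._support([("node", "a", 5, np.nan, 0.1, 0.5, 0.9)])
        with pytest.warns(UserWarning, match="empty"):
            g = consensus_grn([], sup, 1e-5)
        assert g.n_vertices == 0

    def test_edge_without_significant_endpoint_dropped(self):
        sup = self._support([
            ("node", "a", 9, np.nan, 0.1, 1e-9, 1e-8),
            ("node", "b", 2, np.nan, 0.1, 0.5, 0.9),
            ("edge", "a|b", 9, 4.5, 0.01, 1e-9, 1e-8),
        ])
        g = consensus_grn([], sup, 1e-5)
        assert g.vertices == ("a",)
        assert g.n_edges == 0

    def test_edge_weight_is_mean_over_specimens(self):
        sup = self._support([
            ("node", "a", 9, np.nan, 0.1, 1e-9, 1e-8),
            ("node", "b", 9, np.nan, 0.1, 1e-9, 1e-8),
            ("edge", "a|b", 3, 4.5, 0.01, 1e-9, 1e-8),
        ])
        g = consensus_grn([], sup, 1e-5)
        assert g.weight("a", "b") == pytest.approx(1.5)

    def test_significance_table_families_are_separate(self):
        import pandas as pd

        sup = pd.DataFrame([("node", "a", 10, np.nan), ("edge", "a|b", 10, 5.0)],
                           columns=["type", "id", "count", "weight_sum"])
        out = significance_table(sup, lam_node=0.1, lam_edge=0.001, M=10,
                                 n_tf_universe=50)
        node_q = out.loc[out["type"] == "node", "q"].iloc[0]
        edge_q = out.loc[out["type"] == "edge", "q"].iloc[0]
        # same count, but different rates and family sizes
        assert node_q != edge_q
        assert (out["q"] >= out["p"] - 1e-15).all()


class TestNullCalibrationInvariant:
    def test_edge_pvalues_not_anticonservative_on_iid_data(self):
        """On independent genes, P(edge p < alpha) stays near or below alpha."""
        from clumpnet.simulate import iid_noise

        alpha = 0.05
        frac = []
        for seed in range(3):
            counts, emb, tfs, cfg = iid_noise(n_cells=300, n_genes=150, seed=seed)
            cfg = ResamplingConfig(**{**cfg.to_dict(), "N": 100, "M": 10,
                                      "M_hat": 30, "K": 5, "n_hvg": 30})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                graphs, support = run_grn_ensemble(counts, tfs, cfg)
                lam_node, lam_edge = run_null_ensemble(counts, tfs, cfg)
                support = significance_table(support, lam_node, lam_edge,
                                             len(graphs),
                                             len(tfs.intersect(counts.gene_ids)))
            n_candidates = math.comb(len(tfs.intersect(counts.gene_ids)), 2)
            edges = support[support["type"] == "edge"]
            frac.append((edges["p"] < alpha).sum() / n_candidates)
        assert np.mean(frac) <= 2 * alpha
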