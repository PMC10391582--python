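import numpy as np
import pytest
from scipy import stats

from engramsim.config import DegradationSpec, NetworkConfig
from engramsim.network_builder import (
    apply_degradation,
    build_network,
    set_ei_manipulation,
)


class TestBuildNetwork:
    def test_zero_probability_gives_empty_graph(self):
        cfg = NetworkConfig(nE=20, nI=4, C=0.0, n_engrams=1, engram_size=5)
        g = build_network(cfg)
        assert g.n_edges == 0

    def test_full_probability_gives_all_ordered_pairs(self):
        cfg = NetworkConfig(nE=4, nI=1, C=1.0, n_engrams=1, engram_size=2)
        g = build_network(cfg)
        assert g.n_edges == 5 * 4  # n(n-1) directed edges, no self-loops
        assert np.all(g.pre != g.post)
        # at most one edge per ordered pair
        pairs = set(zip(g.pre.tolist(), g.post.tolist()))
        assert len(pairs) == g.n_edges

    def test_inter_engram_fraction_default_layout(self, default_layout_config):
        """With 10 disjoint engrams of 200 in 2000 E neurons, the expected
        fraction of E->E edges carrying the baseline weight is
        1 - 10*200*199/(2000*1999) ~= 0.9004."""
        g = build_network(default_layout_config)
        ee = g.is_exc[g.pre] & g.is_exc[g.post]
        intra = ee & (g.weight == default_layout_config.g_M_EE)
        frac_inter = 1.0 - intra.sum() / ee.sum()
        expected = 1.0 - 10 * 200 * 199 / (2000 * 1999)
        assert frac_inter == pytest.approx(expected, abs=0.01)

    def test_edge_count_matches_binomial_expectation(self):
        """Mean edge count over seeds sits inside the CLT interval of
        Binomial(n(n-1), C)."""
        nE, nI, C, n_seeds = 90, 10, 0.3, 200
        n = nE + nI
        counts = []
        for seed in range(n_seeds):
            cfg = NetworkConfig(
                nE=nE, nI=nI, C=C, n_engrams=1, engram_size=10, seed=seed
            )
            counts.append(build_network(cfg).n_edges)
        m = n * (n - 1)
        expected = m * C
        se = np.sqrt(m * C * (1 - C) / n_seeds)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_edge_count_distribution_chi_square(self):
        """Edge counts over seeds are consistent with Binomial(n(n-1), C)."""
        nE, nI, C = 36, 4, 0.25
        n = nE + nI
        m = n * (n - 1)
        counts = np.array(
            [
                build_network(
                    NetworkConfig(
                        nE=nE, nI=nI, C=C, n_engrams=1, engram_size=6, seed=s
                    )
                ).n_edges
                for s in range(150)
            ]
        )
        # bin by quartiles of the binomial
        edges = stats.binom.ppf([0.25, 0.5, 0.75], m, C)
        obs = np.histogram(counts, bins=[-1, *edges, m + 1])[0]
        probs = np.diff([0.0, *stats.binom.cdf(edges, m, C), 1.0])
        _, p = stats.chisquare(obs, probs * counts.size)
        assert p > 0.001

    def test_weights_follow_type_rule(self, tiny_config):
        g = build_network(tiny_config)
        pe, po = g.is_exc[g.pre], g.is_exc[g.post]
        same = (
            pe & po
            & (g.engram_id[g.pre] >= 0)
            & (g.engram_id[g.pre] == g.engram_id[g.post])
        )
        c = tiny_config
        assert np.all(g.weight[same] == c.g_M_EE)
        assert np.all(g.weight[pe & po & ~same] == c.g_EE)
        assert np.all(g.weight[~pe & po] == c.g_IE)
        assert np.all(g.weight[pe & ~po] == c.g_EI)
        assert np.all(g.weight[~pe & ~po] == c.g_II)

    def test_engrams_partition_excitatory_neurons_only(self, tiny_config):
        g = build_network(tiny_config)
        assert np.all(g.engram_id[~g.is_exc] == -1)
        for k in range(tiny_config.n_engrams):
            members = g.engram_members(k)
            assert members.size == tiny_config.engram_size
            assert np.all(g.is_exc[members])
        # engrams are contiguous disjoint blocks
        assigned = g.engram_id[g.engram_id >= 0]
        assert assigned.size == tiny_config.n_engrams * tiny_config.engram_size

    def test_plastic_flag_exactly_ee(self, tiny_config):
        g = build_network(tiny_config)
        assert np.array_equal(g.plastic, g.is_exc[g.pre] & g.is_exc[g.post])

    def test_reproducible_given_seed(self, tiny_config):
        g1 = build_network(tiny_config)
        g2 = build_network(tiny_config)
        assert np.array_equal(g1.pre, g2.pre)
        assert np.array_equal(g1.post, g2.post)
        assert np.array_equal(g1.weight, g2.weight)

    def test_engram_overflow_rejected(self):
        cfg = NetworkConfig(nE=100, nI=20, C=0.1, n_engrams=3, engram_size=40)
        with pytest.raises(ValueError, match="overflow"):
            build_network(cfg)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            build_network(
                NetworkConfig(nE=10, nI=2, C=1.5, n_engrams=1, engram_size=2)
            )


class TestDegradation:
    def test_identity(self, tiny_config):
        g = build_network(tiny_config)
        g2 = apply_degradation(g, DegradationSpec(1.0, 1.0, 1.0), seed=1)
        assert np.array_equal(g.pre, g2.pre)
        assert np.array_equal(g.weight, g2.weight)

    def test_weight_scaling_exact(self, tiny_config):
        g = build_network(tiny_config)
        g2 = apply_degradation(g, DegradationSpec(R_w=0.5), seed=1)
        assert np.allclose(g2.weight, g.weight * 0.5)
        assert g2.n_edges == g.n_edges

    def test_connection_removal_binomial(self):
        cfg = NetworkConfig(nE=180, nI=36, C=0.25, n_engrams=1, engram_size=20, seed=3)
        g = build_network(cfg)
        R_C = 0.8
        remaining = [
            apply_degradation(g, DegradationSpec(R_C=R_C), seed=s).n_edges
            for s in range(60)
        ]
        expected = g.n_edges * R_C
        se = np.sqrt(g.n_edges * R_C * (1 - R_C) / len(remaining))
        assert abs(np.mean(remaining) - expected) < 4 * se

    def test_neuron_removal_preserves_ei_ratio(self, tiny_config):
        g = build_network(tiny_config)
        g2 = apply_degradation(g, DegradationSpec(R_N=0.5), seed=2)
        surviving = np.zeros(g.n_neurons, dtype=bool)
        surviving[g2.pre] = True
        surviving[g2.post] = True
        # engram labels of removed neurons are cleared
        assert (g2.engram_id >= 0).sum() <= (g.engram_id >= 0).sum()
        # edges incident to removed neurons are gone: all engram-labeled
        # endpoints are still labeled
        assert g2.n_edges < g.n_edges

    def test_rw_rc_commute_in_distribution(self, tiny_config):
        g = build_network(tiny_config)
        a = apply_degradation(
            apply_degradation(g, DegradationSpec(R_w=0.6), seed=5),
            DegradationSpec(R_C=0.7),
            seed=9,
        )
        b = apply_degradation(
            apply_degradation(g, DegradationSpec(R_C=0.7), seed=9),
            DegradationSpec(R_w=0.6),
            seed=5,
        )
        assert a.n_edges == b.n_edges
        assert np.allclose(np.sort(a.weight), np.sort(b.weight))

    def test_fraction_out_of_range_rejected(self, tiny_config):
        g = build_network(tiny_config)
        with pytest.raises(ValueError):
            apply_degradation(g, DegradationSpec(R_N=0.0), seed=1)
        with pytest.raises(ValueError):
            apply_degradation(g, DegradationSpec(R_w=1.5), seed=1)


class TestEIManipulation:
    def test_same_value_is_identity(self, tiny_config):
        g = build_network(tiny_config)
        g2 = set_ei_manipulation(g, tiny_config.g_EI)
        assert np.array_equal(g.weight, g2.weight)

    def test_all_ei_weights_rewritten(self, tiny_config):
        g = build_network(tiny_config)
        g2 = set_ei_manipulation(g, 0.10)
        ei = g2.is_exc[g2.pre] & ~g2.is_exc[g2.post]
        assert np.all(g2.weight[ei] == 0.10)
        assert np.array_equal(g2.weight[~ei], g.weight[~ei])

    def test_negative_weight_rejected(self, tiny_config):
        g = build_network(tiny_config)
        with pytest.raises(ValueError):
            set_ei_manipulation(g, -0.1)
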