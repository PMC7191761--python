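from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypome.analysis import (
    cloud_frequencies,
    cluster_genomes,
    cluster_heatmap,
    cooccurrence,
    fit_power_law,
    fit_power_law_xy,
    pan_core_curve,
)
from conftest import gcm_from_counts, random_gcm_counts

from _oracles import exhaustive_pan_core, pair_count_cooccurrence


def toy_gcm():
    # rows A(1,1,1), B(1,0,0), C(0,1,1)
    return gcm_from_counts(np.array([[1, 1, 1], [1, 0, 0], [0, 1, 1]]))


class TestPanCore:
    def test_single_genome(self):
        g = gcm_from_counts(np.array([[2], [1], [3]]))
        curve = pan_core_curve(g, samples=10, seed=0)
        assert curve.pan_mean[0] == curve.core_mean[0] == 3

    def test_toy_exhaustive_n2(self):
        curve = pan_core_curve(toy_gcm(), samples=300, seed=0)
        assert curve.samples_per_n == [3, 3, 1]
        assert curve.pan_mean[1] == pytest.approx(8 / 3)
        assert curve.core_mean[1] == pytest.approx(4 / 3)

    def test_full_subset_hits_totals(self):
        g = toy_gcm()
        curve = pan_core_curve(g, samples=300, seed=0)
        assert curve.pan_sizes[-1] == [3]
        assert curve.core_sizes[-1] == [1]

    def test_sampling_equals_exhaustive_when_budget_covers(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            counts = random_gcm_counts(rng, n_cyps=7, n_genomes=6)
            g = gcm_from_counts(counts)
            curve = pan_core_curve(g, samples=comb(6, 3), seed=1)
            presence = counts > 0
            for i, n in enumerate(curve.n):
                pan, core = exhaustive_pan_core(presence, n)
                assert np.mean(curve.pan_sizes[i]) == pytest.approx(pan)
                assert np.mean(curve.core_sizes[i]) == pytest.approx(core)

    def test_sampled_mean_converges_to_exhaustive(self):
        rng = np.random.default_rng(2)
        counts = random_gcm_counts(rng, n_cyps=10, n_genomes=8)
        presence = counts > 0
        g = gcm_from_counts(counts)
        pan_exact, _ = exhaustive_pan_core(presence, 4)
        errs = []
        for samples in (10, 40, 70):  # C(8,4)=70 is exhaustive
            curve = pan_core_curve(g, samples=samples, seed=5)
            errs.append(abs(np.mean(curve.pan_sizes[3]) - pan_exact))
        assert errs[-1] == pytest.approx(0.0)
        assert errs[0] >= errs[-1]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotonicity_property(self, seed):
        """Pan means never decrease and core means never increase with n."""
        rng = np.random.default_rng(seed)
        counts = random_gcm_counts(rng, n_cyps=rng.integers(2, 8), n_genomes=rng.integers(2, 7))
        curve = pan_core_curve(gcm_from_counts(counts), samples=50, seed=seed)
        assert np.all(np.diff(curve.pan_mean) >= -1e-12)
        assert np.all(np.diff(curve.core_mean) <= 1e-12)

    def test_distinct_subsets_only(self):
        g = gcm_from_counts(random_gcm_counts(np.random.default_rng(3), 5, 9))
        curve = pan_core_curve(g, samples=20, seed=7)
        # 20 < C(9,4): the sampler must have drawn 20 distinct subsets
        assert curve.samples_per_n[3] == 20

    def test_invalid_samples(self):
        with pytest.raises(ValueError):
            pan_core_curve(toy_gcm(), samples=0)


class TestPowerLaw:
    def test_exact_recovery(self):
        n = np.arange(1, 11)
        fit = fit_power_law_xy(n, 2.5 * n**0.8)
        assert fit.sigma == pytest.approx(2.5, abs=1e-9)
        assert fit.gamma == pytest.approx(0.8, abs=1e-9)

    def test_constant_curve(self):
        fit = fit_power_law_xy(np.arange(1, 8), np.full(7, 4.0))
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma == pytest.approx(4.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        n = np.arange(1, 31)
        y = 2.5 * n**0.8 * np.exp(rng.normal(0, 0.05, size=30))
        fit = fit_power_law_xy(n, y)
        assert fit.gamma == pytest.approx(0.8, abs=0.05)

    def test_fit_targets_mean_and_median(self):
        curve = pan_core_curve(toy_gcm(), samples=300, seed=0)
        mean_fit = fit_power_law(curve, fit_target="mean")
        median_fit = fit_power_law(curve, fit_target="median")
        assert mean_fit.fit_target == "mean" and median_fit.fit_target == "median"
        assert mean_fit.gamma > 0  # pan grows on the toy

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_power_law_xy([1, 2, 3], [1.0, 0.0, 2.0])


class TestCooccurrence:
    def test_single_genome_triangle(self):
        g = gcm_from_counts(np.array([[1], [2], [1]]))
        net = cooccurrence(g)
        assert len(net.edges) == 3
        assert (net.edges["weight"] == 1).all()

    def test_toy_counts(self):
        g = gcm_from_counts(np.array([[2, 1, 0], [1, 0, 3], [0, 4, 0]]))
        net = cooccurrence(g)
        w = net.weighted
        assert w.loc["CYP1", "CYP2"] == 1
        assert w.loc["CYP1", "CYP3"] == 1
        assert w.loc["CYP2", "CYP3"] == 0
        assert net.adjacency.to_numpy().sum() == 4  # 2 undirected edges

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            counts = random_gcm_counts(rng, n_cyps=10, n_genomes=10)
            net = cooccurrence(gcm_from_counts(counts, level="family"))
            expected = pair_count_cooccurrence(counts)
            np.testing.assert_array_equal(net.weighted.to_numpy(), expected)
            adj = net.adjacency.to_numpy()
            assert np.array_equal(adj, adj.T)
            assert np.all(np.diag(adj) == 0)
            assert np.array_equal(adj, (expected >= 1).astype(int))

    def test_weight_bounded_by_occurrence(self):
        rng = np.random.default_rng(23)
        counts = random_gcm_counts(rng, 8, 6)
        net = cooccurrence(gcm_from_counts(counts))
        occ = net.occurrence
        for row in net.edges.itertuples():
            assert row.weight <= min(occ[row.cyp_a], occ[row.cyp_b])

    def test_networkx_round_trip(self):
        g = gcm_from_counts(np.array([[1, 1], [1, 0], [0, 1]]))
        graph = cooccurrence(g).to_networkx()
        assert graph.number_of_nodes() == 3
        assert graph.nodes["CYP1"]["occurrence"] == 2


class TestGenomeClustering:
    def test_identical_columns_merge_first(self):
        counts = np.array([[3, 3, 0], [1, 1, 5], [0, 0, 2]])
        g = gcm_from_counts(counts)
        clustering = cluster_genomes(g)
        # first merge joins the two identical genomes at distance 0
        assert clustering.genome_linkage[0, 2] == pytest.approx(0.0)
        order = clustering.genome_leaf_order
        assert abs(order.index("g1") - order.index("g2")) == 1

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(31)
        g = gcm_from_counts(random_gcm_counts(rng, 6, 5))
        clustering = cluster_genomes(g)
        assert sorted(clustering.genome_leaf_order) == sorted(g.genome_ids)
        assert sorted(clustering.cyp_leaf_order) == sorted(g.cyp_names)

    def test_two_divergent_groups_form_top_subtrees(self):
        # genomes 0-2 use CYPs 0-2; genomes 3-5 use CYPs 3-5
        counts = np.zeros((6, 6), dtype=int)
        counts[:3, :3] = 3
        counts[3:, 3:] = 3
        clustering = cluster_genomes(gcm_from_counts(counts))
        order = clustering.genome_leaf_order
        groups = [{"g1", "g2", "g3"}, {"g4", "g5", "g6"}]
        first_half, second_half = set(order[:3]), set(order[3:])
        assert {frozenset(first_half), frozenset(second_half)} == {
            frozenset(g) for g in groups
        }

    def test_single_genome_skipped(self, caplog):
        g = gcm_from_counts(np.array([[1], [2]]))
        with caplog.at_level("WARNING"):
            assert cluster_genomes(g) is None

    def test_heatmap_outputs(self, tmp_path):
        g = gcm_from_counts(random_gcm_counts(np.random.default_rng(5), 5, 4))
        clustering = cluster_heatmap(
            g, out_image=tmp_path / "h.png", out_text=tmp_path / "h.txt"
        )
        assert (tmp_path / "h.png").stat().st_size > 0
        text = (tmp_path / "h.txt").read_text()
        assert text.startswith("#GENOME_LEAF_ORDER")
        assert "#GENOME_MERGE_TREE" in text
        assert clustering is not None


class TestCloud:
    def test_single_row(self):
        g = gcm_from_counts(np.array([[2, 3]]))
        cloud = cloud_frequencies(g)
        assert cloud.loc[0, "frequency"] == 5 and cloud.loc[0, "rank"] == 1

    def test_conservation_and_tie_break(self):
        g = gcm_from_counts(np.array([[2, 1, 0], [1, 0, 3], [0, 4, 0]]))
        cloud = cloud_frequencies(g)
        assert cloud["frequency"].sum() == g.total()
        # B=4 and C=4 tie broken by name, then A=3
        assert list(cloud["cyp"]) == ["CYP2", "CYP3", "CYP1"]
        assert list(cloud["frequency"]) == [4, 4, 3]


def test_open_vs_closed_pan_behaviour(reference, default_config):
    """A homogeneous population saturates (γ near 0); a union of two
    disjoint-family populations keeps growing (larger γ)."""
    import dataclasses

    from cypome.synth import expected_gcm, generate_genomes

    rng = np.random.default_rng(77)
    cfg = dataclasses.replace(default_config, n_genomes=8, decoys_per_genome=0)
    fams = reference.family_names
    homog, man_h = generate_genomes(cfg, reference, family_pool=fams[:1],
                                    genome_prefix="h", rng=rng)
    half = dataclasses.replace(cfg, n_genomes=4)
    a, man_a = generate_genomes(half, reference, family_pool=fams[:2],
                                genome_prefix="a", rng=rng)
    b, man_b = generate_genomes(half, reference, family_pool=fams[2:],
                                genome_prefix="b", rng=rng)
    man_union = pd.concat([man_a, man_b], ignore_index=True)
    g_h = expected_gcm(man_h, "subfamily")
    g_u = expected_gcm(man_union, "subfamily")
    gamma_h = fit_power_law(pan_core_curve(g_h, samples=100, seed=1)).gamma
    gamma_u = fit_power_law(pan_core_curve(g_u, samples=100, seed=1)).gamma
    assert gamma_u > gamma_h
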