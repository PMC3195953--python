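"""Graph measures, distributions, and the random-query null model."""

import math

import networkx as nx
import numpy as np
import pytest

from interolognet.network_ops import extract_query_network
from interolognet.topology import (
    MEASURE_NAMES,
    GraphMeasures,
    NullDistribution,
    clustering_distribution,
    compare_to_null,
    compute_measures,
    degree_distribution,
    sample_null,
)

import oracles


def graph(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return g


class TestComputeMeasures:
    def test_square_with_diagonal(self):
        # hand-enumerated: degrees A3 B2 C3 D2; local clustering A,C = 2/3,
        # B,D = 1; eccentric pair is B-D at distance 2
        g = graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C")])
        m = compute_measures(g)
        assert m.mean_degree == pytest.approx(2.5)
        assert m.diameter == 2
        assert m.index_of_aggregation == 1.0
        assert m.connectivity == pytest.approx(5 / 6)
        assert m.clustering_coefficient == pytest.approx(5 / 6)
        assert m.n_components == 1

    def test_star_is_perfectly_disassortative(self):
        # endpoint-degree pairs are (3,1) three times in each orientation
        m = compute_measures(nx.star_graph(3))
        assert m.assortativity == pytest.approx(-1.0)

    def test_cycle_assortativity_undefined(self):
        m = compute_measures(nx.cycle_graph(4))
        assert m.assortativity is None
        assert not m.assortativity_defined

    def test_single_node(self):
        m = compute_measures(graph([], extra_nodes=["A"]))
        assert m.diameter == 0
        assert m.connectivity == 0.0
        assert not m.density_defined

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            compute_measures(nx.Graph())

    def test_self_loop_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "A")
        with pytest.raises(ValueError, match="loop"):
            compute_measures(g)

    def test_disconnected_diameter_uses_largest_component(self):
        g = graph([("A", "B"), ("B", "C"), ("X", "Y")])
        m = compute_measures(g)
        assert m.diameter == 2
        assert m.n_components == 2
        assert m.index_of_aggregation == pytest.approx(3 / 5)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 13))
            p = float(rng.uniform(0, 1))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            got = compute_measures(g)
            want = oracles.oracle_measures(g)
            for name in MEASURE_NAMES:
                g_val, w_val = getattr(got, name), want[name]
                if name == "assortativity":
                    assert (g_val is None) == (w_val is None)
                    if g_val is None:
                        continue
                assert g_val == pytest.approx(w_val, abs=1e-9), name

    def test_index_of_aggregation_one_iff_connected(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = nx.gnp_random_graph(int(rng.integers(2, 20)), rng.uniform(0, 0.5),
                                    seed=int(rng.integers(2**31)))
            m = compute_measures(g)
            assert (m.index_of_aggregation == 1.0) == (m.n_components == 1)

    def test_edge_addition_monotonicity_on_connected_graphs(self):
        rng = np.random.default_rng(11)
        tried = 0
        while tried < 30:
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            missing = [e for e in nx.non_edges(g)]
            if not missing:
                continue
            tried += 1
            before = compute_measures(g)
            g2 = g.copy()
            g2.add_edge(*missing[int(rng.integers(len(missing)))])
            after = compute_measures(g2)
            assert after.diameter <= before.diameter
            assert after.connectivity >= before.connectivity
            assert after.mean_degree >= before.mean_degree


class TestDistributions:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert degree_distribution(g) == {2: 3}
        counts, edges = clustering_distribution(g)
        assert counts[-1] == 3 and counts[:-1].sum() == 0

    def test_path(self):
        g = nx.path_graph(3)
        assert degree_distribution(g) == {1: 2, 2: 1}
        counts, _ = clustering_distribution(g)
        assert counts[0] == 3

    def test_edgeless(self):
        assert degree_distribution(graph([], extra_nodes=range(5))) == {0: 5}

    def test_interior_value_lands_in_left_closed_bin(self):
        # 4-clique minus one edge: A sees B,C,D with 2 of 3 pairs linked,
        # local clustering exactly 2/3 -> bin [0.6, 0.7)
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("C", "D")])
        assert nx.clustering(g)["A"] == pytest.approx(2 / 3)
        counts, _ = clustering_distribution(g, bin_width=0.1)
        assert counts[6] >= 1


class TestSampleNull:
    def base(self):
        return nx.relabel_nodes(
            nx.gnp_random_graph(60, 0.08, seed=2), {i: f"N{i:02d}" for i in range(60)}
        )

    def test_same_seed_identical(self):
        base = self.base()
        a = sample_null(base, 5, n_reps=20, seed=9)
        b = sample_null(base, 5, n_reps=20, seed=9)
        assert a.samples == b.samples

    def test_different_seed_differs(self):
        base = self.base()
        a = sample_null(base, 5, n_reps=20, seed=9)
        b = sample_null(base, 5, n_reps=20, seed=10)
        assert a.samples != b.samples

    def test_shapes(self):
        null = sample_null(self.base(), 5, n_reps=50, seed=0)
        for name in MEASURE_NAMES:
            assert len(null.samples[name]) == 50

    def test_complete_graph_always_fully_aggregated(self):
        null = sample_null(nx.complete_graph(20), 3, n_reps=10, seed=1)
        assert all(v == 1.0 for v in null.samples["index_of_aggregation"])
        assert all(v == 1.0 for v in null.samples["connectivity"])

    def test_oversized_query_rejected(self):
        with pytest.raises(ValueError):
            sample_null(nx.complete_graph(5), 6, n_reps=2, seed=0)

    def test_replicates_match_public_extraction_path(self):
        base = self.base()
        null = sample_null(base, 6, n_reps=5, seed=3)
        nodes = sorted(base.nodes)
        for rep in range(5):
            rng = np.random.default_rng([3, rep])
            idx = rng.choice(len(nodes), size=6, replace=False)
            m = compute_measures(extract_query_network(base, [nodes[i] for i in idx]))
            for name in MEASURE_NAMES:
                a, b = null.samples[name][rep], getattr(m, name)
                if a is None or b is None:
                    assert a is b
                else:
                    assert a == pytest.approx(b, abs=1e-12)

    def test_undefined_assortativity_recorded_as_missing(self):
        # a perfect matching: every extracted subnetwork is degree-regular
        g = nx.Graph([(f"A{i}", f"B{i}") for i in range(10)])
        null = sample_null(g, 2, n_reps=10, seed=0)
        assert null.n_assortativity_undefined == 10
        assert math.isnan(null.mean("assortativity"))


class TestCompareToNull:
    def make_null(self, values, measure="mean_degree"):
        n = len(values)
        samples = {m: [0.0] * n for m in MEASURE_NAMES}
        samples[measure] = list(values)
        return NullDistribution(n_reps=n, query_size=3, seed=0, samples=samples)

    def obs(self, **kwargs):
        base = dict(
            n_nodes=10, n_edges=10, mean_degree=2.0, diameter=3,
            index_of_aggregation=1.0, connectivity=0.2,
            clustering_coefficient=0.1, assortativity=0.0, n_components=1,
        )
        base.update(kwargs)
        return GraphMeasures(**base)

    def test_observation_at_mean_of_symmetric_null_has_p_one(self):
        null = self.make_null([1.0, 2.0, 3.0, 2.0, 1.0, 3.0])
        report = compare_to_null(self.obs(mean_degree=2.0), null).set_index("measure")
        assert report.loc["mean_degree", "p"] == pytest.approx(1.0)

    def test_observation_beyond_all_samples(self):
        values = list(np.linspace(1.0, 2.0, 300))
        null = self.make_null(values)
        report = compare_to_null(self.obs(mean_degree=50.0), null).set_index("measure")
        assert report.loc["mean_degree", "p"] == pytest.approx(1 / 301)

    def test_z_score(self):
        values = [1.0, 2.0, 3.0] * 40
        null = self.make_null(values)
        report = compare_to_null(self.obs(mean_degree=4.0), null).set_index("measure")
        mu = np.mean(values)
        sd = np.std(values, ddof=1)
        assert report.loc["mean_degree", "z"] == pytest.approx((4.0 - mu) / sd)

    def test_small_null_warns(self):
        null = self.make_null([1.0] * 5)
        with pytest.warns(UserWarning, match="replicates"):
            compare_to_null(self.obs(), null)

    def test_undefined_observed_assortativity_gives_nan_row(self):
        null = self.make_null([1.0] * 30)
        report = compare_to_null(self.obs(assortativity=None), null).set_index("measure")
        assert math.isnan(report.loc["assortativity", "observed"])
        assert math.isnan(report.loc["assortativity", "p"])

    def test_round_trip_through_frame(self):
        null = sample_null(nx.gnp_random_graph(30, 0.2, seed=1), 4, n_reps=25, seed=2)
        back = NullDistribution.from_frame(null.to_frame())
        for name in MEASURE_NAMES:
            for a, b in zip(back.samples[name], null.samples[name]):
                if a is None or b is None:
                    assert a is None and b is None
                else:
                    assert a == pytest.approx(b)
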