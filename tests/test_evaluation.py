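"""Attack curves, normalized modularity, f-measure accuracy, ranked profiles."""

import pytest

from treeify import WeightedNetwork
from treeify.evaluation import (
    attack_simulation,
    clustering_accuracy,
    f_measure,
    modularity_by_depth,
    normalized_modularity,
    ranked_property_profile,
)
from treeify.graph_io import ValidationError
from treeify.hubs_modules import Cluster, ClusterSet


class TestAttackSimulation:
    def test_connected_network_starts_at_one(self, toy_net):
        curve = attack_simulation(toy_net, "degree", 0)
        assert curve.fraction_at(0) == 1.0

    def test_star_degree_attack_shatters(self):
        net = WeightedNetwork([("hub", f"l{i}", 1.0) for i in range(4)])
        curve = attack_simulation(net, "degree", 1)
        assert curve.removed == ["hub"]
        assert curve.fraction_at(1) == pytest.approx(1 / 5)

    def test_random_attack_reproducible_under_seed(self):
        net = WeightedNetwork([("A", "B", 1.0), ("B", "C", 1.0)])
        c1 = attack_simulation(net, "random", 2, seed=42)
        c2 = attack_simulation(net, "random", 2, seed=42)
        assert c1.points == c2.points and c1.removed == c2.removed

    def test_deterministic_strategy_fractions_non_increasing(self):
        from treeify.synthetic_fixtures import scale_free_fixture

        net = scale_free_fixture(40, 2, seed=5)
        curve = attack_simulation(net, "degree", 10)
        fs = [f for _, f in curve.points]
        assert all(a >= b for a, b in zip(fs, fs[1:]))
        assert all(0.0 <= f <= 1.0 for f in fs)

    def test_hub_confidence_static_ranking_used(self, toy_net):
        curve = attack_simulation(
            toy_net, "hub_confidence", 2, ranking=["A", "C", "B", "D"]
        )
        assert curve.removed == ["A", "C"]

    def test_unknown_strategy_rejected(self, toy_net):
        with pytest.raises(ValidationError):
            attack_simulation(toy_net, "betweenness", 1)

    def test_too_many_steps_rejected(self, toy_net):
        with pytest.raises(ValidationError):
            attack_simulation(toy_net, "random", 5)


class TestNormalizedModularity:
    def test_toy_two_node_set(self, toy_net):
        score = normalized_modularity(toy_net, {"A", "B"})
        assert score.raw == pytest.approx(1 / 3)
        assert score.normalization == pytest.approx(1 / 3)
        assert score.normalized == pytest.approx(1.0)

    def test_isolated_component_raw_one(self):
        net = WeightedNetwork(
            [("A", "B", 1.0), ("B", "C", 1.0), ("X", "Y", 1.0)]
        )
        assert normalized_modularity(net, {"X", "Y"}).raw == pytest.approx(1.0)

    def test_no_internal_edge_raw_zero(self):
        net = WeightedNetwork([("A", "B", 1.0), ("B", "C", 1.0)])
        assert normalized_modularity(net, {"A", "C"}).raw == 0.0

    def test_no_incident_edge_undefined(self):
        net = WeightedNetwork([("A", "B", 1.0)], nodes=["X", "Y", "Z"])
        score = normalized_modularity(net, {"X", "Y"})
        assert not score.defined

    def test_size_bounds_enforced(self, toy_net):
        with pytest.raises(ValidationError):
            normalized_modularity(toy_net, {"A"})
        with pytest.raises(ValidationError):
            normalized_modularity(toy_net, {"A", "B", "C", "D"})


class TestModularityByDepth:
    def make_clusters(self, specs):
        return ClusterSet(
            clusters=[
                Cluster(hub=h, members=frozenset(m), depth=d, confidence=1.0)
                for h, m, d in specs
            ]
        )

    def test_single_cluster_single_group(self, toy_net):
        cs = self.make_clusters([("A", {"A", "B"}, 1)])
        got = modularity_by_depth(toy_net, cs)
        assert got == [(1, pytest.approx(1.0))]

    def test_same_depth_groups_average(self, toy_net):
        cs = self.make_clusters(
            [("A", {"A", "B"}, 1), ("C", {"C", "D"}, 1)]
        )
        [(d, m)] = modularity_by_depth(toy_net, cs)
        s1 = normalized_modularity(toy_net, {"A", "B"}).normalized
        s2 = normalized_modularity(toy_net, {"C", "D"}).normalized
        assert d == 1 and m == pytest.approx((s1 + s2) / 2)

    def test_empty_cluster_set_rejected(self, toy_net):
        with pytest.raises(ValidationError):
            modularity_by_depth(toy_net, ClusterSet(clusters=[]))


class TestFMeasure:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 2 / 3),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            ({"A", "B", "C", "D"}, {"B", "C", "D"}, 6 / 7),
            ({"C", "D"}, {"B", "C", "D"}, 4 / 5),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert f_measure(x, y) == pytest.approx(expected)

    def test_symmetric_under_swap(self):
        a, b = {"A", "B", "C"}, {"B", "D"}
        assert f_measure(a, b) == pytest.approx(f_measure(b, a))

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            f_measure(set(), {"A"})


class TestClusteringAccuracy:
    def test_perfect_match(self):
        mods = {"m1": {"A", "B"}, "m2": {"C", "D"}}
        acc = clustering_accuracy(
            [frozenset({"A", "B"}), frozenset({"C", "D"})], mods
        )
        assert acc[None] == pytest.approx(1.0)

    def test_no_overlap_is_zero(self):
        acc = clustering_accuracy([frozenset({"X", "Y"})], {"m": {"A", "B"}})
        assert acc[None] == 0.0

    def test_best_match_selected(self):
        # module {B,C,D}: candidates score 6/7 and 4/5; best must win
        acc = clustering_accuracy(
            [frozenset({"A", "B", "C", "D"}), frozenset({"C", "D"})],
            {"m": {"B", "C", "D"}},
        )
        assert acc[None] == pytest.approx(6 / 7)

    def test_reported_per_level(self):
        mods = {"m1": {"A", "B"}, "m2": {"C", "D"}}
        acc = clustering_accuracy(
            [frozenset({"A", "B"})], mods, levels={"m1": 1, "m2": 2}
        )
        assert acc[1] == pytest.approx(1.0) and acc[2] == 0.0

    def test_no_clusters_warns_zero(self):
        acc = clustering_accuracy([], {"m": {"A", "B"}})
        assert acc[None] == 0.0

    def test_no_usable_module_rejected(self):
        with pytest.raises(ValidationError):
            clustering_accuracy([frozenset({"A"})], {"m": {"A"}})


class TestRankedPropertyProfile:
    def test_lethal_block_proportions(self):
        ranking = [f"n{i:02d}" for i in range(20)]
        flags = {n: i < 10 for i, n in enumerate(ranking)}
        prof = ranked_property_profile(ranking, flags, window=10)
        assert prof.window_means == [pytest.approx(1.0), pytest.approx(0.0)]
        assert prof.cumulative_means[9] == pytest.approx(1.0)
        assert prof.cumulative_means[-1] == pytest.approx(0.5)

    def test_constant_counts_flat_profile(self):
        ranking = ["a", "b", "c", "d"]
        prof = ranked_property_profile(ranking, {n: 3.0 for n in ranking}, 2)
        assert prof.window_means == [3.0, 3.0]
        assert all(c == pytest.approx(3.0) for c in prof.cumulative_means)

    def test_missing_values_excluded(self):
        prof = ranked_property_profile(["a", "b"], {"a": 1.0}, 1)
        assert prof.n_missing == 1 and prof.window_means == [1.0]

    def test_window_below_one_rejected(self):
        with pytest.raises(ValidationError):
            ranked_property_profile(["a"], {"a": 1.0}, 0)

    def test_hub_term_overlap_decreases_along_ranking(self):
        """Designated hubs carry more terms, so the overlap profile peaks early."""
        import numpy as np

        from treeify import all_pairs_similarity, build_tree, rank_hubs
        from treeify.path_strength import PathStrengthParams
        from treeify.synthetic_fixtures import FixtureSpec, generate

        p = PathStrengthParams()
        tops, rests = [], []
        for seed in range(5):
            net, ann, _, _ = generate(FixtureSpec(seed=seed))
            store = all_pairs_similarity(net, p)
            report = rank_hubs(build_tree(net, store), store)
            counts = {n: float(len(ann.terms_of(n))) for n in net.nodes}
            prof = ranked_property_profile(report.ranking, counts, window=10)
            tops.append(prof.window_means[0])
            rests.append(prof.window_means[-1])
        assert np.mean(tops) > np.mean(rests)
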