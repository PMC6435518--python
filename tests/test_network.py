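import numpy as np
import pytest

from trimodenet import (
    EntityTermWeights,
    GoiEdge,
    TriModeNetwork,
    ValidationError,
    assemble,
    maxflow_score,
    score_matrix,
)
from _oracles import isolated_int_arcs, min_cut_enumeration, random_layered_network

SCALE = 10**6


class TestTriModeNetworkInvariants:
    def test_component_to_effect_arc_rejected(self):
        with pytest.raises(ValidationError):
            TriModeNetwork(("c",), ("g",), ("e",), {("c", "e"): 1.0})

    def test_go_go_arc_needs_equal_antiparallel(self):
        with pytest.raises(ValidationError):
            TriModeNetwork(("c",), ("g1", "g2"), ("e",), {("g1", "g2"): 0.5})

    def test_negative_capacity_rejected(self):
        with pytest.raises(ValidationError):
            TriModeNetwork(("c",), ("g",), ("e",), {("c", "g"): -0.1})


class TestAssemble:
    def test_minimal_two_layer_merge(self):
        net = assemble(
            [EntityTermWeights("c1", {"g1": 0.4})],
            [],
            [EntityTermWeights("e1", {"g1": 0.9})],
        )
        assert net.arcs == {("c1", "g1"): 0.4, ("g1", "e1"): 0.9}

    def test_goi_only_isolated_term_pruned(self):
        net = assemble(
            [EntityTermWeights("c1", {"g1": 0.4})],
            [GoiEdge("g8", "g9", 2, 0.7)],
            [EntityTermWeights("e1", {"g1": 0.9})],
        )
        assert set(net.go_terms) == {"g1"}

    def test_goi_bridge_terms_kept(self):
        # g2 is only in the GOI layer but lies on a c1->g1->g2->e1 path
        net = assemble(
            [EntityTermWeights("c1", {"g1": 0.4})],
            [GoiEdge("g1", "g2", 3, 0.6)],
            [EntityTermWeights("e1", {"g2": 0.9})],
        )
        assert set(net.go_terms) == {"g1", "g2"}
        assert net.arcs[("g1", "g2")] == 0.6

    def test_shared_term_id_merges_into_one_node(self):
        net = assemble(
            [EntityTermWeights("c1", {"g1": 0.4}), EntityTermWeights("c2", {"g1": 0.2})],
            [],
            [EntityTermWeights("e1", {"g1": 0.9})],
        )
        assert net.go_terms == ("g1",)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValidationError):
            assemble([], [], [EntityTermWeights("e1", {"g1": 0.9})])

    def test_goi_capacity_count_option(self):
        net = assemble(
            [EntityTermWeights("c1", {"g1": 0.4})],
            [GoiEdge("g1", "g2", 3, 0.6)],
            [EntityTermWeights("e1", {"g2": 0.9})],
            goi_capacity="count",
        )
        assert net.arcs[("g1", "g2")] == 3.0


class TestMaxflowScore:
    def test_single_path_bottleneck(self):
        net = assemble(
            [EntityTermWeights("c", {"g": 0.4})],
            [],
            [EntityTermWeights("e", {"g": 0.9})],
        )
        assert maxflow_score(net, "c", "e") == pytest.approx(0.4)

    def test_parallel_paths_add(self):
        net = assemble(
            [EntityTermWeights("c", {"g1": 0.3, "g2": 0.5})],
            [],
            [EntityTermWeights("e", {"g1": 1.0, "g2": 1.0})],
        )
        assert maxflow_score(net, "c", "e") == pytest.approx(0.8)

    def test_diamond_with_goi_detour(self):
        # brute-force enumeration on this 4-node graph gives 0.9
        net = TriModeNetwork(
            ("c",), ("g1", "g2"), ("e",),
            {
                ("c", "g1"): 1.0, ("c", "g2"): 1.0,
                ("g1", "g2"): 0.2, ("g2", "g1"): 0.2,
                ("g1", "e"): 0.5, ("g2", "e"): 0.4,
            },
        )
        arcs = isolated_int_arcs(net, "c", "e", SCALE)
        assert min_cut_enumeration(arcs, "c", "e") == int(0.9 * SCALE)
        assert maxflow_score(net, "c", "e") == pytest.approx(0.9)

    def test_no_path_returns_zero(self):
        net = TriModeNetwork(("c",), ("g",), ("e",), {("c", "g"): 1.0})
        assert maxflow_score(net, "c", "e") == 0.0

    def test_unknown_node_rejected(self):
        net = TriModeNetwork(("c",), ("g",), ("e",), {})
        with pytest.raises(ValidationError):
            maxflow_score(net, "nope", "e")

    def test_other_entities_cannot_relay_flow(self):
        # c2's arcs must not help the (c1, e1) flow
        base = {
            ("c1", "g1"): 0.5, ("g1", "e1"): 0.5,
            ("c2", "g1"): 9.0, ("g1", "e2"): 9.0,
        }
        net = TriModeNetwork(("c1", "c2"), ("g1",), ("e1", "e2"), base)
        assert maxflow_score(net, "c1", "e1") == pytest.approx(0.5)

    def test_agrees_with_min_cut_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            net = random_layered_network(rng)
            comp = net.components[int(rng.integers(len(net.components)))]
            eff = net.effects[int(rng.integers(len(net.effects)))]
            arcs = isolated_int_arcs(net, comp, eff, SCALE)
            expected = min_cut_enumeration(arcs, comp, eff)
            got = maxflow_score(net, comp, eff)
            assert int(round(got * SCALE)) == expected

    def test_min_cut_certificate_for_each_pair(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_layered_network(rng)
            for comp in net.components:
                for eff in net.effects:
                    graph = nx.DiGraph()
                    graph.add_nodes_from([comp, eff, *net.go_terms])
                    for (u, v), cap in isolated_int_arcs(net, comp, eff, SCALE).items():
                        graph.add_edge(u, v, capacity=cap)
                    cut_value, _ = nx.minimum_cut(graph, comp, eff)
                    assert int(round(maxflow_score(net, comp, eff) * SCALE)) == cut_value

    def test_increasing_capacity_never_decreases_flow(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_layered_network(rng)
            if not net.arcs:
                continue
            base = score_matrix(net)
            key = sorted(net.arcs)[int(rng.integers(len(net.arcs)))]
            bumped = dict(net.arcs)
            bumped[key] = bumped[key] + 0.25
            if (key[1], key[0]) in bumped:  # keep GO-GO arcs symmetric
                bumped[(key[1], key[0])] = bumped[key]
            net2 = TriModeNetwork(net.components, net.go_terms, net.effects, bumped)
            assert np.all(score_matrix(net2).z >= base.z - 1e-12)

    def test_without_goi_flow_is_sum_of_min_weights(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_g = int(rng.integers(1, 5))
            gos = [f"g{i}" for i in range(n_g)]
            cw = {g: int(rng.integers(0, 101)) / 100 for g in gos if rng.random() < 0.8}
            ew = {g: int(rng.integers(0, 101)) / 100 for g in gos if rng.random() < 0.8}
            if not cw or not ew:
                continue
            net = assemble(
                [EntityTermWeights("c", cw)], [], [EntityTermWeights("e", ew)]
            )
            closed_form = sum(min(cw[g], ew[g]) for g in set(cw) & set(ew))
            assert maxflow_score(net, "c", "e") == pytest.approx(closed_form)


class TestScoreMatrix:
    def test_trivial_path_matrix(self):
        net = assemble(
            [EntityTermWeights("c", {"g": 0.4})],
            [],
            [EntityTermWeights("e", {"g": 0.9})],
        )
        zm = score_matrix(net)
        assert zm.z.tolist() == [[pytest.approx(0.4)]]

    def test_component_without_arcs_has_zero_row(self):
        net = assemble(
            [EntityTermWeights("c1", {"g": 0.4}), EntityTermWeights("c2", {})],
            [],
            [EntityTermWeights("e", {"g": 0.9})],
        )
        zm = score_matrix(net)
        i = zm.components.index("c2")
        assert np.all(zm.z[i] == 0)

    def test_row_bound_by_outgoing_capacity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_layered_network(rng)
            zm = score_matrix(net)
            for i, comp in enumerate(zm.components):
                out_cap = sum(c for (u, _), c in net.arcs.items() if u == comp)
                assert np.all(zm.z[i] <= out_cap + 1e-9)

    def test_label_equivariance_under_component_permutation(self, worked_network):
        net, _ = worked_network
        zm = score_matrix(net)
        permuted = TriModeNetwork(
            tuple(reversed(net.components)), net.go_terms, net.effects, dict(net.arcs)
        )
        zp = score_matrix(permuted)
        for comp in net.components:
            i, j = zm.components.index(comp), zp.components.index(comp)
            assert np.allclose(zm.z[i], zp.z[j])
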