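import math

import numpy as np
import pytest

import demeflow as dm
from demeflow.layers import LayerNetwork
from demeflow.mapeq import (
    MultilayerPartition,
    StateNetwork,
    build_multilayer,
    codelength,
    louvain_minimize,
    modularity_for_subgraph,
    sex_pair_filter,
    stationary_flow,
)

from conftest import enumerate_set_partitions


def layer_net(ids, edges, index=0):
    n = len(ids)
    A = np.zeros((n, n))
    for a, b, w in edges:
        i, j = ids.index(a), ids.index(b)
        A[i, j] = A[j, i] = w
    return LayerNetwork(index, list(ids), A)


def brute_force_minimum(net, teleport=0.0):
    """Exhaustive search over all partitions of the state nodes."""
    p = stationary_flow(net, teleport)
    best_L, best_groups = np.inf, None
    for groups in enumerate_set_partitions(net.nodes):
        assignment = {}
        for m, group in enumerate(groups):
            for node in group:
                assignment[node] = m
        L = codelength(net, MultilayerPartition(assignment), teleport, visit_rates=p).L
        if L < best_L - 1e-12:
            best_L, best_groups = L, groups
    return best_L, best_groups


class TestStationaryFlow:
    def test_triangle_uniform(self):
        net = StateNetwork.from_single_layer(
            layer_net("abc", [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        )
        assert np.allclose(stationary_flow(net, 0.0), 1 / 3)

    def test_path_proportional_to_strength(self):
        net = StateNetwork.from_single_layer(
            layer_net("abc", [("a", "b", 1), ("b", "c", 1)])
        )
        assert np.allclose(stationary_flow(net, 0.0), [0.25, 0.5, 0.25], atol=1e-12)

    def test_matches_dense_eigen_solve(self, rng):
        # independent oracle: stationary vector of the exact teleported
        # transition matrix via dense linear algebra
        n = 5
        W = rng.uniform(0, 1, (n, n)) * rng.integers(0, 2, (n, n))
        np.fill_diagonal(W, 0)
        W[3] = 0  # a dangling node
        links = {
            i: {j: W[i, j] for j in range(n) if W[i, j] > 0}
            for i in range(n)
            if W[i].sum() > 0
        }
        net = StateNetwork(nodes=[(t, 0) for t in "abcde"], links=links)
        tau = 0.01
        P = np.zeros((n, n))
        for i in range(n):
            if W[i].sum() > 0:
                P[i] = (1 - tau) * W[i] / W[i].sum() + tau / n
            else:
                P[i] = 1.0 / n
        vals, vecs = np.linalg.eig(P.T)
        k = np.argmin(np.abs(vals - 1.0))
        expected = np.real(vecs[:, k])
        expected /= expected.sum()
        assert np.allclose(stationary_flow(net, tau), expected, atol=1e-9)

    def test_all_zero_network_raises(self):
        net = StateNetwork(nodes=[("a", 0), ("b", 0)], links={})
        with pytest.raises(ValueError, match="all-zero"):
            stationary_flow(net)


class TestCodelength:
    def test_one_module_equals_entropy_of_visit_rates(self, rng):
        net = StateNetwork.from_single_layer(
            layer_net("abcd", [("a", "b", 2), ("b", "c", 1), ("c", "d", 3), ("a", "d", 1)])
        )
        p = stationary_flow(net, 0.01)
        one = MultilayerPartition({node: 0 for node in net.nodes})
        res = codelength(net, one, 0.01)
        assert res.L == pytest.approx(-np.sum(p * np.log2(p)), abs=1e-12)
        assert res.index_length == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_hand_value(self):
        # separate codebooks per component, no exit flow at tau = 0:
        # L = sum_m p_m H(P_m) = 2 * (1/2) * log2(3)
        fx = dm.make_fixture("two_triangles")
        net = StateNetwork.from_single_layer(fx["network"])
        part = MultilayerPartition({(t, 0): m for t, m in fx["components"].items()})
        res = codelength(net, part, teleport=0.0)
        assert res.L == pytest.approx(math.log2(3), abs=1e-9)

    def test_singletons_cost_more_than_components(self):
        fx = dm.make_fixture("two_triangles")
        net = StateNetwork.from_single_layer(fx["network"])
        comp = MultilayerPartition({(t, 0): m for t, m in fx["components"].items()})
        singles = MultilayerPartition({(t, 0): i for i, t in enumerate("abcdef")})
        assert codelength(net, singles, 0.0).L > codelength(net, comp, 0.0).L

    def test_missing_node_raises(self):
        fx = dm.make_fixture("two_triangles")
        net = StateNetwork.from_single_layer(fx["network"])
        with pytest.raises(ValueError, match="missing"):
            codelength(net, MultilayerPartition({("a", 0): 0}))

    def test_nonnegative_and_bounded_below_by_entropy(self, rng):
        net = StateNetwork.from_single_layer(
            layer_net("abcde", [("a", "b", 1), ("b", "c", 2), ("c", "d", 1), ("d", "e", 2), ("a", "e", 1)])
        )
        p = stationary_flow(net, 0.01)
        h = -np.sum(p * np.log2(p))
        for groups in [[["a", "b"], ["c", "d", "e"]], [["a"], ["b", "c"], ["d", "e"]]]:
            part = MultilayerPartition(
                {(t, 0): m for m, g in enumerate(groups) for t in g}
            )
            assert codelength(net, part, 0.01).L >= h - 1e-12


class TestBuildMultilayer:
    def two_layers(self, identical=True):
        l0 = layer_net("abc", [("a", "b", 2), ("b", "c", 1)], index=0)
        edges = [("a", "b", 2), ("b", "c", 1)] if identical else [("a", "c", 5)]
        l1 = layer_net("abc", edges, index=1)
        return [l0, l1]

    def test_r_zero_no_cross_links(self):
        net = build_multilayer(self.two_layers(), r=0.0)
        for i, nbrs in net.links.items():
            layer_i = net.nodes[i][1]
            assert all(net.nodes[j][1] == layer_i for j in nbrs)

    def test_identical_layers_cross_equals_intra(self):
        # sigma = 1 for every node, so the cross-layer out-weight of a state
        # node equals r/(1-r) times its intra-layer out-weight at r = 0.5
        net = build_multilayer(self.two_layers(identical=True), r=0.5)
        for i in range(net.n_nodes):
            intra = sum(
                w for j, w in net.links.get(i, {}).items()
                if net.nodes[j][1] == net.nodes[i][1]
            )
            cross = sum(
                w for j, w in net.links.get(i, {}).items()
                if net.nodes[j][1] != net.nodes[i][1]
            )
            if intra + cross > 0:
                assert cross == pytest.approx(intra, rel=1e-12)

    def test_disjoint_neighborhoods_no_cross_flow(self):
        # b's neighbors: {a,c} in layer 0 vs {a,c}... use a net where a's
        # neighborhoods are disjoint between layers
        l0 = layer_net("abcd", [("a", "b", 1)], index=0)
        l1 = layer_net("abcd", [("a", "c", 1)], index=1)
        net = build_multilayer([l0, l1], r=0.5)
        ia0 = net.index_of(("a", 0))
        cross = [
            j for j in net.links.get(ia0, {}) if net.nodes[j][1] != 0
        ]
        assert cross == []  # overlap of disjoint supports is zero

    def test_out_strength_conserved_when_similar(self):
        net = build_multilayer(self.two_layers(identical=True), r=0.3)
        s = net.out_strength()
        for i in range(net.n_nodes):
            tag, layer = net.nodes[i]
            assert s[i] == pytest.approx(3.0 if tag == "b" else 2.0 if tag == "a" else 1.0)

    def test_invalid_relax_rate_raises(self):
        with pytest.raises(ValueError):
            build_multilayer(self.two_layers(), r=1.2)


class TestLouvain:
    def test_two_triangles_recovers_components(self):
        fx = dm.make_fixture("two_triangles")
        net = StateNetwork.from_single_layer(fx["network"])
        part, res = louvain_minimize(net, rng=0, teleport=0.0)
        groups = {}
        for node, m in part.assignment.items():
            groups.setdefault(m, set()).add(node[0])
        assert sorted(map(sorted, groups.values())) == [list("abc"), list("def")]
        assert res.L_after == pytest.approx(math.log2(3), abs=1e-9)
        assert res.M == pytest.approx(math.log2(6) / math.log2(3), abs=1e-9)

    def test_complete_graph_one_module(self):
        edges = [(a, b, 1) for i, a in enumerate("abcde") for b in "abcde"[i + 1:]]
        net = StateNetwork.from_single_layer(layer_net("abcde", edges))
        part, res = louvain_minimize(net, rng=0)
        assert len(part.modules()) == 1
        assert res.M == 1.0

    def test_never_below_one(self, rng):
        for _ in range(5):
            ids = list("abcdef")
            edges = []
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    if rng.random() < 0.5:
                        edges.append((a, b, float(rng.uniform(0.5, 3))))
            if not edges:
                continue
            net = StateNetwork.from_single_layer(layer_net(ids, edges))
            _part, res = louvain_minimize(net, rng=int(rng.integers(1000)))
            assert res.M >= 1.0

    def test_deterministic_under_seed(self):
        fx = dm.make_fixture("two_triangles")
        net = StateNetwork.from_single_layer(fx["network"])
        p1, r1 = louvain_minimize(net, rng=99)
        p2, r2 = louvain_minimize(net, rng=99)
        assert p1.assignment == p2.assignment
        assert r1.L_after == r2.L_after

    @pytest.mark.parametrize("teleport", [0.0, 0.01])
    def test_matches_brute_force_on_small_fixtures(self, teleport, rng):
        # global-optimality oracle: exhaustive enumeration over all
        # partitions of <= 8 state nodes
        fixtures = []
        fx = dm.make_fixture("two_triangles")
        fixtures.append(StateNetwork.from_single_layer(fx["network"]))
        # two individuals across three coupled layers
        lns = [
            layer_net("ab", [("a", "b", 1 + l)], index=l) for l in range(3)
        ]
        fixtures.append(build_multilayer(lns, r=0.4))
        # asymmetric barbell: two triangles joined by a weak bridge
        bar = layer_net(
            "abcdef",
            [("a", "b", 2), ("b", "c", 2), ("a", "c", 2),
             ("d", "e", 1), ("e", "f", 1), ("d", "f", 1), ("c", "d", 0.2)],
        )
        fixtures.append(StateNetwork.from_single_layer(bar))
        for net in fixtures:
            if teleport == 0.0 and not all(
                net.links.get(i) for i in range(net.n_nodes)
            ):
                continue  # teleport-free flow needs no dangling nodes
            best_L, _groups = brute_force_minimum(net, teleport)
            _part, res = louvain_minimize(net, rng=1, teleport=teleport)
            assert res.L_after == pytest.approx(best_L, abs=1e-9)

    def test_found_compresses_at_least_as_well_as_planted(self, small_sim):
        sim, pre = small_sim
        net = build_multilayer(pre.networks, r=0.6)
        part, res = louvain_minimize(net, rng=0)
        truth = sim.truth_partition(net.nodes)
        assert res.L_after <= codelength(net, truth).L + 1e-9

    def test_r_zero_equals_independent_layerwise_clustering(self, small_sim):
        _sim, pre = small_sim
        nets = pre.networks[:3]
        multi = build_multilayer(nets, r=0.0)
        _part, res = louvain_minimize(multi, rng=4)
        per_layer_L = []
        weights = []
        p_all = stationary_flow(multi, 0.01)
        # with r = 0 the state network is block-diagonal: clustering each
        # block independently must reach the same codelength
        joint = {}
        for ln in nets:
            sub = build_multilayer([ln], r=0.0)
            part_l, _ = louvain_minimize(sub, rng=4)
            for node, m in part_l.assignment.items():
                joint[node] = (node[1], m)
        relabel = {key: i for i, key in enumerate(sorted(set(joint.values())))}
        stitched = MultilayerPartition({n: relabel[v] for n, v in joint.items()})
        assert codelength(multi, stitched).L == pytest.approx(res.L_after, abs=1e-6)


class TestSubgraphModularity:
    def test_identity_filter_reproduces_full_M(self, small_sim):
        _sim, pre = small_sim
        net = build_multilayer(pre.networks, r=0.6)
        part, res = louvain_minimize(net, rng=0)
        M = modularity_for_subgraph(
            pre.networks, part, edge_filter=lambda a, b: True, r=0.6
        )
        assert M == pytest.approx(res.M, rel=1e-9)

    def test_opposite_sex_filter_on_single_sex_network_raises(self):
        lns = [layer_net("ab", [("a", "b", 1)])]
        sexes = {"a": "F", "b": "F"}

        def ff(x, y):
            return {sexes[x], sexes[y]} == {"F", "M"}

        part = MultilayerPartition({("a", 0): 0, ("b", 0): 0})
        with pytest.raises(ValueError, match="no interactions"):
            modularity_for_subgraph(lns, part, edge_filter=ff, r=0.0)

    def test_sex_pair_filter_classes(self, small_sim):
        sim, _pre = small_sim
        ff = sex_pair_filter(sim.individuals, "FF")
        mm = sex_pair_filter(sim.individuals, "MM")
        fm = sex_pair_filter(sim.individuals, "FM")
        assert ff("F01", "F02") and not ff("F01", "M01")
        assert mm("M01", "M02") and not mm("F01", "M01")
        assert fm("F01", "M01") and not fm("F01", "F02")
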