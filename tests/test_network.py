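"""Residue networks, I_min selection, stability filtering, shortest paths."""

import networkx as nx
import numpy as np
import pytest

from interlock.network import (
    NetworkError,
    NetworkParams,
    PathResult,
    ResidueNetwork,
    build_network,
    common_path_residues,
    ensemble_paths,
    interaction_strength,
    largest_cluster_profile,
    select_imin,
    shortest_path,
    stable_network,
)
from interlock.structio import Ensemble, Residue, Snapshot, make_atom
from interlock.synthetic_data import (
    generate_ensemble,
    generate_two_cluster_snapshot,
)
from conftest import point_snapshot, single_atom_residue


def clump_residue(chain, number, centre, n_atoms, name="ALA"):
    rng = np.random.default_rng(number)
    atoms = [make_atom("CA", "C", centre)]
    for k in range(n_atoms - 1):
        atoms.append(make_atom(f"C{k}", "C", centre + rng.normal(0, 0.5, 3)))
    return Residue(chain, number, name, atoms)


class TestInteractionStrength:
    def test_distant_residues_score_zero(self):
        r1 = single_atom_residue("A", 1, [0, 0, 0])
        r2 = single_atom_residue("A", 5, [30, 0, 0])
        assert interaction_strength(r1, r2, NetworkParams()) == 0.0

    def test_direct_formula(self):
        # 5 heavy-atom contact pairs, both normalization constants 100 -> 5.0%
        r1 = single_atom_residue("A", 1, [0, 0, 0], name="ALA")
        atoms = [make_atom(f"C{k}", "C", [1.0 + 0.1 * k, 0, 0]) for k in range(5)]
        r2 = Residue("A", 5, "ALA", atoms)
        params = NetworkParams(normalization={"ALA": 100.0})
        assert interaction_strength(r1, r2, params) == pytest.approx(5.0)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        params = NetworkParams()
        for _ in range(10):
            r1 = clump_residue("A", 1, rng.normal(0, 2, 3), 4)
            r2 = clump_residue("A", 5, rng.normal(0, 2, 3), 3)
            assert interaction_strength(r1, r2, params) == pytest.approx(
                interaction_strength(r2, r1, params)
            )

    def test_unknown_residue_type_rejected(self):
        r1 = single_atom_residue("A", 1, [0, 0, 0], name="XXX")
        with pytest.raises(NetworkError):
            interaction_strength(r1, r1, NetworkParams())


def brute_force_network(snapshot, params):
    """O(n^2) reference edge set built via per-pair interaction_strength."""
    residues = snapshot.residues
    edges = {}
    for i, ri in enumerate(residues):
        for rj in residues[i + 1 :]:
            if (
                ri.chain_id == rj.chain_id
                and abs(ri.number - rj.number) <= params.exclude_neighbors
            ):
                continue
            s = interaction_strength(ri, rj, params)
            if s >= params.i_min:
                key = tuple(sorted((ri.key, rj.key)))
                edges[key] = s
    return edges


class TestBuildNetwork:
    def test_matches_brute_force_oracle(self, toy_complex):
        params = NetworkParams(i_min=1.0)
        net = build_network(toy_complex, params)
        oracle = brute_force_network(toy_complex, params)
        assert set(net.edges) == set(oracle)
        for e, s in net.edges.items():
            assert s == pytest.approx(oracle[e])

    def test_planted_cross_chain_edge_present(self, toy_complex, toy_spec):
        net = build_network(toy_complex, NetworkParams(i_min=0.1))
        a, b = toy_spec.contact_pairs[0]
        assert (("A", a, ""), ("B", b, "")) in net.edges

    def test_imin_above_maximum_gives_empty_network(self, toy_complex):
        net = build_network(toy_complex, NetworkParams(i_min=99.0))
        assert net.edges == {}

    def test_edge_count_nonincreasing_in_imin(self, toy_complex):
        counts = [
            len(build_network(toy_complex, NetworkParams(i_min=v)).edges)
            for v in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


def union_find_largest(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    sizes = {}
    for n in nodes:
        root = find(n)
        sizes[root] = sizes.get(root, 0) + 1
    return max(sizes.values()) if sizes else 0


class TestClusterProfileAndImin:
    def test_profile_nonincreasing_and_matches_union_find(self):
        snap = generate_two_cluster_snapshot()
        params = NetworkParams(exclude_neighbors=0)
        profile = largest_cluster_profile(snap, params=params)
        sizes = [s for _, s in profile]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))
        for imin, size in profile:
            p = NetworkParams(exclude_neighbors=0, i_min=imin)
            net = build_network(snap, p)
            assert size == union_find_largest(net.nodes, list(net.edges))

    def test_grid_past_max_strength_gives_isolated_nodes(self):
        snap = generate_two_cluster_snapshot()
        profile = largest_cluster_profile(
            snap, i_min_grid=[50.0, 60.0], params=NetworkParams(exclude_neighbors=0)
        )
        assert [s for _, s in profile] == [1, 1]

    def test_maximal_drop_selected_first_on_ties(self):
        assert select_imin([(1, 50), (2, 48), (3, 20), (4, 19)]) == 3
        assert select_imin([(1, 50), (2, 30), (3, 29), (4, 9)]) == 2  # tie -> first

    def test_constant_profile_flags_no_transition(self):
        assert select_imin([(1, 10), (2, 10), (3, 10)]) is None

    def test_two_cluster_bridge_transition(self):
        snap = generate_two_cluster_snapshot()
        profile = largest_cluster_profile(snap, params=NetworkParams(exclude_neighbors=0))
        # the 2.1%-strength bridge breaks at the first grid point above it
        assert select_imin(profile) == pytest.approx(2.5)

    def test_invalid_grids_rejected(self, toy_complex):
        with pytest.raises(NetworkError):
            largest_cluster_profile(toy_complex, i_min_grid=[])
        with pytest.raises(NetworkError):
            largest_cluster_profile(toy_complex, i_min_grid=[2.0, 1.0])


class TestStableNetwork:
    def test_frequencies_match_per_frame_recount(self, toy_ensemble):
        params = NetworkParams(i_min=1.0)
        ens_net = stable_network(toy_ensemble, params)
        for edge, freq in ens_net.edge_frequency.items():
            count = sum(edge in net.edges for net in ens_net.per_frame)
            assert freq == pytest.approx(count / len(toy_ensemble))

    def test_persistent_edge_is_stable(self, toy_complex):
        ens = generate_ensemble(toy_complex, 10, noise_sd=0.0, seed=0)
        ens_net = stable_network(ens, NetworkParams(i_min=1.0))
        assert all(f == 1.0 for f in ens_net.edge_frequency.values())
        assert set(ens_net.stable_edges) == set(ens_net.edge_frequency)

    def test_half_time_edge_is_stable_at_inclusive_threshold(self, toy_complex, toy_spec):
        # 5/10 broken frames: cross-chain contacts exist in exactly half
        ens = generate_ensemble(toy_complex, 10, noise_sd=0.0, broken_fraction=0.5, seed=0)
        ens_net = stable_network(ens, NetworkParams(i_min=1.0), stability=0.5)
        a, b = toy_spec.contact_pairs[0]
        edge = (("A", a, ""), ("B", b, ""))
        assert ens_net.edge_frequency[edge] == pytest.approx(0.5)
        assert edge in ens_net.stable_edges  # inclusive >=

    def test_stable_sets_nest_across_thresholds(self, toy_ensemble):
        params = NetworkParams(i_min=1.0)
        loose = stable_network(toy_ensemble, params, stability=0.3)
        strict = stable_network(toy_ensemble, params, stability=0.8)
        assert set(strict.stable_edges) <= set(loose.stable_edges)


def network_from_graph(g: nx.Graph) -> ResidueNetwork:
    nodes = [("A", n, "") for n in g.nodes]
    edges = {
        tuple(sorted((("A", u, ""), ("A", v, "")))): 5.0 for u, v in g.edges
    }
    return ResidueNetwork(nodes=nodes, edges=edges, i_min=1.0)


class TestShortestPath:
    def test_line_graph(self):
        net = network_from_graph(nx.path_graph(5))
        path = shortest_path(net, ("A", 0, ""), ("A", 4, ""))
        assert [n[1] for n in path] == [0, 1, 2, 3, 4]

    def test_disconnected_returns_none(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        net = network_from_graph(g)
        assert shortest_path(net, ("A", 0, ""), ("A", 2, "")) is None

    def test_unknown_nodes_rejected(self):
        net = network_from_graph(nx.path_graph(3))
        with pytest.raises(KeyError):
            shortest_path(net, ("A", 0, ""), ("A", 99, ""))

    def test_lexicographic_tie_break(self):
        # diamond 0-1-3 / 0-2-3: both 2 hops; the smaller intermediate wins
        g = nx.Graph([(0, 1), (1, 3), (0, 2), (2, 3)])
        net = network_from_graph(g)
        path = shortest_path(net, ("A", 0, ""), ("A", 3, ""))
        assert [n[1] for n in path] == [0, 1, 3]

    def test_hop_counts_match_bfs_oracle_on_random_graphs(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, 0.15, seed=seed)
            net = network_from_graph(g)
            expected = dict(nx.all_pairs_shortest_path_length(g))
            for u in range(n):
                for v in range(n):
                    got = shortest_path(net, ("A", u, ""), ("A", v, ""))
                    if v in expected.get(u, {}):
                        assert got is not None
                        assert len(got) - 1 == expected[u][v]
                    else:
                        assert got is None

    def test_weighted_mode_prefers_strong_edges(self):
        # 0-1-3 over weak edges, 0-2-3 strong: weighted picks the strong route
        nodes = [("A", n, "") for n in range(4)]
        edges = {
            tuple(sorted((("A", 0, ""), ("A", 1, "")))): 1.0,
            tuple(sorted((("A", 1, ""), ("A", 3, "")))): 1.0,
            tuple(sorted((("A", 0, ""), ("A", 2, "")))): 10.0,
            tuple(sorted((("A", 2, ""), ("A", 3, "")))): 10.0,
        }
        net = ResidueNetwork(nodes=nodes, edges=edges, i_min=0.5)
        unweighted = shortest_path(net, ("A", 0, ""), ("A", 3, ""))
        weighted = shortest_path(net, ("A", 0, ""), ("A", 3, ""), weighted=True)
        assert [n[1] for n in unweighted] == [0, 1, 3]  # lexicographic tie-break
        assert [n[1] for n in weighted] == [0, 2, 3]


def hexagon_points(side=4.2):
    r = side  # circumradius equals side for a regular hexagon
    return [
        (r * np.cos(k * np.pi / 3), r * np.sin(k * np.pi / 3), 0.0) for k in range(6)
    ]


class TestEnsemblePaths:
    def test_identical_frames_average_equals_single_length(self, toy_complex):
        ens = generate_ensemble(toy_complex, 3, noise_sd=0.0, seed=0)
        params = NetworkParams(i_min=1.0)
        res = ensemble_paths(ens, ("A", 18, ""), ("A", 27, ""), params)
        single = shortest_path(
            build_network(toy_complex, params), ("A", 18, ""), ("A", 27, "")
        )
        assert res.average_length == pytest.approx(len(single) - 1)

    def test_average_over_frames_with_different_lengths(self):
        # frame 1: open chain of 6 (5 hops); frame 2: closed hexagon (1 hop)
        line = point_snapshot([(k * 4.2, 0.0, 0.0) for k in range(6)])
        ring = point_snapshot(hexagon_points())
        ens = Ensemble([line, ring])
        params = NetworkParams(i_min=0.5, exclude_neighbors=0)
        res = ensemble_paths(ens, ("A", 1, ""), ("A", 6, ""), params, stability=1.0)
        lengths = [len(p) - 1 for p in res.per_frame_paths]
        assert sorted(lengths) == [1, 5]
        assert res.average_length == pytest.approx(3.0)

    def test_planted_path_recovered_exactly(self, toy_complex, toy_spec):
        ens = generate_ensemble(toy_complex, 5, noise_sd=0.0, seed=0)
        res = ensemble_paths(
            ens, ("A", 18, ""), ("A", 27, ""), NetworkParams(i_min=1.0)
        )
        planted = [("A", p, "") for p in toy_spec.path_chain]
        for path in res.per_frame_paths:
            assert path == planted
        assert res.consensus_nodes == sorted(planted)
        assert res.stable_path == planted

    def test_no_path_reported_explicitly(self):
        far = point_snapshot([(0, 0, 0), (50, 0, 0)])
        ens = Ensemble([far])
        res = ensemble_paths(
            ens, ("A", 1, ""), ("A", 2, ""), NetworkParams(i_min=0.5, exclude_neighbors=0)
        )
        assert res.average_length is None
        assert res.per_frame_paths == [None]


class TestCommonPathResidues:
    def make_result(self, nodes):
        keys = [("A", n, "") for n in nodes]
        return PathResult(
            source=keys[0],
            sink=keys[-1],
            per_frame_paths=[keys],
            average_length=float(len(keys) - 1),
            consensus_nodes=sorted(keys),
        )

    def test_identical_paths_share_all_intermediates(self):
        r = self.make_result([1, 2, 3, 4])
        assert common_path_residues([r, r]) == {("A", 2, ""), ("A", 3, "")}

    def test_disjoint_paths_share_nothing(self):
        r1 = self.make_result([1, 2, 3])
        r2 = self.make_result([10, 11, 12])
        assert common_path_residues([r1, r2]) == set()

    def test_single_shared_intermediate(self):
        r1 = self.make_result([1, 7, 3])
        r2 = self.make_result([4, 7, 5])
        r3 = self.make_result([8, 7, 9])
        assert common_path_residues([r1, r2, r3]) == {("A", 7, "")}

    def test_requires_at_least_two(self):
        with pytest.raises(NetworkError):
            common_path_residues([self.make_result([1, 2, 3])])
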