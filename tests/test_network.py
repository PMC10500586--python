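"""Dynamic network model: contacts, correlations, weights, communities, paths."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import ensemblevs as ev
from ensemblevs.core import LIGAND_NODE, InputError, Structure, Trajectory
from ensemblevs.network import (
    NetworkConfig,
    build_network,
    contact_map,
    correlation_matrix,
    critical_nodes,
    detect_communities,
    optimal_path,
    path_overlap,
)


def _two_residue_traj(distance, n_frames=10, contact_frames=None):
    """Minimal 3-residue chain; residues 1 and 3 sit ``distance`` apart in
    ``contact_frames`` (all by default) and far apart otherwise."""
    atoms = pd.DataFrame(
        dict(res_id=[1, 2, 3], res_name=["ALA"] * 3, atom_name=["CA"] * 3,
             segment=["protein"] * 3, role=["apolar"] * 3, parent=[0, 1, 2])
    )
    base = np.array([[0.0, 0, 0], [50.0, 0, 0], [0.0, distance, 0]])
    coords = np.repeat(base[None], n_frames, axis=0)
    if contact_frames is not None:
        far = np.array([0.0, 30.0, 0.0])
        for f in range(n_frames):
            if f not in contact_frames:
                coords[f, 2] = far
    return Trajectory(Structure(atoms, base), coords)


class TestContactMap:
    def test_permanent_contact_present(self):
        adj = contact_map(_two_residue_traj(3.0))
        assert (1, 3) in adj["edges"]

    def test_persistence_threshold_semantics(self):
        # contact in 74% of frames: absent at 0.75, present at 0.70
        traj = _two_residue_traj(3.0, n_frames=100, contact_frames=set(range(74)))
        assert (1, 3) not in contact_map(traj, NetworkConfig(persistence=0.75))["edges"]
        assert (1, 3) in contact_map(traj, NetworkConfig(persistence=0.70))["edges"]
        # exactly 75%: >= semantics keeps the edge
        traj75 = _two_residue_traj(3.0, n_frames=100, contact_frames=set(range(75)))
        assert (1, 3) in contact_map(traj75, NetworkConfig(persistence=0.75))["edges"]

    def test_sequence_neighbors_excluded(self, block_traj):
        adj = contact_map(block_traj)
        for i, j in adj["edges"]:
            if isinstance(i, int) and isinstance(j, int):
                assert abs(i - j) > 1

    def test_matches_brute_force_distance_scan(self):
        spec = ev.ToyReceptorSpec(n_residues=10)
        s = ev.generate_reference_structure(spec, seed=6)
        planted = ev.PlantedStructure(
            substates=[(s.coords.copy(), 1.0)],
            correlation_blocks=ev.two_block_partition(s),
            block_coupling=0.5, noise_sd=0.2, ligand_block=0,
        )
        traj = ev.generate_trajectory(s, planted, 40, seed=8)
        cfg = NetworkConfig()
        adj = contact_map(traj, cfg)
        # independent O(n^2) per-frame scan
        atoms = traj.topology.atoms
        groups = {int(r): g.index.to_numpy()
                  for r, g in atoms[atoms["segment"] == "protein"].groupby("res_id")}
        groups[LIGAND_NODE] = atoms.index[atoms["segment"] == "ligand"].to_numpy()
        expected = {}
        keys = sorted(groups, key=str)
        for a, b in itertools.combinations(keys, 2):
            if isinstance(a, int) and isinstance(b, int) and abs(a - b) <= 1:
                continue
            hits = 0
            for f in range(traj.n_frames):
                dmin = min(
                    np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                    for i in groups[a] for j in groups[b]
                )
                hits += dmin <= cfg.contact_cutoff
            if hits / traj.n_frames >= cfg.persistence:
                expected[tuple(sorted((a, b), key=str))] = hits / traj.n_frames
        got = {tuple(sorted(k, key=str)): v for k, v in adj["edges"].items()}
        assert got == pytest.approx(expected)


class TestCorrelation:
    def test_diagonal_is_one(self, block_traj):
        _, c = correlation_matrix(block_traj)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_shared_and_opposed_drivers(self):
        # hand-built displacements: no superposition ambiguity (4 static
        # anchor residues pin the frame), nodes 5/6 share a driver, 7 opposes
        atoms = pd.DataFrame(
            dict(res_id=list(range(1, 8)), res_name=["ALA"] * 7,
                 atom_name=["CA"] * 7, segment=["protein"] * 7,
                 role=["apolar"] * 7, parent=list(range(7)))
        )
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                         [5, 5, 0], [5, 0, 5], [0, 5, 5]], dtype=float)
        rng = np.random.default_rng(3)
        z = rng.normal(size=30)
        coords = np.repeat(base[None], 30, axis=0)
        coords[:, 4, 0] += z
        coords[:, 5, 0] += z
        coords[:, 6, 0] -= z
        traj = Trajectory(Structure(atoms, base), coords)
        order, c = correlation_matrix(traj, None)
        i5, i6, i7 = order.index(5), order.index(6), order.index(7)
        assert c[i5, i6] > 0.99
        assert c[i5, i7] < -0.99

    def test_zero_variance_node_flagged(self):
        traj = _two_residue_traj(3.0, n_frames=10)
        with pytest.warns(UserWarning, match="zero-variance"):
            correlation_matrix(traj)


class TestWeights:
    def _graph(self, corr_values):
        order = list(range(1, len(corr_values) + 2))
        n = len(order)
        c = np.eye(n)
        adjacency = {"nodes": order, "edges": {}}
        for k, val in enumerate(corr_values):
            c[0, k + 1] = c[k + 1, 0] = val
            adjacency["edges"][(order[0], order[k + 1])] = 1.0
        return build_network(adjacency, order, c)

    def test_log_weight_values(self):
        g = self._graph([1.0, np.exp(-1.0)])
        assert g[1][2]["weight"] == pytest.approx(0.0)
        assert g[1][3]["weight"] == pytest.approx(1.0)

    def test_weight_monotone_in_correlation_magnitude(self):
        g = self._graph([0.9, 0.5, -0.9])
        assert g[1][2]["weight"] < g[1][3]["weight"]
        assert g[1][2]["weight"] == pytest.approx(g[1][4]["weight"])  # |C| symmetric
        assert all(d["weight"] >= 0 for _, _, d in g.edges(data=True))

    def test_zero_correlation_edge_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            g = self._graph([0.9, 1e-9])
        assert g.has_edge(1, 2) and not g.has_edge(1, 3)


class TestCommunities:
    def _weighted(self, edges):
        g = nx.Graph()
        for u, v, strength in edges:
            g.add_edge(u, v, strength=strength, weight=float(-np.log(strength)))
        return g

    def test_two_cliques_split_at_bridge(self):
        edges = [(a, b, 0.9) for a, b in itertools.combinations(range(4), 2)]
        edges += [(a, b, 0.9) for a, b in itertools.combinations(range(4, 8), 2)]
        edges += [(3, 4, 0.9)]
        g = self._weighted(edges)
        part = detect_communities(g)
        groups = {frozenset(v) for v in part.groups().values()}
        assert groups == {frozenset(range(4)), frozenset(range(4, 8))}
        # exhaustive check: no 2-subset split beats the returned modularity
        nodes = list(g)
        best = max(
            nx.community.modularity(g, [set(c), set(nodes) - set(c)], weight="strength")
            for r in range(1, 5)
            for c in itertools.combinations(nodes, r)
            if set(c) != set(nodes)
        )
        assert part.modularity >= best - 1e-12

    def test_uniform_complete_graph_stays_single_community(self):
        edges = [(a, b, 0.8) for a, b in itertools.combinations(range(6), 2)]
        part = detect_communities(self._weighted(edges))
        assert len(part.groups()) == 1
        assert part.critical_nodes == []

    def test_planted_blocks_recovered(self, block_traj):
        from sklearn.metrics import adjusted_rand_score

        net = ev.build_from_trajectory(block_traj)
        part = detect_communities(net)
        res = sorted(n for n in net if isinstance(n, int))
        half = res[len(res) // 2 - 1]
        truth = {n: (0 if isinstance(n, int) and n <= half else 1) for n in net}
        nodes = sorted(net, key=str)
        ari = adjusted_rand_score([truth[n] for n in nodes],
                                  [part.community[n] for n in nodes])
        assert ari >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            detect_communities(nx.Graph())


class TestCriticalNodes:
    def test_single_community_gives_empty_set(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=0.1, strength=0.9)
        assert critical_nodes(g, {1: 1, 2: 1}) == []

    def test_bridge_endpoints_only(self):
        g = nx.Graph()
        for u, v in [(1, 2), (2, 3), (4, 5), (5, 6), (3, 4)]:
            g.add_edge(u, v, weight=0.1, strength=0.9)
        comm = {n: (1 if n <= 3 else 2) for n in g}
        assert critical_nodes(g, comm) == [3, 4]

    def test_matches_edge_scan(self, block_traj):
        net = ev.build_from_trajectory(block_traj)
        part = detect_communities(net)
        expected = set()
        for u, v in net.edges:
            if part.community[u] != part.community[v]:
                expected |= {u, v}
        assert set(part.critical_nodes) == expected


class TestOptimalPath:
    def test_source_equals_target(self):
        g = nx.Graph()
        g.add_edge("LIG", 2, weight=1.0)
        p = optimal_path(g, "LIG", "LIG")
        assert p.found and p.nodes == ["LIG"] and p.total_weight == 0.0

    def test_two_hop_beats_heavy_direct_edge(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        g.add_edge(1, 3, weight=3.0)
        p = optimal_path(g, 1, 3)
        assert p.nodes == [1, 2, 3] and p.total_weight == pytest.approx(2.0)

    def test_disconnected_gives_no_path_result(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_node(3)
        p = optimal_path(g, 1, 3)
        assert not p.found and p.nodes == []

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.05, 3.0))
            s, t = 0, n - 1
            p = optimal_path(g, s, t)
            if not nx.has_path(g, s, t):
                assert not p.found
                continue
            best = min(
                sum(g[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
                for path in nx.all_simple_paths(g, s, t)
            )
            assert p.total_weight == pytest.approx(best)


class TestPathOverlap:
    def _p(self, nodes):
        return ev.SignalPath("s", "t", nodes, 0.0, True)

    def test_identical_paths_share_everything(self):
        a = self._p(["s", 1, 2, 3, "t"])
        assert path_overlap(a, a) == (3, 1.0)

    def test_disjoint_interiors(self):
        a = self._p(["s", 1, 2, "t"])
        b = self._p(["s", 5, 6, "t"])
        assert path_overlap(a, b) == (0, 0.0)

    def test_partial_overlap_fraction(self):
        a = self._p(["s", "A", "B", "C", "D", "t"])
        b = self._p(["s", "A", "C", "X", "Y", "t"])
        assert path_overlap(a, b) == (2, 0.5)

    def test_direct_paths_have_full_overlap(self):
        a = self._p(["s", "t"])
        assert path_overlap(a, a) == (0, 1.0)
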