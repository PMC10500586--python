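"""Weighted dynamic network model of a receptor-ligand trajectory.

Nodes are residues (placed at their alpha-carbons) plus one ligand node
(geometric center of the ligand heavy atoms).  An edge connects two nodes
whose heavy atoms come within a distance cutoff (default 4.5 Angstrom) in
at least a persistence fraction of frames (default 75%); sequence-adjacent
residues are excluded to avoid trivial backbone edges.  Edges are weighted

    w_ij = -log |C_ij|

where C_ij is the normalized displacement covariance of the two nodes over
the superposed trajectory, so strongly correlated pairs carry low weight
and transmit "signal" cheaply.  Communities come from a Girvan-Newman
edge-betweenness sweep (the modularity-maximal level); critical nodes are
the endpoints of inter-community edges; optimal signal-transduction paths
are minimum-total-weight paths from the ligand node to GPCR microswitch
residues (tyrosine toggle switch in the NPxxY motif, transmission switch
in CWxP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import LIGAND, LIGAND_NODE, PROTEIN, InputError, Trajectory
from .metrics import _fit_frames

#: edges with |C| below this are dropped (infinite weight) with a warning
MIN_ABS_CORRELATION = 1e-6


@dataclass
class NetworkConfig:
    contact_cutoff: float = 4.5
    persistence: float = 0.75
    exclude_neighbors: int = 1

    def validate(self) -> None:
        if self.contact_cutoff <= 0:
            raise InputError("contact_cutoff must be > 0")
        if not (0 < self.persistence <= 1):
            raise InputError("persistence must be in (0, 1]")


@dataclass
class SwitchDefinition:
    """Microswitch target residues for optimal-path analysis."""

    toggle_switch: int        # tyrosine toggle (NPxxY motif), e.g. Y318
    transmission_switch: int  # transmission switch (CWxP motif), e.g. S255


@dataclass
class CommunityPartition:
    community: dict            # node -> community id (1-based, largest first)
    critical_nodes: list
    modularity: float

    def groups(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, cid in self.community.items():
            out.setdefault(cid, []).append(node)
        return out


@dataclass
class SignalPath:
    """Minimum-weight path between two nodes; ``found`` is False when the
    endpoints are disconnected."""

    source: object
    target: object
    nodes: list = field(default_factory=list)
    total_weight: float = float("inf")
    found: bool = False

    @property
    def interior(self) -> list:
        return self.nodes[1:-1] if len(self.nodes) > 2 else []


def _node_key(node) -> tuple:
    """Deterministic sort key over mixed residue-int / ligand-str node ids."""
    if isinstance(node, (int, np.integer)):
        return (0, int(node), "")
    return (1, 0, str(node))


def _node_atom_indices(traj: Trajectory) -> dict:
    """Map node id -> heavy-atom indices (residues by id, ligand pooled)."""
    atoms = traj.topology.atoms
    nodes: dict = {}
    for rid, grp in atoms[atoms["segment"] == PROTEIN].groupby("res_id"):
        nodes[int(rid)] = grp.index.to_numpy()
    lig = atoms.index[atoms["segment"] == LIGAND].to_numpy()
    if len(lig):
        nodes[LIGAND_NODE] = lig
    for node, idx in nodes.items():
        if len(idx) == 0:
            raise InputError(f"node {node!r} has no heavy atoms")
    return nodes


# ---------------------------------------------------------------------------
# contacts and correlations
# ---------------------------------------------------------------------------

def contact_map(traj: Trajectory, cfg: NetworkConfig | None = None) -> dict:
    """Persistent-contact adjacency over node pairs.

    Edge (i, j) present iff the minimum heavy-atom distance between the two
    nodes' atom sets is <= ``contact_cutoff`` in at least ``persistence``
    of the frames.  Returns ``{"nodes": [...], "edges": {(i, j): fraction}}``
    with i < j under the deterministic node ordering.
    """
    cfg = cfg or NetworkConfig()
    cfg.validate()
    if traj.n_frames < 1:
        raise InputError("trajectory has no frames")
    nodes = _node_atom_indices(traj)
    order = sorted(nodes, key=_node_key)
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                ni, nj = order[a], order[b]
                if (
                    isinstance(ni, int) and isinstance(nj, int)
                    and abs(ni - nj) <= cfg.exclude_neighbors
                ):
                    continue
                xi = xyz[nodes[ni]]
                xj = xyz[nodes[nj]]
                d2 = np.sum((xi[:, None, :] - xj[None, :, :]) ** 2, axis=-1)
                if d2.min() <= cfg.contact_cutoff**2:
                    counts[(ni, nj)] = counts.get((ni, nj), 0) + 1
    nf = traj.n_frames
    edges = {pair: c / nf for pair, c in counts.items() if c / nf >= cfg.persistence}
    return {"nodes": order, "edges": edges}


def node_positions(traj: Trajectory, superpose_frames: bool = True) -> tuple[list, np.ndarray]:
    """Per-frame node coordinates: residue alpha-carbons, ligand center.

    Frames are superposed to the mean structure on the alpha-carbons first
    (two-pass) so node displacements are internal motions, not rigid-body
    drift.  Returns (ordered node ids, array (n_frames, n_nodes, 3)).
    """
    atoms = traj.topology.atoms
    coords = traj.coords
    if superpose_frames and traj.n_frames >= 2:
        fit_idx = traj.select("protein_ca")
        coords = _fit_frames(coords, coords[0], fit_idx)
        coords = _fit_frames(coords, coords.mean(axis=0), fit_idx)
    order = sorted(_node_atom_indices(traj), key=_node_key)
    pos = np.empty((coords.shape[0], len(order), 3))
    ca_mask = (atoms["segment"] == PROTEIN) & (atoms["atom_name"] == "CA")
    ca_of = {int(r): i for i, r in zip(atoms.index[ca_mask], atoms.loc[ca_mask, "res_id"])}
    lig_idx = atoms.index[atoms["segment"] == LIGAND].to_numpy()
    for k, node in enumerate(order):
        if node == LIGAND_NODE:
            pos[:, k] = coords[:, lig_idx].mean(axis=1)
        else:
            pos[:, k] = coords[:, ca_of[node]]
    return order, pos


def correlation_matrix(traj: Trajectory, cfg: NetworkConfig | None = None):
    """Normalized displacement covariance between node pairs.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the node
    displacement from its trajectory mean, frames superposed to the mean
    structure first.  Zero-variance nodes get C = 0 off-diagonal with a
    warning (their edges are later dropped).

    Returns (ordered node ids, C matrix).
    """
    if traj.n_frames < 2:
        raise InputError("correlations require at least 2 frames")
    order, pos = node_positions(traj)
    d = pos - pos.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", d, d) / traj.n_frames
    var = np.diag(cov).copy()
    dead = var <= 1e-24
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance node(s); their correlations are set to 0",
            stacklevel=2,
        )
        var[dead] = 1.0
    c = cov / np.sqrt(np.outer(var, var))
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    return order, np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(adjacency: dict, order: list, c: np.ndarray) -> nx.Graph:
    """Assemble the weighted graph: w = -log|C| (natural log) on contact edges.

    Edge attributes: ``corr`` (signed C), ``strength`` (|C|), ``weight``
    (w, nonnegative).  Edges with |C| < 1e-6 are dropped with a warning
    rather than carrying effectively infinite weight.
    """
    index = {node: k for k, node in enumerate(order)}
    g = nx.Graph(log_base="e")
    g.add_nodes_from(order)
    dropped = 0
    for (ni, nj), fraction in adjacency["edges"].items():
        cij = float(c[index[ni], index[nj]])
        if abs(cij) < MIN_ABS_CORRELATION:
            dropped += 1
            continue
        g.add_edge(ni, nj, corr=cij, strength=abs(cij),
                   weight=float(-np.log(abs(cij))), persistence=fraction)
    if dropped:
        warnings.warn(f"dropped {dropped} edge(s) with |C| < {MIN_ABS_CORRELATION}",
                      stacklevel=2)
    return g


# ---------------------------------------------------------------------------
# communities, critical nodes, paths
# ---------------------------------------------------------------------------

def _components_partition(g: nx.Graph) -> list[frozenset]:
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(_node_key(n) for n in c)))


def detect_communities(net: nx.Graph) -> CommunityPartition:
    """Girvan-Newman sweep with deterministic tie-breaking.

    Edges are removed in order of decreasing weighted edge betweenness
    (distance = w); among all partition levels of the sweep (including the
    initial connected components) the one maximizing modularity — computed
    with |C| edge strengths — is returned.  Ties prefer fewer communities.
    """
    if net.number_of_edges() == 0:
        raise InputError("network has no edges")
    work = net.copy()
    levels = [_components_partition(work)]
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, weight="weight")
        # among equal-betweenness edges the lexicographically smallest wins
        top = max(eb.values())
        candidates = [e for e, v in eb.items() if abs(v - top) <= 1e-12]
        best_edge = min(candidates, key=lambda e: sorted((_node_key(e[0]), _node_key(e[1]))))
        work.remove_edge(*best_edge)
        comps = _components_partition(work)
        if len(comps) > len(levels[-1]):
            levels.append(comps)
    scores = [nx.community.modularity(net, level, weight="strength") for level in levels]
    best = int(np.argmax(np.array(scores) - 1e-12 * np.arange(len(scores))))
    # argmax takes the earliest (coarsest) level on exact ties
    partition = levels[best]
    community = {}
    for cid, comp in enumerate(partition, start=1):
        for node in comp:
            community[node] = cid
    crit = critical_nodes(net, community)
    return CommunityPartition(community=community, critical_nodes=crit,
                              modularity=float(scores[best]))


def critical_nodes(net: nx.Graph, partition: CommunityPartition | dict) -> list:
    """Nodes incident to at least one inter-community edge."""
    comm = partition.community if isinstance(partition, CommunityPartition) else partition
    crit = {
        n for u, v in net.edges if comm[u] != comm[v] for n in (u, v)
    }
    return sorted(crit, key=_node_key)


def optimal_path(net: nx.Graph, source, target) -> SignalPath:
    """Minimum total-weight path (Dijkstra); lexicographic tie-breaking.

    Returns a no-path :class:`SignalPath` (``found=False``) when the nodes
    are disconnected, rather than raising.
    """
    for node in (source, target):
        if node not in net:
            raise InputError(f"node {node!r} not in network")
    if source == target:
        return SignalPath(source, target, [source], 0.0, True)
    try:
        paths = list(nx.all_shortest_paths(net, source, target, weight="weight"))
    except nx.NetworkXNoPath:
        return SignalPath(source, target, [], float("inf"), False)
    best = min(paths, key=lambda p: [_node_key(n) for n in p])
    total = float(
        sum(net[u][v]["weight"] for u, v in zip(best[:-1], best[1:]))
    )
    return SignalPath(source, target, list(best), total, True)


def path_overlap(path_a: SignalPath, path_b: SignalPath) -> tuple[int, float]:
    """Shared interior residues between two paths.

    Returns (count of common interior nodes, fraction of path_a's interior
    shared).  Source and target are excluded.  Two paths with identical
    (possibly empty) interiors have fraction 1.
    """
    ia, ib = set(path_a.interior), set(path_b.interior)
    shared = len(ia & ib)
    if not ia:
        return shared, 1.0 if ib == ia else 0.0
    return shared, shared / len(ia)


def build_from_trajectory(traj: Trajectory, cfg: NetworkConfig | None = None) -> nx.Graph:
    """Convenience: contact map + correlations + weighted graph in one call."""
    cfg = cfg or NetworkConfig()
    adjacency = contact_map(traj, cfg)
    order, c = correlation_matrix(traj, cfg)
    return build_network(adjacency, order, c)
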