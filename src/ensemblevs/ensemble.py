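"""Representative conformations and collective motion.

Two complementary views of a receptor ensemble:

* **RMSD hierarchical clustering** — an average-linkage agglomerative tree
  over the superposed backbone-RMSD matrix, cut at a merging distance
  (default 2 Angstrom); clusters below an abundance floor (default 2% of
  frames) are dropped from reporting but kept in the assignments.  Each
  cluster is represented by its *centroid* frame, the member with the most
  same-cluster neighbors within a cutoff.
* **Elastic-network normal modes** — an anisotropic network model on the
  alpha-carbons (uniform springs within a cutoff, default 15 Angstrom);
  the six rigid-body modes are discarded and the lowest nontrivial modes
  returned, approximating the dominant collective motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
from scipy.spatial.distance import squareform

from .core import InputError, Structure, Trajectory
from .metrics import superpose


@dataclass
class ClusterSet:
    """Partition of frames with abundances and centroid frames.

    Cluster ids are assigned in order of decreasing abundance (ties broken
    by the lowest member frame index).  ``reported`` lists the ids at or
    above the abundance floor; ``assignments`` always covers every frame.
    """

    assignments: np.ndarray
    abundances: dict[int, float]
    centroids: dict[int, int]
    merge_cutoff: float
    abundance_floor: float
    reported: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.abundances)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)


@dataclass
class ModeSet:
    """Low-frequency elastic-network modes, eigenvalues ascending."""

    eigenvalues: np.ndarray           # (n_reported,) nontrivial eigenvalues
    mode_vectors: np.ndarray          # (n_reported, n_nodes, 3) orthonormal
    rigid_eigenvalues: np.ndarray     # the 6 near-zero eigenvalues
    spring_cutoff: float


# ---------------------------------------------------------------------------
# pairwise RMSD
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(traj: Trajectory, selection: str = "backbone") -> np.ndarray:
    """Symmetric matrix of superposed backbone RMSDs between all frame pairs.

    Uses a batched Kabsch evaluation (SVD of stacked 3x3 cross-covariance
    matrices), equivalent pair-by-pair to :func:`ensemblevs.metrics.superpose`.
    """
    idx = traj.select(selection)
    if len(idx) == 0:
        raise InputError(f"empty selection {selection!r}")
    nf = traj.n_frames
    if nf < 2:
        raise InputError("at least 2 frames required")
    x = traj.coords[:, idx, :]
    x = x - x.mean(axis=1, keepdims=True)
    g = np.sum(x * x, axis=(1, 2))
    n = len(idx)
    mat = np.zeros((nf, nf))
    for i in range(nf - 1):
        h = np.einsum("ak,jal->jkl", x[i], x[i + 1:])
        s = np.linalg.svd(h, compute_uv=False)
        dets = np.linalg.det(h)
        ssum = s[:, 0] + s[:, 1] + np.where(dets < 0, -s[:, 2], s[:, 2])
        msd = (g[i] + g[i + 1:] - 2.0 * ssum) / n
        mat[i, i + 1:] = np.sqrt(np.maximum(msd, 0.0))
    mat = mat + mat.T
    return mat


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_trajectory(
    matrix: np.ndarray,
    merge_cutoff: float = 2.0,
    abundance_floor: float = 0.02,
    linkage: str = "average",
    neighbor_cutoff: float | None = None,
) -> ClusterSet:
    """Average-linkage agglomerative clustering of the RMSD matrix.

    The tree is cut at ``merge_cutoff``; abundances are fractions of all
    frames; clusters below ``abundance_floor`` are excluded from
    ``reported`` only.  ``neighbor_cutoff`` for centroid selection defaults
    to the merge cutoff.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InputError("RMSD matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise InputError("RMSD matrix must be symmetric")
    if merge_cutoff <= 0:
        raise InputError("merge_cutoff must be > 0")
    nf = matrix.shape[0]
    z = sch.linkage(squareform(matrix, checks=False), method=linkage)
    raw = sch.fcluster(z, t=merge_cutoff, criterion="distance")
    # relabel by decreasing abundance, ties by lowest member frame index
    ids, counts = np.unique(raw, return_counts=True)
    first = {c: int(np.flatnonzero(raw == c)[0]) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first[c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    assignments = np.array([remap[c] for c in raw])
    abundances = {remap[c]: counts[list(ids).index(c)] / nf for c in ids}
    ncut = merge_cutoff if neighbor_cutoff is None else neighbor_cutoff
    centroids = {
        cid: centroid_frame(np.flatnonzero(assignments == cid), matrix, ncut)
        for cid in abundances
    }
    reported = [c for c in sorted(abundances) if abundances[c] >= abundance_floor]
    return ClusterSet(
        assignments=assignments, abundances=abundances, centroids=centroids,
        merge_cutoff=merge_cutoff, abundance_floor=abundance_floor, reported=reported,
    )


def centroid_frame(members: np.ndarray, matrix: np.ndarray, neighbor_cutoff: float) -> int:
    """Member frame with the most same-cluster neighbors within the cutoff.

    Ties break toward the lowest frame index.
    """
    members = np.asarray(members, dtype=int)
    if len(members) == 0:
        raise InputError("cluster has no members")
    sub = matrix[np.ix_(members, members)]
    counts = np.sum(sub <= neighbor_cutoff, axis=1) - 1  # exclude self
    best = int(np.argmax(counts))  # argmax returns first (lowest-index) max
    return int(members[best])


# ---------------------------------------------------------------------------
# elastic network modes
# ---------------------------------------------------------------------------

def elastic_network_modes(
    structure: Structure,
    spring_cutoff: float = 15.0,
    n_modes: int = 10,
    selection: str = "protein_ca",
) -> ModeSet:
    """Anisotropic elastic-network normal modes on the alpha-carbons.

    Builds the 3N x 3N Hessian with uniform unit springs between nodes
    within ``spring_cutoff``, discards the 6 rigid-body modes and returns
    the lowest ``n_modes`` nontrivial ones (eigenvalues ascending,
    orthonormal eigenvectors).
    """
    idx = structure.select(selection)
    xyz = structure.coords[idx]
    n = len(xyz)
    if n < 2:
        raise InputError("at least 2 nodes required")
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist <= spring_cutoff) & ~np.eye(n, dtype=bool)
    ncomp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(contact.astype(int))
    )
    if ncomp != 1:
        raise InputError(
            f"elastic network disconnected at cutoff {spring_cutoff} A "
            f"({ncomp} components); increase spring_cutoff"
        )
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            if j <= i:
                continue
            d = diff[i, j]
            block = -np.outer(d, d) / (dist[i, j] ** 2)
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    evals, evecs = scipy.linalg.eigh(hess)
    tol = 1e-8 * max(evals[-1], 1.0)
    # 6 rigid-body modes for any non-collinear 3-D network (5 for a dimer)
    n_rigid = int(np.sum(evals < tol))
    k = min(n_modes, 3 * n - n_rigid)
    sel = slice(n_rigid, n_rigid + k)
    vectors = evecs[:, sel].T.reshape(k, n, 3)
    return ModeSet(
        eigenvalues=evals[sel].copy(),
        mode_vectors=vectors,
        rigid_eigenvalues=evals[:n_rigid].copy(),
        spring_cutoff=spring_cutoff,
    )


def harmonic_energy(structure: Structure, displaced: np.ndarray,
                    spring_cutoff: float = 15.0, selection: str = "protein_ca") -> float:
    """Elastic-network energy of a displaced configuration (unit springs).

    Exposed so a finite-difference Hessian can serve as an independent
    check of :func:`elastic_network_modes`.
    """
    idx = structure.select(selection)
    ref = structure.coords[idx]
    dist0 = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    contact = (dist0 <= spring_cutoff) & ~np.eye(len(ref), dtype=bool)
    dist = np.linalg.norm(displaced[:, None] - displaced[None, :], axis=-1)
    return float(0.25 * np.sum(contact * (dist - dist0) ** 2))  # 1/2 k, pairs twice
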