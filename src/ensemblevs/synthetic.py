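"""Synthetic receptor-ligand trajectories and screening tables.

Every downstream stage of the pipeline (metrics, clustering, network
analysis, contact profiling, screening triage) is exercised on data produced
here, with *planted* statistical structure whose recovery the tests check:

* metastable conformational substates with prescribed occupancies
  (e.g. 75% / 25%), built as smooth low-rank deformations of an idealized
  helical chain so that substates separate cleanly under an RMSD cutoff;
* blocks of residues sharing a latent displacement driver, giving
  within-block displacement correlations that exceed between-block ones —
  the ground truth for community detection;
* screening tables whose per-gate pass fractions are drawn per compound,
  and whose MM-GBSA component terms sum exactly to the planted total.

The chain is an idealized alpha-helix of labelled points (3.8 Angstrom
consecutive alpha-carbon spacing); there is no side-chain chemistry, no
force field and no integrator — the analyses only require labelled
coordinates with realistic contact topology (side-chain pseudo-atoms are
tilted along the helix axis so i/i+3 and i/i+4 contacts exist, as in a real
helix).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    LIGAND,
    PROTEIN,
    WATER,
    ConfigurationError,
    Structure,
    Trajectory,
)

# helix geometry: radius and twist chosen so consecutive CA spacing is 3.8 A
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)
_CA_SPACING = 3.8
_HELIX_RISE = float(np.sqrt(_CA_SPACING**2 - (2 * _HELIX_RADIUS * np.sin(_HELIX_TURN / 2)) ** 2))

# residue "chemistry": a repeating motif of side-chain role patterns so the
# interaction profiler sees donors, acceptors and charges of both signs
_RESIDUE_MOTIF = (
    ("ALA", ("apolar",)),
    ("SER", ("donor", "acceptor")),
    ("ASP", ("acceptor", "anion")),
    ("LEU", ("apolar", "apolar")),
    ("LYS", ("donor", "cation")),
    ("THR", ("acceptor", "donor")),
    ("PHE", ("apolar", "apolar")),
    ("ASN", ("donor", "acceptor")),
)

_LIGAND_ROLES = ("donor", "acceptor", "apolar", "apolar", "cation", "acceptor", "apolar", "donor")


@dataclass
class ToyReceptorSpec:
    """Geometry of the toy receptor-ligand system.

    ``atoms_per_residue`` includes the alpha-carbon (always the first atom of
    each residue).  ``anchor_residue`` is the residue the ligand is placed
    against (1-based; default mid-chain).
    """

    n_residues: int
    atoms_per_residue: int = 3
    ligand_atoms: int = 8
    include_waters: bool = False
    n_waters: int = 4
    anchor_residue: int | None = None

    def validate(self) -> None:
        if self.n_residues < 4:
            raise ConfigurationError("n_residues must be >= 4")
        if self.atoms_per_residue < 1:
            raise ConfigurationError("atoms_per_residue must be >= 1")
        if self.ligand_atoms < 1:
            raise ConfigurationError("ligand_atoms must be >= 1")
        if self.include_waters and self.n_waters < 1:
            raise ConfigurationError("n_waters must be >= 1 when waters are enabled")
        anchor = self.anchor_residue
        if anchor is not None and not (2 <= anchor <= self.n_residues - 1):
            raise ConfigurationError("anchor_residue must be an interior residue")


@dataclass
class PlantedStructure:
    """Planted statistical structure for :func:`generate_trajectory`.

    ``substates`` maps conformer coordinate arrays to occupancy fractions;
    ``correlation_blocks`` partitions protein residue ids into groups that
    share a latent displacement driver of strength ``block_coupling``
    (Angstrom scale of the shared displacement).  The ligand (and any
    waters) move with block ``ligand_block``.
    """

    substates: list[tuple[np.ndarray, float]]
    correlation_blocks: list[list[int]]
    block_coupling: float = 0.9
    noise_sd: float = 0.1
    ligand_block: int = 0

    def validate(self, structure: Structure) -> None:
        occ = np.array([f for _, f in self.substates], dtype=float)
        if len(occ) == 0:
            raise ConfigurationError("at least one substate required")
        if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-9:
            raise ConfigurationError("substate occupancies must be >= 0 and sum to 1")
        for conf, _ in self.substates:
            if np.asarray(conf).shape != structure.coords.shape:
                raise ConfigurationError("substate conformer shape mismatch")
        res_ids = structure.residue_ids()
        seen: set[int] = set()
        for block in self.correlation_blocks:
            for r in block:
                if r in seen:
                    raise ConfigurationError(f"residue {r} in more than one block")
                seen.add(r)
        if seen != set(int(r) for r in res_ids):
            raise ConfigurationError("correlation blocks must partition the residues")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not (0 < self.block_coupling <= 1):
            raise ConfigurationError("block_coupling must be in (0, 1]")
        if not (0 <= self.ligand_block < len(self.correlation_blocks)):
            raise ConfigurationError("ligand_block out of range")


@dataclass
class ScreeningTableSpec:
    """Planted distributions for a synthetic compound table."""

    n_compounds: int
    score_mean: float = -7.5
    score_sd: float = 1.5
    docking_cutoff: float = -8.6
    mmgbsa_cutoff: float = -90.2
    fraction_passing: dict = field(
        default_factory=lambda: {
            "docking": 0.5,
            "stars": 0.5,
            "mmgbsa": 0.5,
            "gi": 0.5,
            "bbb": 0.5,
            "alerts": 0.5,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ConfigurationError("n_compounds must be >= 0")
        for key, frac in self.fraction_passing.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"fraction_passing[{key!r}] must be in [0, 1]")


# ---------------------------------------------------------------------------
# reference structure
# ---------------------------------------------------------------------------

def _helix_ca(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = i * _HELIX_TURN
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(phi), _HELIX_RADIUS * np.sin(phi), i * _HELIX_RISE]
    )


def generate_reference_structure(spec: ToyReceptorSpec, seed: int) -> Structure:
    """Build the labelled reference conformer.

    Deterministic for a fixed seed.  The ligand is a compact blob placed
    against the outer face of the anchor residue and is guaranteed to have
    heavy atoms within 4.5 Angstrom of at least three residues.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    ca = _helix_ca(n)
    axis_points = np.column_stack([np.zeros(n), np.zeros(n), ca[:, 2]])
    outward = ca - axis_points
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    # side chains pack against the i+3/i+4 turn above (below, near the
    # C-terminus), giving the deep i/i+3 and i/i+4 contacts of a real helix
    side_dir = np.empty_like(ca)
    for i in range(n):
        if i + 4 < n:
            target = 0.5 * (ca[i + 3] + ca[i + 4])
        else:
            target = 0.5 * (ca[i - 3] + ca[i - 4])
        v = target - ca[i]
        side_dir[i] = v / np.linalg.norm(v)

    rows: list[dict] = []
    coords: list[np.ndarray] = []
    for i in range(n):
        res_name, side_roles = _RESIDUE_MOTIF[i % len(_RESIDUE_MOTIF)]
        ca_index = len(rows)
        rows.append(
            dict(res_id=i + 1, res_name=res_name, atom_name="CA",
                 segment=PROTEIN, role="apolar", parent=ca_index)
        )
        coords.append(ca[i])
        prev = ca_index
        for j in range(spec.atoms_per_residue - 1):
            role = side_roles[j % len(side_roles)]
            jitter = rng.normal(0.0, 0.1, size=3)
            pos = ca[i] + (1.8 + 1.5 * j) * side_dir[i] + jitter
            rows.append(
                dict(res_id=i + 1, res_name=res_name, atom_name=f"S{j + 1}",
                     segment=PROTEIN, role=role, parent=prev)
            )
            coords.append(pos)
            prev = len(rows) - 1

    anchor = spec.anchor_residue or max(2, n // 2)
    center = ca[anchor - 2:anchor + 1].mean(axis=0) + 2.0 * outward[anchor - 1]
    lig_start = len(rows)
    for j in range(spec.ligand_atoms):
        offset = rng.normal(0.0, 0.7, size=3)
        norm = np.linalg.norm(offset)
        if norm > 1.5:
            offset *= 1.5 / norm
        rows.append(
            dict(res_id=0, res_name="LIG", atom_name=f"L{j + 1}", segment=LIGAND,
                 role=_LIGAND_ROLES[j % len(_LIGAND_ROLES)],
                 parent=lig_start + (j - 1 if j > 0 else 1 if spec.ligand_atoms > 1 else 0))
        )
        coords.append(center + offset)

    if spec.include_waters:
        lig_coords = np.asarray(coords[lig_start:])
        for w in range(spec.n_waters):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = lig_coords.mean(axis=0) + (3.0 + 0.4 * rng.random()) * direction
            idx = len(rows)
            rows.append(
                dict(res_id=-(w + 1), res_name="HOH", atom_name="O", segment=WATER,
                     role="water", parent=idx)
            )
            coords.append(pos)

    structure = Structure(pd.DataFrame(rows), np.asarray(coords))
    assert _ligand_contact_count(structure) >= 3, "ligand placement failed contact check"
    return structure


def _ligand_contact_count(structure: Structure, cutoff: float = 4.5) -> int:
    lig = structure.coords[structure.select("ligand_heavy")]
    prot = structure.atoms[structure.atoms["segment"] == PROTEIN]
    count = 0
    for _, grp in structure.atoms.groupby("res_id"):
        if grp["segment"].iloc[0] != PROTEIN:
            continue
        xyz = structure.coords[grp.index.to_numpy()]
        d = np.linalg.norm(xyz[:, None, :] - lig[None, :, :], axis=-1)
        if d.min() <= cutoff:
            count += 1
    return count


# ---------------------------------------------------------------------------
# substate conformers
# ---------------------------------------------------------------------------

def _deformation_field(structure: Structure, order: int) -> np.ndarray:
    """Smooth low-rank per-atom displacement field (unit RMS over CA)."""
    res_ids = structure.atoms["res_id"].to_numpy()
    prot_ids = structure.residue_ids()
    n = len(prot_ids)
    axis = np.zeros(3)
    axis[(order - 1) % 3] = 1.0
    amp_by_res = {int(r): float(np.sin(order * np.pi * (k + 1) / (n + 1)))
                  for k, r in enumerate(prot_ids)}
    # ligand and waters ride with the anchor region: use the mean amplitude of
    # the residues nearest the ligand centroid
    lig_idx = structure.select("ligand_heavy")
    lig_center = structure.coords[lig_idx].mean(axis=0)
    ca_idx = structure.select("protein_ca")
    d = np.linalg.norm(structure.coords[ca_idx] - lig_center, axis=1)
    near = np.argsort(d)[:3]
    lig_amp = float(np.mean([amp_by_res[int(structure.atoms["res_id"].iloc[ca_idx[k]])]
                             for k in near]))
    field = np.zeros_like(structure.coords)
    for i, rid in enumerate(res_ids):
        amp = amp_by_res.get(int(rid), lig_amp)
        field[i] = amp * axis
    rms = float(np.sqrt(np.mean(np.sum(field[ca_idx] ** 2, axis=1))))
    return field / rms


def make_substates(
    structure: Structure,
    occupancies: list[float],
    separation: float = 5.0,
    seed: int = 0,
) -> list[tuple[np.ndarray, float]]:
    """Build substate conformers with pairwise CA RMSD close to ``separation``.

    The first substate is the reference conformer itself; subsequent ones are
    smooth orthogonal deformations scaled (iteratively, since superposition
    absorbs part of any displacement field) to the requested separation.
    """
    from .metrics import superpose

    if len(occupancies) < 1:
        raise ConfigurationError("at least one occupancy required")
    ca_idx = structure.select("protein_ca")
    conformers = [structure.coords.copy()]
    for k in range(1, len(occupancies)):
        fld = _deformation_field(structure, order=k)
        amp = separation
        conf = structure.coords + amp * fld
        for _ in range(4):  # rescale: superposed RMSD < raw RMS displacement
            _, _, r = superpose(conf[ca_idx], structure.coords[ca_idx])
            if abs(r - separation) < 0.05 * separation:
                break
            amp *= separation / max(r, 1e-9)
            conf = structure.coords + amp * fld
        conformers.append(conf)
    return list(zip(conformers, occupancies))


def two_block_partition(structure: Structure) -> list[list[int]]:
    """Split the chain into first/second-half correlation blocks."""
    res_ids = [int(r) for r in structure.residue_ids()]
    half = len(res_ids) // 2
    return [res_ids[:half], res_ids[half:]]


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def generate_trajectory(
    structure: Structure,
    planted: PlantedStructure,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Sample frames from planted substates with block-correlated displacement.

    Per frame: a substate conformer is drawn with the planted occupancies;
    each correlation block is displaced by a shared scalar latent times a
    fixed internal pattern (half the block's residues move +1, half -1
    along a per-block axis, scaled by ``block_coupling`` Angstrom), and
    every atom then receives independent isotropic noise of ``noise_sd``
    Angstrom.  The zero-mean pattern keeps block motion *internal* — a
    uniform block translation would be largely absorbed (and mixed across
    blocks) by the rigid superposition that precedes correlation analysis.
    The ligand (and waters) move with the full +1 amplitude of
    ``ligand_block``.  Frame-level substate labels are retained as
    ground-truth metadata.
    """
    if n_frames < 10:
        raise ConfigurationError("n_frames must be >= 10")
    planted.validate(structure)
    rng = np.random.default_rng(seed)
    occ = np.array([f for _, f in planted.substates], dtype=float)
    labels = rng.choice(len(occ), size=n_frames, p=occ)

    res_ids = structure.atoms["res_id"].to_numpy()
    seg = structure.atoms["segment"].to_numpy()
    n_blocks = len(planted.correlation_blocks)
    block_of_res: dict[int, int] = {}
    sign_of_res: dict[int, float] = {}
    for b, block in enumerate(planted.correlation_blocks):
        half = (len(block) + 1) // 2
        for k, r in enumerate(block):
            block_of_res[int(r)] = b
            sign_of_res[int(r)] = 1.0 if k < half else -1.0
    axes = np.eye(3)
    # per-atom displacement direction (axis of its block, signed pattern)
    pattern = np.zeros((structure.n_atoms, 3))
    atom_block = np.zeros(structure.n_atoms, dtype=int)
    for i in range(structure.n_atoms):
        if seg[i] == PROTEIN:
            b = block_of_res[int(res_ids[i])]
            sign = sign_of_res[int(res_ids[i])]
        else:
            b, sign = planted.ligand_block, 1.0
        atom_block[i] = b
        pattern[i] = sign * axes[b % 3]

    latents = rng.standard_normal((n_frames, n_blocks)) * planted.block_coupling
    noise = rng.normal(0.0, planted.noise_sd, size=(n_frames, structure.n_atoms, 3))

    frames = np.empty((n_frames, structure.n_atoms, 3))
    conformers = [np.asarray(c) for c, _ in planted.substates]
    for f in range(n_frames):
        frames[f] = (
            conformers[labels[f]]
            + latents[f, atom_block][:, None] * pattern
            + noise[f]
        )
    return Trajectory(structure, frames, substate_labels=labels)


# ---------------------------------------------------------------------------
# screening table
# ---------------------------------------------------------------------------

#: column order of synthetic and bundled compound tables
TABLE_COLUMNS = [
    "compound_id", "docking_score", "vdw", "gbele", "sur",
    "conf_receptor", "conf_ligand", "mmgbsa_total",
    "mw", "hbd", "hba", "logp",
    "gi_absorption", "bbb_permeant", "pains_alerts", "brenk_alerts",
]


def generate_screening_table(spec: ScreeningTableSpec) -> pd.DataFrame:
    """Synthesize a per-compound screening table with planted gate outcomes.

    The four MM-GBSA component terms always sum exactly to the planted
    total.  Pass/fail for each triage gate is drawn per compound from
    ``fraction_passing``, with property values placed on the corresponding
    side of the planted cutoffs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    fp = spec.fraction_passing
    for k in range(spec.n_compounds):
        passes = {gate: rng.random() < frac for gate, frac in fp.items()}
        margin = abs(rng.normal(0.8, 0.4)) + 0.05
        dock = spec.docking_cutoff - margin if passes.get("docking", True) else spec.docking_cutoff + margin
        gmargin = abs(rng.normal(8.0, 4.0)) + 0.5
        total = spec.mmgbsa_cutoff - gmargin if passes.get("mmgbsa", True) else spec.mmgbsa_cutoff + gmargin
        # split total into components: conf terms small, rest partitioned
        conf_r = rng.normal(0.0, 1.5)
        conf_l = rng.normal(0.0, 1.0)
        interaction = total - conf_r - conf_l
        w = rng.dirichlet([4.0, 2.0, 3.0])
        vdw, gbele, sur = (interaction * w).tolist()
        if passes.get("stars", True):
            mw = rng.uniform(250, 480)
            logp = rng.uniform(0.5, 4.5)
            hbd, hba = int(rng.integers(0, 5)), int(rng.integers(1, 10))
        else:
            mw = rng.uniform(520, 750)
            logp = rng.uniform(5.2, 8.0)
            hbd, hba = int(rng.integers(6, 9)), int(rng.integers(11, 15))
        gi = "high" if passes.get("gi", True) else "low"
        bbb = "yes" if passes.get("bbb", True) else "no"
        pains = 0 if passes.get("alerts", True) else int(rng.integers(1, 3))
        brenk = 0 if passes.get("alerts", True) else int(rng.integers(1, 3))
        rows.append(
            dict(compound_id=f"CMPD{k + 1:05d}", docking_score=round(dock, 2),
                 vdw=vdw, gbele=gbele, sur=sur, conf_receptor=conf_r, conf_ligand=conf_l,
                 mmgbsa_total=total, mw=round(mw, 1), hbd=hbd, hba=hba, logp=round(logp, 2),
                 gi_absorption=gi, bbb_permeant=bbb, pains_alerts=pains, brenk_alerts=brenk)
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
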