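"""Shared containers: labelled structures, trajectories, and error types.

The analyses in this package operate on *labelled point clouds*: every atom
carries a residue id, a segment (protein / ligand / water), and a chemical
role used by the interaction profiler (hydrogen-bond donor or acceptor,
apolar carbon, formal charge carrier, water oxygen).  Nothing downstream
requires force-field atom types, so the containers stay deliberately thin —
a pandas table of atom labels plus a coordinate array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN = "protein"
LIGAND = "ligand"
WATER = "water"

#: chemical roles understood by the interaction profiler
ROLES = ("apolar", "donor", "acceptor", "cation", "anion", "water")

#: networkx node id used for the ligand node in dynamic network models
LIGAND_NODE = "LIG"

ATOM_COLUMNS = ("res_id", "res_name", "atom_name", "segment", "role", "parent")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid specification or parameter set."""


class DegenerateGeometryError(ValueError):
    """Geometry insufficient for the requested operation (e.g. collinear)."""


@dataclass
class Structure:
    """A labelled single-conformer structure.

    Parameters
    ----------
    atoms:
        One row per atom with columns ``res_id`` (int; 0 for the ligand,
        negative for waters), ``res_name``, ``atom_name``, ``segment``
        (``protein`` / ``ligand`` / ``water``), ``role`` (see :data:`ROLES`)
        and ``parent`` (index of the bonded antecedent atom, used for
        hydrogen-bond donor angles; an atom may be its own parent).
    coords:
        ``(n_atoms, 3)`` Cartesian coordinates in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"coords must be (n_atoms, 3), got {self.coords.shape}")
        if len(self.atoms) != len(self.coords):
            raise InputError(
                f"{len(self.atoms)} atom labels but {len(self.coords)} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InputError(f"atom table missing columns: {missing}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # -- selections -------------------------------------------------------

    def select(self, selection: str) -> np.ndarray:
        """Return atom indices for a named selection.

        Supported: ``protein_ca`` (alpha-carbons, the toy backbone),
        ``backbone`` (alias), ``protein_heavy``, ``ligand_heavy``,
        ``water``, ``all``.
        """
        a = self.atoms
        if selection in ("protein_ca", "backbone"):
            mask = (a["segment"] == PROTEIN) & (a["atom_name"] == "CA")
        elif selection == "protein_heavy":
            mask = a["segment"] == PROTEIN
        elif selection == "ligand_heavy":
            mask = a["segment"] == LIGAND
        elif selection == "water":
            mask = a["segment"] == WATER
        elif selection == "all":
            mask = np.ones(len(a), dtype=bool)
        else:
            raise InputError(f"unknown selection {selection!r}")
        idx = np.flatnonzero(mask.to_numpy())
        return idx

    def residue_ids(self) -> np.ndarray:
        """Sorted protein residue ids."""
        prot = self.atoms[self.atoms["segment"] == PROTEIN]
        return np.sort(prot["res_id"].unique())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, coords)


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``substate_labels`` carries planted ground-truth metadata for synthetic
    trajectories (which metastable conformer generated each frame) and is
    ``None`` for real inputs.
    """

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    substate_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise InputError("frame atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if self.substate_labels is not None:
            self.substate_labels = np.asarray(self.substate_labels)
            if len(self.substate_labels) != len(self.coords):
                raise InputError("one substate label per frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology.atoms, self.coords[i])

    def select(self, selection: str) -> np.ndarray:
        return self.topology.select(selection)
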