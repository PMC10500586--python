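"""PDB input/output and ground-truth sidecars.

Structures are written as standard PDB and trajectories as multi-model
PDB through biotite.  Chemical roles are not representable in PDB, so
synthetic ground truth (roles, planted substate labels, correlation
blocks) travels in a JSON sidecar; on reading a plain PDB, roles are
inferred coarsely from the element (N -> donor, O -> acceptor, otherwise
apolar) unless a sidecar is supplied.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
import numpy as np
import pandas as pd

from .core import LIGAND, PROTEIN, WATER, InputError, Structure, Trajectory

_CHAIN = {PROTEIN: "A", LIGAND: "L", WATER: "W"}
_ROLE_ELEMENT = {"donor": "N", "acceptor": "O", "cation": "N", "anion": "O",
                 "water": "O", "apolar": "C"}


def _to_atom_array(structure: Structure, coords: np.ndarray) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    atoms = structure.atoms
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([_CHAIN[s] for s in atoms["segment"]])
    arr.res_id = np.array(
        [rid if rid > 0 else (900 + abs(rid)) for rid in atoms["res_id"]], dtype=int
    )
    arr.res_name = atoms["res_name"].to_numpy(dtype="U5")
    arr.atom_name = atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = np.array([_ROLE_ELEMENT.get(r, "C") for r in atoms["role"]])
    arr.hetero = atoms["segment"].isin([LIGAND, WATER]).to_numpy()
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    pdb = bpdb.PDBFile()
    pdb.set_structure(_to_atom_array(structure, structure.coords))
    pdb.write(str(path))


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    stack = bst.stack(
        [_to_atom_array(traj.topology, traj.coords[f]) for f in range(traj.n_frames)]
    )
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_ground_truth(traj: Trajectory, path: str | Path, blocks=None) -> None:
    """JSON sidecar: roles per atom, substate labels, correlation blocks."""
    payload = {
        "roles": traj.topology.atoms["role"].tolist(),
        "parents": [int(p) for p in traj.topology.atoms["parent"]],
        "substate_labels": (
            [int(x) for x in traj.substate_labels]
            if traj.substate_labels is not None else None
        ),
        "correlation_blocks": blocks,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _from_atom_array(arr: bst.AtomArray, sidecar: dict | None = None) -> Structure:
    seg = np.where(
        arr.res_name == "HOH", WATER, np.where(arr.hetero, LIGAND, PROTEIN)
    )
    if sidecar and "roles" in sidecar:
        roles = list(sidecar["roles"])
        parents = [int(p) for p in sidecar.get("parents", range(len(arr)))]
    else:
        roles = [
            "water" if s == WATER else
            {"N": "donor", "O": "acceptor"}.get(e, "apolar")
            for s, e in zip(seg, arr.element)
        ]
        parents = list(range(len(arr)))
    atoms = pd.DataFrame(
        dict(
            res_id=np.where(seg == WATER, -(arr.res_id - 899), np.where(seg == LIGAND, 0, arr.res_id)),
            res_name=arr.res_name,
            atom_name=arr.atom_name,
            segment=seg,
            role=roles,
            parent=parents,
        )
    )
    return Structure(atoms, np.asarray(arr.coord, dtype=float))


def read_pdb(path: str | Path, sidecar_path: str | Path | None = None):
    """Read a PDB file as a Structure (single model) or Trajectory."""
    pdb = bpdb.PDBFile.read(str(path))
    sidecar = None
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
    obj = pdb.get_structure()
    if isinstance(obj, bst.AtomArrayStack):
        if obj.stack_depth() == 1:
            return _from_atom_array(obj[0], sidecar)
        top = _from_atom_array(obj[0], sidecar)
        labels = None
        if sidecar and sidecar.get("substate_labels") is not None:
            labels = np.array(sidecar["substate_labels"])
        return Trajectory(top, np.asarray(obj.coord, dtype=float), substate_labels=labels)
    return _from_atom_array(obj, sidecar)
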