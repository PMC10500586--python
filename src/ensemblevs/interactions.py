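"""Per-frame protein-ligand contact classification and interaction fractions.

Categories and default geometric criteria (standard literature values,
kept as data on :class:`InteractionCriteria` so they are configuration,
not code):

* hydrogen bond — donor/acceptor heavy-atom distance <= 3.5 Angstrom and
  an angle of at least 120 degrees at the donor between its bonded
  antecedent atom and the acceptor (the toy structures carry no hydrogens,
  so the antecedent stands in for the donor-H direction);
* hydrophobic — apolar-carbon pair within 4.0 Angstrom;
* ionic — opposite formal charges within 4.0 Angstrom;
* water bridge — one water simultaneously hydrogen-bonded (distance rule)
  to a protein residue and to the ligand.

The interaction fraction of a (residue, category) pair is the number of
contact events divided by the number of frames; multiple simultaneous
contacts on one residue accumulate, so fractions may exceed 1.  Residues
whose summed fraction reaches the report threshold (default 30% of the
simulation time) are flagged for the summary table.

Event granularity: hydrogen bonds and ionic contacts count one event per
qualifying atom pair; hydrophobic contacts one per (residue, ligand atom);
water bridges one per (residue, water).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LIGAND, PROTEIN, WATER, InputError, Structure, Trajectory

CATEGORIES = ("hbond", "hydrophobic", "ionic", "water_bridge")


@dataclass
class InteractionCriteria:
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0       # degrees, at the donor
    hydrophobic_distance: float = 4.0
    ionic_distance: float = 4.0
    report_threshold: float = 0.30

    def validate(self) -> None:
        for name in ("hbond_distance", "hydrophobic_distance", "ionic_distance"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if not (0 < self.report_threshold <= 1):
            raise InputError("report_threshold must be in (0, 1]")


@dataclass
class ContactProfile:
    """Aggregated interaction fractions per (residue, category)."""

    fractions: pd.DataFrame  # columns: res_id, category, fraction
    n_frames: int
    report_threshold: float

    def flagged_residues(self, per_category: bool = False) -> pd.DataFrame:
        """Residues at or above the report threshold.

        By default the threshold applies to the fraction summed over
        categories; ``per_category=True`` applies it per category instead.
        """
        if self.fractions.empty:
            return self.fractions.copy()
        if per_category:
            out = self.fractions[self.fractions["fraction"] >= self.report_threshold]
            return out.reset_index(drop=True)
        totals = self.fractions.groupby("res_id")["fraction"].sum()
        keep = totals[totals >= self.report_threshold].index
        out = self.fractions[self.fractions["res_id"].isin(keep)]
        return out.reset_index(drop=True)


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def _donor_angle_ok(coords, donor_idx, acceptor_idx, parent_idx, min_angle):
    """Angle parent-donor-acceptor must open at least ``min_angle`` degrees."""
    d = coords[donor_idx]
    p = coords[parent_idx]
    a = coords[acceptor_idx]
    if np.allclose(p, d):  # atom is its own parent: no direction, accept
        return True
    v1 = p - d
    v2 = a - d
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang >= min_angle


def classify_frame(frame: Structure, criteria: InteractionCriteria | None = None) -> list[tuple]:
    """Contact events for one frame: list of ``(res_id, category)`` tuples.

    One residue may emit several events per frame (they accumulate in the
    interaction fraction).
    """
    criteria = criteria or InteractionCriteria()
    criteria.validate()
    atoms = frame.atoms
    if "role" not in atoms.columns or atoms["role"].isna().any():
        raise InputError("atom roles (donor/acceptor/apolar/charge) required")
    coords = frame.coords
    prot = atoms[atoms["segment"] == PROTEIN]
    lig = atoms[atoms["segment"] == LIGAND]
    wat = atoms[atoms["segment"] == WATER]
    events: list[tuple] = []

    def hbond_pairs(side_a: pd.DataFrame, side_b: pd.DataFrame):
        """Directed donor(a) -> acceptor(b) pairs passing distance + angle."""
        donors = side_a[side_a["role"] == "donor"]
        acceptors = side_b[side_b["role"] == "acceptor"]
        if donors.empty or acceptors.empty:
            return []
        d = _dist(coords[donors.index.to_numpy()], coords[acceptors.index.to_numpy()])
        pairs = []
        for (di, dj) in zip(*np.nonzero(d <= criteria.hbond_distance)):
            don = donors.index[di]
            acc = acceptors.index[dj]
            if _donor_angle_ok(coords, don, acc, int(atoms.loc[don, "parent"]),
                               criteria.hbond_angle):
                pairs.append((don, acc))
        return pairs

    # hydrogen bonds, both directions
    for don, acc in hbond_pairs(prot, lig):
        events.append((int(atoms.loc[don, "res_id"]), "hbond"))
    for don, acc in hbond_pairs(lig, prot):
        events.append((int(atoms.loc[acc, "res_id"]), "hbond"))

    # hydrophobic: one event per (residue, ligand atom)
    papol = prot[prot["role"] == "apolar"]
    lapol = lig[lig["role"] == "apolar"]
    if not papol.empty and not lapol.empty:
        d = _dist(coords[papol.index.to_numpy()], coords[lapol.index.to_numpy()])
        hit = d <= criteria.hydrophobic_distance
        seen = set()
        for (pi, lj) in zip(*np.nonzero(hit)):
            key = (int(papol["res_id"].iloc[pi]), int(lapol.index[lj]))
            if key not in seen:
                seen.add(key)
                events.append((key[0], "hydrophobic"))

    # ionic: opposite formal charges, per atom pair
    for prole, lrole in (("cation", "anion"), ("anion", "cation")):
        pa = prot[prot["role"] == prole]
        la = lig[lig["role"] == lrole]
        if pa.empty or la.empty:
            continue
        d = _dist(coords[pa.index.to_numpy()], coords[la.index.to_numpy()])
        for (pi, lj) in zip(*np.nonzero(d <= criteria.ionic_distance)):
            events.append((int(pa["res_id"].iloc[pi]), "ionic"))

    # water bridges: water within hbond distance of a polar protein atom and
    # a polar ligand atom simultaneously; one event per (residue, water)
    if not wat.empty:
        polar = ("donor", "acceptor")
        ppol = prot[prot["role"].isin(polar)]
        lpol = lig[lig["role"].isin(polar)]
        if not ppol.empty and not lpol.empty:
            wxyz = coords[wat.index.to_numpy()]
            dp = _dist(wxyz, coords[ppol.index.to_numpy()])
            dl = _dist(wxyz, coords[lpol.index.to_numpy()])
            lig_bonded = (dl <= criteria.hbond_distance).any(axis=1)
            for wi in np.flatnonzero(lig_bonded):
                res_hit = ppol["res_id"].iloc[
                    np.nonzero(dp[wi] <= criteria.hbond_distance)[0]
                ].unique()
                for rid in res_hit:
                    events.append((int(rid), "water_bridge"))
    return events


def interaction_fractions(
    traj: Trajectory, criteria: InteractionCriteria | None = None
) -> ContactProfile:
    """Aggregate per-frame contact events into interaction fractions."""
    criteria = criteria or InteractionCriteria()
    criteria.validate()
    if traj.n_frames < 1:
        raise InputError("trajectory has no frames")
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        for key in classify_frame(traj.frame(f), criteria):
            counts[key] = counts.get(key, 0) + 1
    rows = [
        dict(res_id=res, category=cat, fraction=c / traj.n_frames)
        for (res, cat), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["res_id", "category", "fraction"])
    return ContactProfile(fractions=df, n_frames=traj.n_frames,
                          report_threshold=criteria.report_threshold)
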