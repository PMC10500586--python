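"""Bundled worked-example datasets.

Two small tables from the delta-opioid-receptor (DOR) ensemble
virtual-screening case study ship with the package:

* ``top8_screening`` — the eight top-ranked ZINC compounds and the DPI-287
  crystal-ligand reference: Glide XP docking score per receptor
  conformation (CC = crystal conformation, C1/C2 = the two abundant MD
  conformations), MM-GBSA interaction-energy components (VDW,
  electrostatic/GB, hydrophobic surface; kcal/mol) and total, RMSD
  averages, and the ADME annotations used as triage gates (GI absorption,
  BBB permeation, CYP inhibition flags, drug-likeness stars, PAINS/Brenk
  alert counts).  The three printed component terms omit the
  conformational-change energies, so for the screened compounds they do
  not sum to the printed totals; for the reference ligand they do, which
  the worked example exploits.
* ``selectivity_scores`` — Glide XP docking scores of the same compounds
  and the DOR/KOR/MOR crystal ligands (DPI-287, MP1104, BU27) on the three
  opioid-receptor crystal conformations, for the selectivity-delta
  arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import ReferenceCompound

REFERENCE_ID = "DPI-287"


def _load(name: str) -> pd.DataFrame:
    with resources.files("ensemblevs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_top8_screening() -> pd.DataFrame:
    """Screening table for the eight top compounds plus the reference ligand."""
    return _load("top8_screening.csv")


def load_selectivity_scores() -> pd.DataFrame:
    """Cross-receptor docking scores for the selectivity analysis."""
    return _load("selectivity_scores.csv")


def reference_compound() -> ReferenceCompound:
    """The crystal-ligand reference anchoring the filter cascade
    (docking -8.6 kcal/mol, MM-GBSA -90.2 kcal/mol)."""
    row = load_top8_screening().set_index("compound_id").loc[REFERENCE_ID]
    return ReferenceCompound(
        compound_id=REFERENCE_ID,
        docking_score=float(row["docking_score"]),
        mmgbsa_total=float(row["mmgbsa_total"]),
    )
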