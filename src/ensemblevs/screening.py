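"""Virtual-screening triage: MM-GBSA bookkeeping, drug-likeness stars,
reference-anchored filter cascade, selectivity deltas and scaffold clustering.

The cascade mirrors an ensemble-docking triage against a crystal-ligand
reference: compounds must dock at least as well as the reference
(kcal/mol, more negative is better, equality passes), carry at most
``max_stars`` drug-likeness violations, bind at least as favorably by
MM-GBSA, be predicted highly GI-absorbed and BBB-permeant, and raise no
PAINS or Brenk substructure alerts.  Gates are conjunctive, so their order
only affects the recorded first failure, never the surviving set.

Selectivity deltas compare each compound's docking score on several
receptors against its original (best-conformation) score on the target
receptor: delta = score_receptor - original_score, with column averages
rounded half-away-from-zero to one decimal, matching the reporting style
of published triage tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .core import ConfigurationError, InputError

#: default gate order; conjunctive, order affects only first_failure labels
GATE_ORDER = ("docking", "stars", "mmgbsa", "gi", "bbb", "alerts")


@dataclass
class EnergyComponents:
    """MM-GBSA terms for one compound (kcal/mol).

    Either the three state energies (complex / receptor / ligand) or the
    decomposed interaction terms (VDW, SUR, GBELE plus conformational-change
    terms) may be supplied; when both are present they must agree.
    """

    e_complex: float | None = None
    e_receptor: float | None = None
    e_ligand: float | None = None
    vdw: float | None = None
    sur: float | None = None
    gbele: float | None = None
    conf_receptor: float = 0.0
    conf_ligand: float = 0.0

    @property
    def has_state_energies(self) -> bool:
        return None not in (self.e_complex, self.e_receptor, self.e_ligand)

    @property
    def has_components(self) -> bool:
        return None not in (self.vdw, self.sur, self.gbele)


def mmgbsa_total(components: EnergyComponents, tol: float = 1e-6) -> float:
    """Binding free energy from either representation.

    State energies give ``E_complex - E_receptor - E_ligand``; decomposed
    terms give ``VDW + SUR + GBELE + conf_receptor + conf_ligand``.  When
    both are supplied and disagree beyond ``tol`` an error is raised.
    """
    c = components
    state = comp = None
    if c.has_state_energies:
        state = c.e_complex - c.e_receptor - c.e_ligand
    if c.has_components:
        comp = c.vdw + c.sur + c.gbele + c.conf_receptor + c.conf_ligand
    if state is None and comp is None:
        raise InputError("neither state energies nor decomposed components supplied")
    if state is not None and comp is not None and abs(state - comp) > tol:
        raise InputError(
            f"inconsistent MM-GBSA representations: {state:.6f} vs {comp:.6f}"
        )
    return float(state if state is not None else comp)


@dataclass
class DrugLikenessRules:
    """Property range table for violation-star counting.

    Defaults to the four Lipinski bounds; the table is extensible with any
    (min, max) range keyed by property name (use ``-inf``/``inf`` for
    one-sided bounds).  ``max_stars`` is the cascade gate (0-1 stars keeps
    a compound drug-like).
    """

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mw": (0.0, 500.0),
            "hbd": (0.0, 5.0),
            "hba": (0.0, 10.0),
            "logp": (-np.inf, 5.0),
        }
    )
    max_stars: int = 1

    def validate(self) -> None:
        for prop, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ConfigurationError(f"range for {prop!r} is not ordered")


def count_violation_stars(record, rules: DrugLikenessRules | None = None) -> int:
    """One star per property outside its drug-like range.

    ``record`` is any mapping (dict / Series) of property values; a
    property listed in the rules but missing from the record earns no star
    and is skipped.
    """
    rules = rules or DrugLikenessRules()
    rules.validate()
    stars = 0
    for prop, (lo, hi) in rules.ranges.items():
        if prop not in record or pd.isna(record[prop]):
            continue
        v = float(record[prop])
        if not (lo <= v <= hi):
            stars += 1
    return stars


@dataclass
class ReferenceCompound:
    """Cutoff anchor for the cascade (the crystal ligand)."""

    compound_id: str
    docking_score: float
    mmgbsa_total: float

    def validate(self) -> None:
        if not np.isfinite(self.docking_score) or not np.isfinite(self.mmgbsa_total):
            raise ConfigurationError("reference docking score and MM-GBSA total required")


def apply_filter_cascade(
    table: pd.DataFrame,
    reference: ReferenceCompound,
    rules: DrugLikenessRules | None = None,
    gate_order: tuple[str, ...] = GATE_ORDER,
) -> pd.DataFrame:
    """Annotate each compound with per-gate pass/fail and the first failure.

    Expected columns: ``docking_score``, ``mmgbsa_total``, ``gi_absorption``
    (high/low), ``bbb_permeant`` (yes/no), ``pains_alerts``, ``brenk_alerts``
    and either ``stars`` or the Lipinski property columns (mw/hbd/hba/logp)
    from which stars are counted.  Adds boolean ``pass_<gate>`` columns,
    ``stars``, ``first_failure`` (empty string for survivors) and
    ``survives``.
    """
    rules = rules or DrugLikenessRules()
    reference.validate()
    out = table.copy()
    if "stars" not in out.columns:
        out["stars"] = [count_violation_stars(row, rules) for _, row in out.iterrows()]
    checks = {
        "docking": out["docking_score"] <= reference.docking_score,
        "stars": out["stars"] <= rules.max_stars,
        "mmgbsa": out["mmgbsa_total"] <= reference.mmgbsa_total,
        "gi": out["gi_absorption"].astype(str).str.lower() == "high",
        "bbb": out["bbb_permeant"].astype(str).str.lower().isin(("yes", "true", "1")),
        "alerts": (out["pains_alerts"] == 0) & (out["brenk_alerts"] == 0),
    }
    unknown = set(gate_order) - set(checks)
    if unknown:
        raise ConfigurationError(f"unknown gates {sorted(unknown)}")
    first = np.array([""] * len(out), dtype=object)
    for gate in gate_order:
        out[f"pass_{gate}"] = checks[gate].to_numpy()
        newly = (first == "") & ~checks[gate].to_numpy()
        first[newly] = gate
    out["first_failure"] = first
    out["survives"] = first == ""
    return out


def survivors(cascade: pd.DataFrame) -> pd.DataFrame:
    return cascade[cascade["survives"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityTable:
    """Per-compound docking scores and deltas across receptors.

    ``per_compound`` holds one row per compound with ``<receptor>_score``
    and ``<receptor>_delta`` columns; ``score_averages`` / ``delta_averages``
    are column means over the screened (non-crystal) compounds, rounded
    half-away-from-zero to one decimal.
    """

    per_compound: pd.DataFrame
    score_averages: dict[str, float]
    delta_averages: dict[str, float]
    original_average: float


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-table convention)."""
    scale = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5 + 1e-9) / scale)


def selectivity_deltas(
    table: pd.DataFrame,
    receptor_columns: tuple[str, ...] = ("dor_cc", "kor_cc", "mor_cc"),
) -> SelectivityTable:
    """Delta table: receptor score minus the compound's original score.

    ``table`` needs ``compound_id``, ``original_score`` (NaN for crystal
    ligands, whose reference is their best — most negative — score among
    the receptor columns) and one score column per receptor.  Compounds
    missing a receptor score are skipped with a warning.  Averages are
    taken over the screened compounds only (crystal ligands excluded).
    """
    rows = []
    for _, rec in table.iterrows():
        scores = {col: rec.get(col) for col in receptor_columns}
        if any(pd.isna(s) for s in scores.values()):
            warnings.warn(f"skipping {rec.get('compound_id')!r}: missing score",
                          stacklevel=2)
            continue
        crystal = pd.isna(rec.get("original_score"))
        origin = min(scores.values()) if crystal else float(rec["original_score"])
        row = {"compound_id": rec["compound_id"], "is_crystal_ligand": crystal,
               "original_score": origin}
        for col in receptor_columns:
            row[f"{col}_score"] = float(scores[col])
            row[f"{col}_delta"] = float(scores[col]) - origin
        rows.append(row)
    per = pd.DataFrame(rows)
    screened = per[~per["is_crystal_ligand"]]
    score_avg = {c: round_half_away(screened[f"{c}_score"].mean()) for c in receptor_columns}
    delta_avg = {c: round_half_away(screened[f"{c}_delta"].mean()) for c in receptor_columns}
    orig_avg = round_half_away(screened["original_score"].mean()) if len(screened) else float("nan")
    return SelectivityTable(per_compound=per, score_averages=score_avg,
                            delta_averages=delta_avg, original_average=orig_avg)


# ---------------------------------------------------------------------------
# scaffold diversity
# ---------------------------------------------------------------------------

def tanimoto_matrix(smiles: list[str]):
    """Hashed path fingerprints + pairwise Tanimoto similarity.

    Returns (similarity matrix over parseable compounds, list of parseable
    indices, list of failed indices).
    """
    from rdkit import Chem, DataStructs

    fps, ok, bad = [], [], []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            bad.append(i)
            continue
        fps.append(Chem.RDKFingerprint(mol, fpSize=2048))
        ok.append(i)
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sim[i, i + 1:] = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
    sim = np.maximum(sim, sim.T)
    return sim, ok, bad


def scaffold_clusters(smiles: list[str], similarity_cutoff: float = 0.7) -> np.ndarray:
    """Average-linkage scaffold clustering on Tanimoto distance.

    Compounds merge while their average similarity stays above
    ``similarity_cutoff``.  Returns one cluster id per input compound
    (ids assigned by first occurrence, deterministic); unparseable
    structures get id -1.
    """
    if not (0 < similarity_cutoff <= 1):
        raise ConfigurationError("similarity_cutoff must be in (0, 1]")
    sim, ok, bad = tanimoto_matrix(smiles)
    if bad:
        warnings.warn(f"{len(bad)} unparseable structure(s) excluded", stacklevel=2)
    labels = np.full(len(smiles), -1, dtype=int)
    n = len(ok)
    if n == 1:
        labels[ok[0]] = 1
        return labels
    if n > 1:
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        z = sch.linkage(squareform(dist, checks=False), method="average")
        raw = sch.fcluster(z, t=1.0 - similarity_cutoff, criterion="distance")
        remap: dict[int, int] = {}
        for pos, cl in enumerate(raw):
            if cl not in remap:
                remap[cl] = len(remap) + 1
            labels[ok[pos]] = remap[cl]
    return labels
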