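"""Superposition-based RMSD/RMSF time series and convergence diagnostics.

Conventions
-----------
* RMSD uses least-squares rigid superposition (Kabsch); the returned value
  is the global minimum over rotations and translations.
* Ligand RMSD is a *binding-pose* RMSD: frames are superposed on the protein
  alpha-carbons and the deviation is measured over ligand heavy atoms, i.e.
  ligand movement in the receptor frame.
* RMSF is taken about the mean structure with a two-pass alignment: align
  all frames to frame 0, compute the mean, re-align to the mean, then take
  the per-atom root-mean-square deviation.
* Convergence is declared when the mean of the last window differs from the
  mean of the penultimate window by at most ``drift_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DegenerateGeometryError, InputError, Structure, Trajectory


@dataclass
class MetricSeries:
    """Per-frame scalar metric (Angstrom) over a named selection."""

    values: np.ndarray
    selection: str
    reference: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise InputError("metric values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConvergenceReport:
    window: int
    mean: float
    drift: float
    drift_tol: float
    converged: bool


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` in the
    least-squares sense.  The rotation is proper (determinant +1).

    Raises
    ------
    InputError
        if the point sets differ in shape.
    DegenerateGeometryError
        for fewer than 3 points or collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError(f"point sets must share shape (n, 3); got {mobile.shape} vs {target.shape}")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError("at least 3 points required for superposition")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    x = mobile - mu_m
    y = target - mu_t
    # collinearity: centered point cloud with rank < 2 leaves the rotation
    # under-determined about the line
    if np.linalg.matrix_rank(x, tol=1e-8 * max(1.0, np.abs(x).max())) < 2:
        raise DegenerateGeometryError("mobile points are collinear")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(corr) @ u.T
    # residual-based evaluation avoids the cancellation error of the
    # trace formula (exact zeros stay zero to ~1e-12)
    rmsd = float(np.sqrt(np.mean(np.sum((x @ rotation.T - y) ** 2, axis=1))))
    translation = mu_t - rotation @ mu_m
    return rotation, translation, rmsd


def _fit_frames(coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit selection."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = superpose(coords[f, fit_idx], reference[fit_idx])
        out[f] = coords[f] @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    reference: Structure | int = 0,
    selection: str = "protein_ca",
    fit_selection: str | None = None,
) -> MetricSeries:
    """Per-frame RMSD to a reference structure (or frame index).

    ``fit_selection`` defaults to ``selection``; pass ``"protein_ca"`` with
    ``selection="ligand_heavy"`` for binding-pose ligand RMSD.
    """
    fit_sel = fit_selection or selection
    idx = traj.select(selection)
    fit_idx = traj.select(fit_sel)
    if len(idx) == 0 or len(fit_idx) == 0:
        raise InputError(f"empty selection {selection!r}/{fit_sel!r}")
    if isinstance(reference, Structure):
        ref_coords, ref_name = reference.coords, "external"
    else:
        ref_coords, ref_name = traj.coords[int(reference)], f"frame {int(reference)}"
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans, fit_rmsd = superpose(traj.coords[f, fit_idx], ref_coords[fit_idx])
        if np.array_equal(fit_idx, idx):
            values[f] = fit_rmsd
        else:
            moved = traj.coords[f, idx] @ rot.T + trans
            values[f] = float(np.sqrt(np.mean(np.sum((moved - ref_coords[idx]) ** 2, axis=1))))
    return MetricSeries(values, selection=selection, reference=ref_name)


def rmsf(
    traj: Trajectory,
    selection: str = "protein_ca",
    fit_selection: str | None = None,
) -> pd.Series:
    """Per-residue RMSF about the mean structure (two-pass alignment).

    Returns a Series indexed by residue id (Angstrom).  ``fit_selection``
    allows excluding flexible regions from the superposition while still
    reporting their fluctuation.
    """
    if traj.n_frames < 2:
        raise InputError("RMSF requires at least 2 frames")
    idx = traj.select(selection)
    if len(idx) == 0:
        raise InputError(f"empty selection {selection!r}")
    if fit_selection is None:
        fit_idx = idx
    elif isinstance(fit_selection, str):
        fit_idx = traj.select(fit_selection)
    else:  # explicit atom indices, e.g. a rigid core excluding mobile tails
        fit_idx = np.asarray(fit_selection, dtype=int)
    aligned = _fit_frames(traj.coords, traj.coords[0], fit_idx)
    mean0 = aligned.mean(axis=0)
    aligned = _fit_frames(aligned, mean0, fit_idx)
    mean = aligned.mean(axis=0)
    sq = np.mean(np.sum((aligned[:, idx] - mean[idx]) ** 2, axis=2), axis=0)
    values = np.sqrt(sq)
    res_ids = traj.topology.atoms["res_id"].to_numpy()[idx]
    per_atom = pd.DataFrame({"res_id": res_ids, "msf": sq})
    per_res = per_atom.groupby("res_id")["msf"].mean().pow(0.5)
    per_res.name = "rmsf"
    # keep one value per selected atom available for exact-sum identities
    per_res.attrs["per_atom_rmsf"] = values
    return per_res


def assess_convergence(
    series: MetricSeries,
    window: int | None = None,
    drift_tol: float = 0.3,
) -> ConvergenceReport:
    """Two-window drift test: converged iff the last and penultimate window
    means differ by at most ``drift_tol``.  Default window is the last 25%
    of frames."""
    n = len(series)
    if window is None:
        window = max(1, n // 4)
    if window > n:
        raise InputError(f"window {window} exceeds series length {n}")
    if 2 * window > n:
        raise InputError("series too short for two windows of this length")
    last = float(np.mean(series.values[-window:]))
    prev = float(np.mean(series.values[-2 * window:-window]))
    drift = abs(last - prev)
    return ConvergenceReport(
        window=window, mean=last, drift=drift,
        drift_tol=drift_tol, converged=drift <= drift_tol,
    )
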