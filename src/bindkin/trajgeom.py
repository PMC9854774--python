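"""Trajectory container, atom selection, Kabsch superposition, RMSD and RMSF.

Coordinates are carried as a plain ``(n_frames, n_atoms, 3)`` float array in
Angstroms alongside a pandas atom table, which keeps the geometric
operations transparent and easily testable.  Superposition uses the Kabsch
algorithm (SVD with reflection correction), the closed-form least-squares
rigid alignment of two point sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

BACKBONE_NAMES = ("N", "CA", "C", "O")

ATOM_COLUMNS = ["name", "element", "res_name", "res_id", "chain", "role"]


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames over a fixed atom table.

    ``atoms`` columns: name, element, res_name, res_id, chain,
    role in {protein, ligand, other}.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    atoms: pd.DataFrame

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 3 or coords.shape[0] < 1:
            raise InputError("coords must have shape (n_frames >= 1, n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InputError(f"atom table missing columns {missing}")
        if len(self.atoms) != coords.shape[1]:
            raise InputError("atom table length does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Selections (boolean masks over the atom table)
# ---------------------------------------------------------------------------


def select_atoms(
    traj: Trajectory,
    role: str | None = None,
    backbone: bool = False,
    res_ids: tuple[int, int] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Boolean atom mask by role, backbone flag, residue window and element."""
    mask = np.ones(traj.n_atoms, dtype=bool)
    atoms = traj.atoms
    if role is not None:
        mask &= (atoms["role"] == role).to_numpy()
    if backbone:
        mask &= atoms["name"].isin(BACKBONE_NAMES).to_numpy()
    if res_ids is not None:
        lo, hi = res_ids
        mask &= ((atoms["res_id"] >= lo) & (atoms["res_id"] <= hi)).to_numpy()
    if heavy_only:
        mask &= (atoms["element"].str.upper() != "H").to_numpy()
    return mask


def active_site_backbone(
    traj: Trajectory,
    ligand_mask: np.ndarray | None = None,
    cutoff: float = 10.0,
    frame: int = 0,
) -> np.ndarray:
    """Backbone N/CA/C/O of residues with any atom within ``cutoff`` of the ligand.

    Evaluated on a reference frame; this is the default fitting selection
    for ligand RMSD (the "active-site backbone").
    """
    if ligand_mask is None:
        ligand_mask = select_atoms(traj, role="ligand")
    if not ligand_mask.any():
        raise InputError("ligand selection is empty")
    xyz = traj.coords[frame]
    lig = xyz[ligand_mask]
    d = np.linalg.norm(xyz[:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    near = d <= cutoff
    prot = select_atoms(traj, role="protein")
    res_keys = traj.atoms[["chain", "res_id"]].apply(tuple, axis=1)
    near_res = set(res_keys[near & prot])
    in_near_res = res_keys.isin(near_res).to_numpy()
    mask = in_near_res & prot & traj.atoms["name"].isin(BACKBONE_NAMES).to_numpy()
    if not mask.any():
        raise InputError(f"no active-site backbone atoms within {cutoff} A")
    return mask


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with the fitted RMSD.

    Minimises ||R @ mobile.T + t - reference.T|| over rigid motions; the
    returned rotation always has determinant +1 (reflections corrected).
    Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InputError("superposition requires >= 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise InputError("selection atoms are collinear; rotation is ill-defined")
    H = m0.T @ r0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return (R @ np.asarray(coords, dtype=float).T).T + t


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    fit_mask: np.ndarray | None = None,
    measure_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) over ``measure_mask`` after fitting on ``fit_mask``.

    ``reference`` is a frame index or an (n_atoms, 3) array.  Each frame is
    rigidly fitted to the reference on the fit selection, then the RMSD is
    measured over the measure selection without refitting.  ``fit_mask=None``
    skips superposition entirely.
    """
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, float)
    if ref.shape != (traj.n_atoms, 3):
        raise InputError("reference must match the trajectory atom count")
    if measure_mask is None:
        measure_mask = np.ones(traj.n_atoms, dtype=bool)
    if not measure_mask.any():
        raise InputError("measure selection is empty")
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        if fit_mask is not None:
            R, t, _ = kabsch_superpose(frame[fit_mask], ref[fit_mask])
            frame = apply_transform(frame, R, t)
        out[k] = _rmsd(frame[measure_mask], ref[measure_mask])
    return out


def rmsf(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    fit_mask: np.ndarray | None = None,
    reference: int = 0,
) -> np.ndarray:
    """Per-atom root mean square fluctuation about the mean position (A).

    Frames are first superposed onto the reference frame on ``fit_mask``
    (or left untouched when None); each selected atom's RMSF is the square
    root of its mean squared deviation from its time-averaged position.
    """
    if traj.n_frames < 2:
        raise InputError("RMSF requires >= 2 frames")
    if mask is None:
        mask = np.ones(traj.n_atoms, dtype=bool)
    if not mask.any():
        raise InputError("RMSF selection is empty")
    ref = traj.coords[reference]
    aligned = np.empty((traj.n_frames, int(mask.sum()), 3))
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        if fit_mask is not None:
            R, t, _ = kabsch_superpose(frame[fit_mask], ref[fit_mask])
            frame = apply_transform(frame, R, t)
        aligned[k] = frame[mask]
    mean_pos = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
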