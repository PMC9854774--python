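"""Geometric protein-ligand interaction profiling and occupancy statistics.

Interactions are detected frame by frame from pure geometry, following the
published PLIP default criteria: hydrogen bonds (donor-acceptor heavy-atom
distance with a donor-angle check when hydrogens are present), hydrophobic
contacts between apolar carbons, pi-pi stacking between aromatic rings, and
pi-cation contacts.  Occupancy ("occurrence") is the percentage of frames
in which a given interaction is present, reported per interaction key
(type, residue) together with its average distance.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .trajgeom import Trajectory

logger = logging.getLogger(__name__)

#: Heavy-atom pair distance below which a covalent bond is assumed (A).
BOND_CUTOFF = 1.75
#: X-H bond cutoff (A).
H_BOND_CUTOFF = 1.25

#: Canonical aromatic ring atom names for protein residues.
PROTEIN_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"), ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
}

#: Protein side-chain cation centres (residue -> atom carrying the charge).
PROTEIN_CATION_ATOMS = {"LYS": "NZ", "ARG": "CZ"}


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance/angle thresholds for geometric interaction detection.

    Defaults follow the published PLIP values.  ``pistack_angle_windows``
    are windows (degrees) for the acute angle between ring planes:
    near-parallel (sandwich) and near-perpendicular (T-shaped).
    """

    hbond_max_dist: float = 4.1           # donor-acceptor heavy atoms, A
    hbond_min_donor_angle: float = 100.0  # D-H...A angle, degrees
    hydrophobic_max_dist: float = 4.0
    pistack_max_centroid_dist: float = 5.5
    pistack_max_offset: float = 2.0
    pistack_angle_windows: tuple[tuple[float, float], ...] = ((0.0, 30.0), (60.0, 90.0))
    pication_max_dist: float = 6.0

    def __post_init__(self):
        for name in (
            "hbond_max_dist", "hydrophobic_max_dist",
            "pistack_max_centroid_dist", "pistack_max_offset", "pication_max_dist",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not (0.0 <= self.hbond_min_donor_angle <= 180.0):
            raise InputError("hbond_min_donor_angle must lie in [0, 180]")
        for lo, hi in self.pistack_angle_windows:
            if not (0.0 <= lo <= hi <= 180.0):
                raise InputError("pistack angle windows must lie in [0, 180]")


@dataclass(frozen=True)
class InteractionEvent:
    """One detected geometric interaction in one frame."""

    frame: int
    type: str  # hbond | hydrophobic | pi_stack | pi_cation
    ligand_atoms: tuple[str, ...]
    res_name: str
    res_id: int
    protein_atoms: tuple[str, ...]
    distance: float
    angle: float | None = None

    @property
    def residue(self) -> str:
        return f"{self.res_name}{self.res_id}"


# ---------------------------------------------------------------------------
# Chemical typing from geometry + elements
# ---------------------------------------------------------------------------


class _Typing:
    """Pre-computed chemistry of one trajectory: bonds, donors, rings, etc.

    Bond perception uses heavy-atom distances on a reference frame; the
    typing is reused for every frame of the same trajectory.
    """

    def __init__(self, traj: Trajectory, ligand_mask, protein_mask, frame: int = 0):
        atoms = traj.atoms
        if atoms["element"].isna().any() or (atoms["element"] == "").any():
            raise InputError("element metadata required for interaction typing")
        self.elements = atoms["element"].str.upper().to_numpy()
        xyz = traj.coords[frame]
        self.ligand_idx = np.flatnonzero(ligand_mask)
        self.protein_idx = np.flatnonzero(protein_mask)

        heavy = self.elements != "H"
        self.graph = nx.Graph()
        self.graph.add_nodes_from(range(traj.n_atoms))
        # bonds within each role group only (no ligand-protein covalent bonds)
        for idx in (self.ligand_idx, self.protein_idx):
            pos = xyz[idx]
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    ia, ib = idx[a], idx[b]
                    cut = BOND_CUTOFF if (heavy[ia] and heavy[ib]) else H_BOND_CUTOFF
                    if d[a, b] <= cut and not (
                        self.elements[ia] == "H" and self.elements[ib] == "H"
                    ):
                        self.graph.add_edge(int(ia), int(ib))

        self.has_hydrogens = {
            "ligand": (self.elements[self.ligand_idx] == "H").any(),
            "protein": (self.elements[self.protein_idx] == "H").any(),
        }

        self.acceptors = {
            "ligand": self._acceptors(self.ligand_idx),
            "protein": self._acceptors(self.protein_idx),
        }
        self.donors = {
            "ligand": self._donors(self.ligand_idx, self.has_hydrogens["ligand"]),
            "protein": self._donors(self.protein_idx, self.has_hydrogens["protein"]),
        }
        self.apolar_carbons = {
            "ligand": self._apolar_carbons(self.ligand_idx),
            "protein": self._apolar_carbons(self.protein_idx),
        }
        self.rings = {
            "ligand": self._ligand_rings(),
            "protein": self._protein_rings(atoms),
        }
        self.cations = {"protein": self._protein_cations(atoms), "ligand": np.array([], int)}

    def _acceptors(self, idx):
        return np.array([i for i in idx if self.elements[i] in ("O", "N")], int)

    def _donors(self, idx, with_h):
        """(donor, hydrogen) pairs; hydrogen = -1 when positions are absent."""
        donors = []
        for i in idx:
            if self.elements[i] not in ("O", "N"):
                continue
            hs = [j for j in self.graph.neighbors(i) if self.elements[j] == "H"]
            if hs:
                donors.extend((i, h) for h in hs)
            elif not with_h:
                donors.append((i, -1))
        if not with_h and donors:
            logger.warning(
                "no hydrogen positions in selection: all N/O treated as donors, "
                "donor-angle criterion skipped"
            )
        return donors

    def _apolar_carbons(self, idx):
        out = []
        for i in idx:
            if self.elements[i] != "C":
                continue
            if any(self.elements[j] in ("N", "O") for j in self.graph.neighbors(i)):
                continue
            out.append(i)
        return np.array(out, int)

    def _ligand_rings(self):
        sub = self.graph.subgraph(
            [int(i) for i in self.ligand_idx if self.elements[i] in ("C", "N")]
        )
        rings = []
        for cycle in nx.minimum_cycle_basis(sub):
            if len(cycle) in (5, 6):
                rings.append(np.array(sorted(cycle), int))
        return rings

    def _protein_rings(self, atoms):
        rings = []
        prot = atoms.iloc[self.protein_idx]
        for (chain, res_id, res_name), grp in prot.groupby(
            ["chain", "res_id", "res_name"], sort=True
        ):
            for ring_names in PROTEIN_RING_ATOMS.get(res_name, []):
                sel = grp[grp["name"].isin(ring_names)]
                if len(sel) == len(ring_names):
                    rings.append(np.array(sel.index, int))
        return rings

    def _protein_cations(self, atoms):
        prot = atoms.iloc[self.protein_idx]
        hits = prot[
            prot.apply(
                lambda r: PROTEIN_CATION_ATOMS.get(r["res_name"]) == r["name"], axis=1
            )
        ]
        return np.array(hits.index, int)


def _ring_geometry(xyz, ring_idx):
    pts = xyz[ring_idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # ring normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def _angle_deg(a, b, c):
    """Angle at vertex b of points a-b-c, degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_interactions(
    traj: Trajectory,
    frame: int,
    ligand_mask: np.ndarray,
    protein_mask: np.ndarray,
    criteria: InteractionCriteria = InteractionCriteria(),
    typing: _Typing | None = None,
) -> list[InteractionEvent]:
    """All geometric interactions between ligand and protein in one frame."""
    if not ligand_mask.any() or not protein_mask.any():
        raise InputError("ligand and protein selections must be non-empty")
    if (ligand_mask & protein_mask).any():
        raise InputError("ligand and protein selections must be disjoint")
    if typing is None:
        typing = _Typing(traj, ligand_mask, protein_mask)
    xyz = traj.coords[frame]
    atoms = traj.atoms
    events: list[InteractionEvent] = []

    def residue_of(i):
        row = atoms.iloc[i]
        return str(row["res_name"]), int(row["res_id"])

    # --- hydrogen bonds (both donor directions) ---
    for donor_side, acceptor_side in (("ligand", "protein"), ("protein", "ligand")):
        for d_idx, h_idx in typing.donors[donor_side]:
            for a_idx in typing.acceptors[acceptor_side]:
                dist = float(np.linalg.norm(xyz[d_idx] - xyz[a_idx]))
                if dist > criteria.hbond_max_dist:
                    continue
                angle = None
                if h_idx >= 0:
                    angle = _angle_deg(xyz[d_idx], xyz[h_idx], xyz[a_idx])
                    if angle < criteria.hbond_min_donor_angle:
                        continue
                prot_i = d_idx if donor_side == "protein" else a_idx
                lig_i = d_idx if donor_side == "ligand" else a_idx
                res_name, res_id = residue_of(prot_i)
                events.append(
                    InteractionEvent(
                        frame=frame, type="hbond",
                        ligand_atoms=(str(atoms.iloc[lig_i]["name"]),),
                        res_name=res_name, res_id=res_id,
                        protein_atoms=(str(atoms.iloc[prot_i]["name"]),),
                        distance=dist, angle=angle,
                    )
                )

    # --- hydrophobic contacts ---
    lc, pc = typing.apolar_carbons["ligand"], typing.apolar_carbons["protein"]
    if len(lc) and len(pc):
        d = np.linalg.norm(xyz[lc][:, None] - xyz[pc][None, :], axis=2)
        for ai, bi in zip(*np.nonzero(d <= criteria.hydrophobic_max_dist)):
            res_name, res_id = residue_of(pc[bi])
            events.append(
                InteractionEvent(
                    frame=frame, type="hydrophobic",
                    ligand_atoms=(str(atoms.iloc[lc[ai]]["name"]),),
                    res_name=res_name, res_id=res_id,
                    protein_atoms=(str(atoms.iloc[pc[bi]]["name"]),),
                    distance=float(d[ai, bi]),
                )
            )

    # --- pi-pi stacking ---
    for lring in typing.rings["ligand"]:
        lcen, lnorm = _ring_geometry(xyz, lring)
        for pring in typing.rings["protein"]:
            pcen, pnorm = _ring_geometry(xyz, pring)
            dvec = pcen - lcen
            dist = float(np.linalg.norm(dvec))
            if dist > criteria.pistack_max_centroid_dist:
                continue
            cosang = abs(float(np.dot(lnorm, pnorm)))
            plane_angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if not any(lo <= plane_angle <= hi for lo, hi in criteria.pistack_angle_windows):
                continue
            # offset: in-plane displacement of one centroid projected on the other ring
            offs = []
            for cen, norm, other in ((lcen, lnorm, pcen), (pcen, pnorm, lcen)):
                v = other - cen
                offs.append(float(np.linalg.norm(v - np.dot(v, norm) * norm)))
            if min(offs) > criteria.pistack_max_offset:
                continue
            res_name, res_id = residue_of(pring[0])
            events.append(
                InteractionEvent(
                    frame=frame, type="pi_stack",
                    ligand_atoms=tuple(atoms.iloc[i]["name"] for i in lring),
                    res_name=res_name, res_id=res_id,
                    protein_atoms=tuple(atoms.iloc[i]["name"] for i in pring),
                    distance=dist, angle=plane_angle,
                )
            )

    # --- pi-cation ---
    for lring in typing.rings["ligand"]:
        lcen, _ = _ring_geometry(xyz, lring)
        for cat in typing.cations["protein"]:
            dist = float(np.linalg.norm(xyz[cat] - lcen))
            if dist > criteria.pication_max_dist:
                continue
            res_name, res_id = residue_of(cat)
            events.append(
                InteractionEvent(
                    frame=frame, type="pi_cation",
                    ligand_atoms=tuple(atoms.iloc[i]["name"] for i in lring),
                    res_name=res_name, res_id=res_id,
                    protein_atoms=(str(atoms.iloc[cat]["name"]),),
                    distance=dist,
                )
            )
    return events


def detect_trajectory(
    traj: Trajectory,
    ligand_mask: np.ndarray,
    protein_mask: np.ndarray,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[InteractionEvent]:
    """Detect interactions in every frame, reusing one chemical typing."""
    typing = _Typing(traj, ligand_mask, protein_mask)
    events: list[InteractionEvent] = []
    for k in range(traj.n_frames):
        events.extend(
            detect_interactions(traj, k, ligand_mask, protein_mask, criteria, typing)
        )
    return events


def occurrence(
    events: Iterable[InteractionEvent],
    n_frames: int,
    interaction_type: str,
    res_name: str,
    res_id: int,
) -> float:
    """Percent of frames with >= 1 matching event for (type, residue)."""
    if n_frames <= 0:
        raise InputError("trajectory frame count must be positive")
    frames = {
        e.frame
        for e in events
        if e.type == interaction_type and e.res_name == res_name and e.res_id == res_id
    }
    return 100.0 * len(frames) / n_frames


def occurrence_summary(
    events: Sequence[InteractionEvent], n_frames: int
) -> pd.DataFrame:
    """Occupancy table: one row per (type, residue) with mean distance.

    Distances are averaged over all emitted events for that key (one value
    per event, as in per-snapshot averaging of interaction distances).
    """
    if n_frames <= 0:
        raise InputError("trajectory frame count must be positive")
    frames = defaultdict(set)
    dists = defaultdict(list)
    for e in events:
        key = (e.type, e.res_name, e.res_id)
        frames[key].add(e.frame)
        dists[key].append(e.distance)
    rows = [
        {
            "type": t,
            "res_name": rn,
            "res_id": ri,
            "occurrence_pct": 100.0 * len(frames[(t, rn, ri)]) / n_frames,
            "mean_distance": float(np.mean(dists[(t, rn, ri)])),
            "n_events": len(dists[(t, rn, ri)]),
        }
        for (t, rn, ri) in sorted(frames)
    ]
    return pd.DataFrame(rows)
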