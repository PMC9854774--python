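"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study's raw data:

* stationary AR(1) interaction-energy series with prescribed means and
  marginal SDs over independent replicates (MD energy output is strongly
  autocorrelated; AR(1) is the minimal model, with effective sample size
  n*(1-rho)/(1+rho));
* initial-velocity tables drawn from the general modifier rate law on the
  assay concentration grids with multiplicative (constant-CV) noise;
* rigid-template coordinate trajectories of a ~50-atom toy protein-ligand
  complex with iid Gaussian jitter, optional rigid drift, and a hydrogen
  bond toggled on/off per frame with known Bernoulli probability.

Every generator is a pure function of its spec (seed included): identical
specs produce identical output.  Each returns its exact ground truth in a
manifest so recovery tests can be automated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .energetics import EnergySeries, State, Interaction
from .kinetics import (
    INHIBITOR_COL,
    KineticParameters,
    REPLICATE_COL,
    SUBSTRATE_COL,
    VELOCITY_COL,
    velocity,
)
from .trajgeom import Trajectory

# Assay concentration grids (uM).  The variable-substrate ranges are the
# standard CDNB (with saturating GSH) and GSH (with fixed CDNB) assay series;
# the inhibitor series brackets low-micromolar inhibition constants.
CDNB_GRID = (14.0, 28.0, 56.0, 112.0, 250.0, 500.0, 1000.0)
GSH_GRID = (37.5, 75.0, 150.0, 300.0, 750.0, 1500.0, 3750.0)
INHIBITOR_GRID = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)

COMPONENT_NAMES = ("vdw_bound", "vdw_free", "ele_bound", "ele_free", "ele_bound_uncharged")

_COMPONENT_STATE = {
    "vdw_bound": (State.BOUND, Interaction.VDW),
    "vdw_free": (State.FREE, Interaction.VDW),
    "ele_bound": (State.BOUND, Interaction.ELE),
    "ele_free": (State.FREE, Interaction.ELE),
    "ele_bound_uncharged": (State.BOUND_Q0, Interaction.ELE),
}


# ---------------------------------------------------------------------------
# Energy series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyGeneratorSpec:
    """AR(1) energy-series generator settings.

    ``means`` maps component names (vdw_bound, vdw_free, ele_bound,
    ele_free, optionally ele_bound_uncharged) to target means in kcal/mol.
    ``sigma`` is the stationary per-frame SD and ``rho`` the lag-1
    autocorrelation.
    """

    means: dict[str, float]
    sigma: float = 1.5
    rho: float = 0.8
    frames: int = 2000
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.means) - set(COMPONENT_NAMES)
        if unknown:
            raise InputError(f"unknown energy components: {sorted(unknown)}")
        required = {"vdw_bound", "vdw_free", "ele_bound", "ele_free"}
        if not required <= set(self.means):
            raise InputError("means must include the four charged-state components")
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise InputError("rho must lie in [0, 1)")
        if self.frames < 10:
            raise InputError("frames must be >= 10")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")

    @property
    def effective_sample_size(self) -> float:
        return self.frames * (1.0 - self.rho) / (1.0 + self.rho)


def gen_energy_series(spec: EnergyGeneratorSpec) -> list[EnergySeries]:
    """Stationary AR(1) series per component and replicate.

    x_0 ~ N(mu, sigma^2); x_t = mu + rho*(x_{t-1} - mu) + eps_t with
    eps_t ~ N(0, sigma^2*(1 - rho^2)), so the marginal distribution is
    N(mu, sigma^2) at every frame and the mean is exact in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    innov_sd = spec.sigma * np.sqrt(1.0 - spec.rho**2)
    for rep in range(1, spec.n_replicates + 1):
        for name in COMPONENT_NAMES:
            if name not in spec.means:
                continue
            mu = spec.means[name]
            x = np.empty(spec.frames)
            x[0] = mu + spec.sigma * rng.standard_normal()
            eps = innov_sd * rng.standard_normal(spec.frames - 1)
            for t in range(1, spec.frames):
                x[t] = mu + spec.rho * (x[t - 1] - mu) + eps[t - 1]
            state, interaction = _COMPONENT_STATE[name]
            out.append(
                EnergySeries(
                    state=state, interaction=interaction, values=x, replicate_id=rep
                )
            )
    return out


# ---------------------------------------------------------------------------
# Kinetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticGeneratorSpec:
    """Initial-velocity generator on the assay concentration grids."""

    params: KineticParameters
    substrate_grid: tuple[float, ...] = CDNB_GRID
    inhibitor_grid: tuple[float, ...] = INHIBITOR_GRID
    noise_cv: float = 0.02           # multiplicative gaussian CV
    noise_sd: float = 0.0            # additive gaussian SD (velocity units)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.substrate_grid or not self.inhibitor_grid:
            raise InputError("concentration grids must be non-empty")
        if 0.0 not in self.inhibitor_grid:
            raise InputError("inhibitor grid must include 0 (uninhibited control)")
        if any(s <= 0 for s in self.substrate_grid):
            raise InputError("substrate concentrations must be positive")
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise InputError("noise levels must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


def gen_kinetic_data(spec: KineticGeneratorSpec) -> pd.DataFrame:
    """Velocity table from the rate law plus noise; truth kept in ``attrs``."""
    rng = np.random.default_rng(spec.seed)
    S, I = np.meshgrid(spec.substrate_grid, spec.inhibitor_grid, indexing="ij")
    S, I = S.ravel(), I.ravel()
    v_true = velocity(spec.params, S, I)
    rows = []
    for rep in range(1, spec.replicates + 1):
        v = v_true * (1.0 + spec.noise_cv * rng.standard_normal(v_true.shape))
        if spec.noise_sd > 0:
            v = v + spec.noise_sd * rng.standard_normal(v_true.shape)
        rows.append(
            pd.DataFrame(
                {SUBSTRATE_COL: S, INHIBITOR_COL: I, VELOCITY_COL: v, REPLICATE_COL: rep}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["truth"] = asdict(spec.params)
    df.attrs["spec"] = {
        "noise_cv": spec.noise_cv,
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "seed": spec.seed,
    }
    return df


# ---------------------------------------------------------------------------
# Toy complex trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryGeneratorSpec:
    """Jittered rigid-template trajectory generator settings.

    ``p_hbond`` is the per-frame Bernoulli probability that the designated
    donor-acceptor pair is in its bonded geometry.  Frame 0 is always the
    unperturbed template (the "initial docked configuration" reference);
    jitter and the hydrogen-bond draw apply from frame 1 on.
    """

    sigma: float = 0.2          # iid per-coordinate jitter, A
    drift_per_frame: tuple[float, float, float] | None = None
    p_hbond: float = 1.0
    frames: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")
        if not (0.0 <= self.p_hbond <= 1.0):
            raise InputError("p_hbond must lie in [0, 1]")
        if self.frames < 1:
            raise InputError("frames must be >= 1")


def toy_complex_template() -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Hard-coded toy protein-ligand complex (six residues + phenol ligand).

    The protein fragment is a schematic extended backbone with a
    phenylalanine whose ring stacks under the ligand ring (centroids 3.8 A,
    parallel) and a glutamine whose side-chain OE1 accepts a hydrogen bond
    from the ligand hydroxyl (O...O 2.9 A, D-H...A = 180 deg).  Returns the
    atom table, template coordinates and a layout dictionary naming the
    toggling side-chain atoms and their displaced (bond-broken) positions.
    """
    atoms: list[tuple] = []  # (name, element, res_name, res_id, chain, role)
    coords: list[tuple] = []

    def add(name, element, res_name, res_id, chain, role, xyz):
        atoms.append((name, element, res_name, res_id, chain, role))
        coords.append(xyz)

    # Backbone anchors spread in all three dimensions around the ligand
    # (centred near (8.2, 2, 8)); a well-conditioned scaffold keeps the
    # rotational fit stable under per-atom jitter.
    res_names = ["GLY", "ALA", "PHE", "GLN", "VAL", "GLY"]
    anchors = [
        (2.0, 2.0, 2.0),
        (8.0, -4.0, 3.0),
        (7.0, 6.0, 2.0),
        (15.0, 0.0, 4.0),
        (8.0, 8.0, 6.0),
        (3.0, -2.0, 8.0),
    ]
    for i, (rn, (x, y, z)) in enumerate(zip(res_names, anchors), start=1):
        add("N", "N", rn, i, "A", "protein", (x, y, z))
        add("CA", "C", rn, i, "A", "protein", (x + 1.2, y + 1.0, z + 0.3))
        add("C", "C", rn, i, "A", "protein", (x + 2.4, y + 0.3, z))
        add("O", "O", rn, i, "A", "protein", (x + 2.4, y - 0.9, z + 0.3))
    # ALA2 side chain
    add("CB", "C", "ALA", 2, "A", "protein", (9.2, -2.0, 4.3))
    # PHE3 side chain: ring centred at (8.2, 2.0, 4.2), plane normal +z
    add("CB", "C", "PHE", 3, "A", "protein", (8.2, 4.6, 3.0))
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for k, nm in enumerate(ring_names):
        th = np.radians(60.0 * k)
        add(nm, "C", "PHE", 3, "A", "protein",
            (8.2 + 1.39 * np.cos(th), 2.0 + 1.39 * np.sin(th), 4.2))
    # GLN4 side chain; OE1 is the hydrogen-bond acceptor
    add("CB", "C", "GLN", 4, "A", "protein", (12.0, 2.0, 1.2))
    add("CG", "C", "GLN", 4, "A", "protein", (12.2, 2.0, 2.6))
    add("CD", "C", "GLN", 4, "A", "protein", (12.41, 2.0, 4.0))
    add("OE1", "O", "GLN", 4, "A", "protein", (12.41, 2.0, 5.49))
    add("NE2", "N", "GLN", 4, "A", "protein", (13.5, 2.0, 3.4))
    # VAL5 side chain
    add("CB", "C", "VAL", 5, "A", "protein", (9.0, 7.8, 6.9))
    add("CG1", "C", "VAL", 5, "A", "protein", (8.6, 7.0, 7.9))
    add("CG2", "C", "VAL", 5, "A", "protein", (10.2, 7.2, 6.5))

    # Ligand: phenol ring centred at (8.2, 2.0, 8.0), parallel to PHE ring
    for k in range(6):
        th = np.radians(60.0 * k)
        add(f"C{k+1}", "C", "LIG", 1, "L", "ligand",
            (8.2 + 1.39 * np.cos(th), 2.0 + 1.39 * np.sin(th), 8.0))
    # hydroxyl on C1 pointing toward OE1; O...OE1 distance 2.9 A
    o1 = np.array([10.96, 2.0, 8.0])
    u = np.array([0.5, 0.0, -np.sqrt(1 - 0.25)])  # unit vector toward acceptor
    add("O1", "O", "LIG", 1, "L", "ligand", tuple(o1))
    add("H1", "H", "LIG", 1, "L", "ligand", tuple(o1 + 0.97 * u))

    atoms_df = pd.DataFrame(
        atoms, columns=["name", "element", "res_name", "res_id", "chain", "role"]
    )
    xyz = np.array(coords, dtype=float)

    # sanity: acceptor position equals o1 + 2.9*u (kept consistent by hand)
    acc_idx = atoms_df.index[
        (atoms_df["name"] == "OE1") & (atoms_df["res_id"] == 4)
    ][0]
    xyz[acc_idx] = o1 + 2.9 * u

    toggle_names = ["CD", "OE1", "NE2"]
    toggle_idx = atoms_df.index[
        (atoms_df["res_name"] == "GLN") & (atoms_df["name"].isin(toggle_names))
    ].to_numpy()
    layout = {
        "hbond": {
            "ligand_atom": "O1",
            "protein_atom": "OE1",
            "res_name": "GLN",
            "res_id": 4,
            "distance": 2.9,
        },
        "toggle_idx": toggle_idx,
        "toggle_shift": np.array([0.0, -6.0, 0.0]),
    }
    return atoms_df, xyz, layout


def gen_toy_trajectory(
    spec: TrajectoryGeneratorSpec,
) -> tuple[Trajectory, dict]:
    """Jittered toy-complex trajectory plus a ground-truth manifest.

    Frames are template + iid N(0, sigma^2) per coordinate (+ optional
    cumulative rigid drift).  In frames where the Bernoulli(p_hbond) draw is
    0, the glutamine side-chain tip is swung away so the hydrogen-bond
    criteria cannot fire; ligand atoms are never moved by the toggle, so
    ligand RMSD/RMSF ground truths are unaffected by p_hbond.
    """
    atoms, template, layout = toy_complex_template()
    rng = np.random.default_rng(spec.seed)
    n_atoms = template.shape[0]
    coords = np.empty((spec.frames, n_atoms, 3))
    formed = np.ones(spec.frames, dtype=bool)
    coords[0] = template
    if spec.frames > 1:
        formed[1:] = rng.random(spec.frames - 1) < spec.p_hbond
    for k in range(1, spec.frames):
        frame = template.copy()
        if not formed[k]:
            frame[layout["toggle_idx"]] += layout["toggle_shift"]
        frame += spec.sigma * rng.standard_normal((n_atoms, 3))
        if spec.drift_per_frame is not None:
            frame += np.asarray(spec.drift_per_frame) * k
        coords[k] = frame
    traj = Trajectory(coords=coords, atoms=atoms)
    manifest = {
        "sigma": spec.sigma,
        "p_hbond": spec.p_hbond,
        "frames": spec.frames,
        "seed": spec.seed,
        "drift_per_frame": spec.drift_per_frame,
        "rmsf_truth": spec.sigma * float(np.sqrt(3.0)),
        "formed_fraction": float(formed.mean()),
        "hbond": layout["hbond"],
    }
    return traj, manifest
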