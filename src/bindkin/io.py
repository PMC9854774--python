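"""Readers/writers for the package's file dialects and the run configuration.

Formats
-------
* Energy tables: CSV/TSV with header ``frame, replicate, state, vdw, ele``;
  ``state`` is one of ``bound | free | bound_q0``.  ``bound_q0`` rows carry
  only an electrostatic energy (the vdW cell may be blank); all other rows
  need both.
* Kinetics tables: CSV with ``substrate_uM, inhibitor_uM, velocity,
  replicate``; lines starting with ``#`` are comments (used for ground-truth
  provenance headers).
* Dose-response tables: CSV with ``conc_uM, response_pct``.
* Coordinate trajectories: multi-model PDB (MODEL/ENDMDL), read and written
  through biotite; author residue numbering is passed through verbatim.
* Run configuration: a namespaced YAML file; flags override config, config
  overrides defaults.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError
from .energetics import EnergySeries, Interaction, LIECoefficients, State, ThermoConstants
from .interactions import InteractionCriteria
from .trajgeom import Trajectory

_STATE_LABELS = {"bound": State.BOUND, "free": State.FREE, "bound_q0": State.BOUND_Q0}

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN"}


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------


def read_energy_table(path: str | Path) -> list[EnergySeries]:
    """Parse an energy CSV/TSV into series grouped by (state, component, replicate)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"frame", "replicate", "state", "vdw", "ele"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"energy table must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            state_label = row["state"].strip()
            state = _STATE_LABELS.get(state_label)
            if state is None:
                raise ParseError(f"unknown state label {state_label!r}", line=lineno)
            try:
                rep = int(row["replicate"])
            except ValueError:
                raise ParseError(
                    f"non-integer replicate {row['replicate']!r}", line=lineno
                ) from None
            ele_txt = (row["ele"] or "").strip()
            vdw_txt = (row["vdw"] or "").strip()
            if not ele_txt:
                raise ParseError("missing electrostatic energy", line=lineno)
            try:
                ele = float(ele_txt)
            except ValueError:
                raise ParseError(f"non-numeric energy {ele_txt!r}", line=lineno) from None
            groups.setdefault((state, Interaction.ELE, rep), []).append(ele)
            if (state, Interaction.ELE, rep) not in order:
                order.append((state, Interaction.ELE, rep))
            if state is State.BOUND_Q0:
                continue  # vdW cell optional (and ignored) for uncharged rows
            if not vdw_txt:
                raise ParseError("missing vdW energy", line=lineno)
            try:
                vdw = float(vdw_txt)
            except ValueError:
                raise ParseError(f"non-numeric energy {vdw_txt!r}", line=lineno) from None
            groups.setdefault((state, Interaction.VDW, rep), []).append(vdw)
            if (state, Interaction.VDW, rep) not in order:
                order.append((state, Interaction.VDW, rep))
    if not groups:
        raise ParseError("energy table contains no data rows")
    return [
        EnergySeries(state=s, interaction=i, values=np.array(v), replicate_id=r)
        for (s, i, r), v in ((k, groups[k]) for k in order)
    ]


def write_energy_table(series: list[EnergySeries], path: str | Path) -> None:
    """Write series to the energy CSV/TSV dialect (round-trips losslessly)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # regroup into per-(state, replicate) frames with vdw/ele columns
    table: dict[tuple[State, int], dict[str, np.ndarray]] = {}
    for s in series:
        slot = table.setdefault((s.state, s.replicate_id), {})
        key = s.interaction.value
        if key in slot:
            raise InputError(
                f"duplicate {key} series for state {s.state.value}, "
                f"replicate {s.replicate_id}"
            )
        slot[key] = s.values
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["frame", "replicate", "state", "vdw", "ele"])
        for (state, rep), slot in table.items():
            if "ele" not in slot:
                raise InputError(
                    f"state {state.value} replicate {rep} lacks an ele series"
                )
            n = len(slot["ele"])
            vdw = slot.get("vdw")
            if state is not State.BOUND_Q0 and vdw is None:
                raise InputError(
                    f"state {state.value} replicate {rep} lacks a vdw series"
                )
            if vdw is not None and len(vdw) != n:
                raise InputError("vdw and ele series lengths differ within a state")
            for k in range(n):
                w.writerow(
                    [
                        k,
                        rep,
                        state.value,
                        repr(float(vdw[k])) if vdw is not None else "",
                        repr(float(slot["ele"][k])),
                    ]
                )


# ---------------------------------------------------------------------------
# Kinetics / dose-response tables
# ---------------------------------------------------------------------------


def read_kinetics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"substrate_uM", "inhibitor_uM", "velocity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"kinetics CSV missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df


def write_kinetics_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a kinetics table; ground-truth ``attrs`` go into ``#`` headers."""
    with open(path, "w") as fh:
        for key, value in df.attrs.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"conc_uM", "response_pct"} - set(df.columns)
    if missing:
        raise ParseError(f"dose-response CSV missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Multi-model PDB trajectories
# ---------------------------------------------------------------------------


def _role_of(res_name: str, hetero: bool) -> str:
    if res_name in _WATER_NAMES or res_name in _ION_NAMES:
        return "other"
    return "ligand" if hetero else "protein"


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    The atom table is taken from the first model; every model must have the
    same atoms.  Elements fall back to the first letter of the atom name
    where the element column is blank.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdbf = PDBFile.read(str(path))
        stack = pdbf.get_structure(model=None)
    except Exception as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    elements = [
        el if el else (nm.strip()[:1].upper() if nm.strip() else "")
        for el, nm in zip(stack.element, stack.atom_name)
    ]
    atoms = pd.DataFrame(
        {
            "name": stack.atom_name,
            "element": elements,
            "res_name": stack.res_name,
            "res_id": stack.res_id.astype(int),
            "chain": stack.chain_id,
            "role": [
                _role_of(rn, het) for rn, het in zip(stack.res_name, stack.hetero)
            ],
        }
    )
    return Trajectory(coords=coords, atoms=atoms)


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB with element columns."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    atoms = traj.atoms
    stack.coord = traj.coords.astype(np.float32)
    stack.atom_name = atoms["name"].to_numpy(dtype="U6")
    stack.element = atoms["element"].to_numpy(dtype="U2")
    stack.res_name = atoms["res_name"].to_numpy(dtype="U5")
    stack.res_id = atoms["res_id"].to_numpy(dtype=int)
    stack.chain_id = atoms["chain"].to_numpy(dtype="U4")
    stack.hetero = (atoms["role"] != "protein").to_numpy()
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Package-wide defaults; every field's default is the analysis-faithful value."""

    lie: LIECoefficients = field(default_factory=LIECoefficients)
    thermo: ThermoConstants = field(default_factory=ThermoConstants)
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    ftest_alpha: float = 0.05
    weighting: str = "relative"
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "lie" in raw:
            kwargs["lie"] = LIECoefficients(**raw["lie"])
        if "thermo" in raw:
            kwargs["thermo"] = ThermoConstants(**raw["thermo"])
        if "criteria" in raw:
            crit = dict(raw["criteria"])
            if "pistack_angle_windows" in crit:
                crit["pistack_angle_windows"] = tuple(
                    tuple(w) for w in crit["pistack_angle_windows"]
                )
            kwargs["criteria"] = InteractionCriteria(**crit)
        for key in ("ftest_alpha", "weighting", "seed", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "lie": asdict(self.lie),
            "thermo": asdict(self.thermo),
            "criteria": {
                **asdict(self.criteria),
                "pistack_angle_windows": [
                    list(w) for w in self.criteria.pistack_angle_windows
                ],
            },
            "ftest_alpha": self.ftest_alpha,
            "weighting": self.weighting,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
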