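"""Linear interaction energy (LIE) and linear response approximation (LRA)
binding free energies.

Both estimators post-process molecular-dynamics interaction-energy series
sampled for a ligand L in two physical states: bound to the solvated protein
binding site (P) and free in aqueous solution (W).  With component averages
in kcal/mol,

    dG_LIE = alpha * (<V_vdw^{L-P}> - <V_vdw^{L-W}>)
           + beta  * (<V_ele^{L-P}> - <V_ele^{L-W}>)

    dG_LRA = dG_LIE + beta * <V_ele^{L-P}>_0

where <V_ele^{L-P}>_0 is the ligand-protein electrostatic energy averaged
over configurations generated with all ligand partial charges set to zero
(the "preorganized electrostatics" of the binding site).  The default
coefficients are alpha = 0.5 and beta = 1.043, the cytochrome-P450cam
refinement of the original Aqvist parametrisation (beta = 0.16, exposed as
:data:`AQVIST_BETA` but never applied silently).

Experimental binding free energies derive from inhibition constants via
dG = R*T*ln(Ki / c_ref) with c_ref = 1 M.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default analysis temperature for Ki -> dG conversion (K).
DEFAULT_TEMPERATURE_K = 310.15

#: Original electrostatic coefficient of the Aqvist LIE scheme.
AQVIST_BETA = 0.16


class State(str, enum.Enum):
    """Physical state of the simulated ligand."""

    BOUND = "bound"          # ligand bound to the solvated protein site
    FREE = "free"            # ligand free in water
    BOUND_Q0 = "bound_q0"    # bound, ligand partial charges set to zero


class Interaction(str, enum.Enum):
    VDW = "vdw"
    ELE = "ele"


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame interaction energies (kcal/mol) for one state/component.

    The uncharged-ligand state only has an electrostatic component; its vdW
    energies are identical to the charged bound state and are never stored.
    """

    state: State
    interaction: Interaction
    values: np.ndarray
    replicate_id: int = 1

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size == 0:
            raise InputError("energy series must be non-empty")
        if not np.all(np.isfinite(values)):
            raise InputError("energy series contains non-finite values")
        if self.state is State.BOUND_Q0 and self.interaction is not Interaction.ELE:
            raise InputError(
                "bound_q0 series exist only for the electrostatic component"
            )
        if self.replicate_id < 1:
            raise InputError("replicate_id must be >= 1")


@dataclass(frozen=True)
class EnergyComponents:
    """The averaged interaction energies entering the LIE/LRA estimators.

    ``ele_bound_uncharged`` (<V_ele^{L-P}>_0) is optional: required for LRA,
    ignored by LIE.
    """

    vdw_bound: float
    vdw_free: float
    ele_bound: float
    ele_free: float
    ele_bound_uncharged: float | None = None

    def __post_init__(self):
        vals = [self.vdw_bound, self.vdw_free, self.ele_bound, self.ele_free]
        if self.ele_bound_uncharged is not None:
            vals.append(self.ele_bound_uncharged)
        if not all(math.isfinite(v) for v in vals):
            raise InputError("energy components must be finite")


@dataclass(frozen=True)
class LIECoefficients:
    alpha: float = 0.5
    beta: float = 1.043

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise InputError("LIE coefficients must be positive")


@dataclass(frozen=True)
class ThermoConstants:
    """Constants for converting inhibition constants to free energies."""

    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K
    c_ref: float = 1.0  # reference concentration, M

    def __post_init__(self):
        if self.T <= 0 or self.R <= 0 or self.c_ref <= 0:
            raise InputError("thermodynamic constants must be positive")


@dataclass(frozen=True)
class BindingFreeEnergy:
    """A binding free energy estimate in kcal/mol."""

    method: str  # "LIE" | "LRA" | "experimental"
    mean: float
    sd: float | None = None
    n_replicates: int = 1

    def __post_init__(self):
        if (self.sd is not None) != (self.n_replicates >= 2):
            raise InputError("sd must be present iff n_replicates >= 2")
        if self.sd is not None and self.sd < 0:
            raise InputError("sd must be non-negative")


def average_energy(series: EnergySeries) -> float:
    """Arithmetic mean of a per-frame energy series (kcal/mol)."""
    return float(np.mean(series.values))


def lie_free_energy(
    c: EnergyComponents, k: LIECoefficients = LIECoefficients()
) -> BindingFreeEnergy:
    """LIE binding free energy from averaged components."""
    dg = k.alpha * (c.vdw_bound - c.vdw_free) + k.beta * (c.ele_bound - c.ele_free)
    return BindingFreeEnergy(method="LIE", mean=dg)


def lra_free_energy(
    c: EnergyComponents, k: LIECoefficients = LIECoefficients()
) -> BindingFreeEnergy:
    """LRA binding free energy: LIE plus the preorganized-electrostatics term."""
    if c.ele_bound_uncharged is None:
        raise InputError("LRA requires the uncharged-ligand electrostatic term")
    base = lie_free_energy(c, k).mean
    return BindingFreeEnergy(method="LRA", mean=base + k.beta * c.ele_bound_uncharged)


def aggregate_replicates(
    per_replicate: Sequence[BindingFreeEnergy],
) -> BindingFreeEnergy:
    """Mean and sample SD (n-1 denominator) of per-replicate free energies."""
    if len(per_replicate) < 2:
        raise InputError("replicate aggregation requires >= 2 replicates")
    methods = {r.method for r in per_replicate}
    if len(methods) != 1:
        raise InputError(f"cannot aggregate mixed methods: {sorted(methods)}")
    values = [r.mean for r in per_replicate]
    return BindingFreeEnergy(
        method=methods.pop(),
        mean=statistics.fmean(values),
        sd=statistics.stdev(values),
        n_replicates=len(values),
    )


def ki_to_free_energy(
    ki_molar: float, t: ThermoConstants = ThermoConstants()
) -> BindingFreeEnergy:
    """Experimental binding free energy dG = R*T*ln(Ki / c_ref).

    ``ki_molar`` is the inhibition constant in mol/L.  The conversion is
    strictly increasing in Ki; Ki = c_ref gives 0.
    """
    if not (ki_molar > 0):
        raise InputError("Ki must be positive")
    dg = t.R * t.T * math.log(ki_molar / t.c_ref)
    return BindingFreeEnergy(method="experimental", mean=dg)


# ---------------------------------------------------------------------------
# Replicate-level pipeline helpers
# ---------------------------------------------------------------------------

_COMPONENT_KEYS = {
    (State.BOUND, Interaction.VDW): "vdw_bound",
    (State.FREE, Interaction.VDW): "vdw_free",
    (State.BOUND, Interaction.ELE): "ele_bound",
    (State.FREE, Interaction.ELE): "ele_free",
    (State.BOUND_Q0, Interaction.ELE): "ele_bound_uncharged",
}


def components_by_replicate(
    series: Iterable[EnergySeries],
) -> dict[int, EnergyComponents]:
    """Group series by replicate and average each into :class:`EnergyComponents`.

    Every replicate must provide the four charged-state components; the
    uncharged term is optional but, when present for any replicate, must be
    present for all of them.
    """
    by_rep: dict[int, dict[str, float]] = {}
    for s in series:
        key = _COMPONENT_KEYS[(s.state, s.interaction)]
        rep = by_rep.setdefault(s.replicate_id, {})
        if key in rep:
            raise InputError(
                f"duplicate series for replicate {s.replicate_id}, component {key}"
            )
        rep[key] = average_energy(s)
    if not by_rep:
        raise InputError("no energy series provided")
    required = {"vdw_bound", "vdw_free", "ele_bound", "ele_free"}
    has_q0 = [("ele_bound_uncharged" in rep) for rep in by_rep.values()]
    if any(has_q0) and not all(has_q0):
        raise InputError("uncharged-ligand term present for only some replicates")
    out = {}
    for rep_id, comp in sorted(by_rep.items()):
        missing = required - comp.keys()
        if missing:
            raise InputError(
                f"replicate {rep_id} is missing components: {sorted(missing)}"
            )
        out[rep_id] = EnergyComponents(**comp)
    return out


def free_energy_from_series(
    series: Iterable[EnergySeries],
    method: str = "LIE",
    k: LIECoefficients = LIECoefficients(),
) -> BindingFreeEnergy:
    """Full pipeline: average series per replicate, estimate, aggregate.

    With a single replicate the per-replicate estimate is returned directly
    (no SD); with two or more, the replicate mean +- sample SD.
    """
    comps = components_by_replicate(series)
    estimator = {"LIE": lie_free_energy, "LRA": lra_free_energy}.get(method.upper())
    if estimator is None:
        raise InputError(f"unknown method {method!r}; expected LIE or LRA")
    per_rep = [estimator(c, k) for c in comps.values()]
    if len(per_rep) == 1:
        return per_rep[0]
    return aggregate_replicates(per_rep)
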