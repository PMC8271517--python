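"""Free-energy assembly variants and pH = 0 reduction thermodynamics.

A species' solution free energy G_sol is assembled from the components on
its :class:`~phredox.core.SpeciesState` according to an
:class:`AssemblyVariant`: which geometry the electronic energy comes from,
how solvation is treated, and whether the gas-phase thermal contribution
(zero-point energy + vibrational enthalpy and entropy) is added.  The
variants mirror the levels of approximation commonly compared when
benchmarking redox potentials:

* ``gas`` / ``none`` — bare gas-phase electronic energy;
* ``solvent`` / ``optimized`` — electronic energy optimized in implicit
  solvent (solvation built in);
* ``gas`` / ``single_point`` or ``additive`` — gas-phase energy plus a
  separately computed solvation free energy.

The reduction free energy of Ox + n e- + np H+ -> Red at pH 0 is

    dG_sol = G_sol(Red) - G_sol(Ox) + np * dG_s(H+)

and the standard potential against SHE follows as

    U0 = -dG_sol / n - U_SHE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

from .core import (
    Constants,
    MissingComponentError,
    PhredoxError,
    RedoxCouple,
    SpeciesState,
)

logger = logging.getLogger("phredox")

#: Potentials outside this window are unusual for aqueous organics and are
#: logged as warnings (the arithmetic itself is general and never rejects).
_PLAUSIBLE_RANGE_V = (-3.0, 3.0)

Geometry = Literal["gas", "solvent"]
Solvation = Literal["none", "single_point", "optimized", "additive"]
ThermalPhase = Literal["gas", "solvent"]


@dataclass(frozen=True)
class AssemblyVariant:
    """Recipe for assembling G_sol from free-energy components."""

    geometry: Geometry = "solvent"
    solvation: Solvation = "optimized"
    thermal: bool = True
    thermal_phase: ThermalPhase = "gas"

    def __post_init__(self) -> None:
        if self.geometry not in ("gas", "solvent"):
            raise PhredoxError(f"unknown geometry {self.geometry!r}")
        if self.solvation not in ("none", "single_point", "optimized", "additive"):
            raise PhredoxError(f"unknown solvation mode {self.solvation!r}")
        if self.solvation == "optimized" and self.geometry != "solvent":
            raise PhredoxError(
                "solvation='optimized' means optimization in solvent; "
                "use geometry='solvent'"
            )
        if self.solvation in ("single_point", "additive") and self.geometry != "gas":
            raise PhredoxError(
                f"solvation={self.solvation!r} adds a solvation term to the "
                "gas-phase energy; use geometry='gas'"
            )
        if self.thermal_phase not in ("gas", "solvent"):
            raise PhredoxError(f"unknown thermal phase {self.thermal_phase!r}")

    @property
    def label(self) -> str:
        parts = [self.geometry, self.solvation]
        if self.thermal:
            parts.append(f"thermal[{self.thermal_phase}]")
        return "+".join(parts)


#: The protocol's recommended variant: optimization in implicit solvent plus
#: the gas-phase thermal contribution.
STANDARD_VARIANT = AssemblyVariant("solvent", "optimized", True, "gas")


def _require(s: SpeciesState, name: str, variant: AssemblyVariant) -> float:
    value = getattr(s, name)
    if value is None:
        raise MissingComponentError(
            f"species {s.id!r}: variant {variant.label!r} requires field "
            f"{name!r}, which is missing"
        )
    return value


def assemble_free_energy(s: SpeciesState, v: AssemblyVariant) -> float:
    """Solution free energy of ``s`` in eV under variant ``v``.

    Raises :class:`MissingComponentError` naming the variant and the missing
    field if the species lacks a required component.
    """
    if v.solvation == "optimized":
        g = _require(s, "energy_solvent_opt", v)
    elif v.solvation == "none":
        g = _require(s, "energy_gas", v)
    else:  # single_point / additive: gas-phase energy + solvation term
        g = _require(s, "energy_gas", v) + _require(s, "dG_solvation", v)
    if v.thermal:
        field = (
            "thermal_correction_gas"
            if v.thermal_phase == "gas"
            else "thermal_correction_solvent"
        )
        g += _require(s, field, v)
    return g


def reduction_free_energy(
    g_red: float, g_ox: float, n_protons: int, c: Constants
) -> float:
    """Reduction free energy dG_sol in eV at pH 0.

    The np protons consumed from solution contribute np * dG_s(H+); only the
    difference of the species free energies enters, so any common energy
    offset cancels.
    """
    if not (math.isfinite(g_red) and math.isfinite(g_ox)):
        raise PhredoxError("free energies must be finite")
    return g_red - g_ox + n_protons * c.dG_solv_proton


def potential_ph0(dG: float, n_electrons: int, c: Constants) -> float:
    """Standard redox potential U0 = -dG/n - U_SHE in volts."""
    if n_electrons < 1:
        raise PhredoxError(f"n_electrons must be >= 1, got {n_electrons}")
    u = -dG / n_electrons - c.U_SHE
    lo, hi = _PLAUSIBLE_RANGE_V
    if not lo <= u <= hi:
        logger.warning(
            "potential %.3f V outside the plausible aqueous window [%g, %g] V",
            u,
            lo,
            hi,
        )
    return u


def couple_potential(
    couple: RedoxCouple,
    c: Constants,
    variant: AssemblyVariant = STANDARD_VARIANT,
) -> tuple[float, float]:
    """Assemble both species and return (dG_sol in eV, U0 in volts)."""
    g_ox = assemble_free_energy(couple.ox, variant)
    g_red = assemble_free_energy(couple.red, variant)
    dG = reduction_free_energy(g_red, g_ox, couple.n_protons, c)
    return dG, potential_ph0(dG, couple.n_electrons, c)
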