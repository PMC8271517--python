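"""Domain types, physical constants, and redox stoichiometry.

Everything downstream works in a single unit convention: free energies and
their components in electron-volts (eV), electrode potentials in volts
referenced to the standard hydrogen electrode (SHE), temperatures in kelvin.
Unit conversion (e.g. from hartree) happens only at the I/O boundary.

The central half-reaction is the proton-coupled reduction

    Ox + n e- + np H+  ->  Red

whose stoichiometry (n electrons, np protons) is derived from the hydrogen
counts and formal charges of the two species rather than supplied by the
user, so every couple is atom- and charge-balanced by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import constants as _codata

logger = logging.getLogger("phredox")

LN10 = math.log(10.0)

#: Boltzmann constant expressed in eV per kelvin (CODATA).
BOLTZMANN_EV = _codata.Boltzmann / _codata.elementary_charge

#: Hartree-to-eV conversion used by the I/O layer.
HARTREE_EV = 27.211386


class PhredoxError(ValueError):
    """Base class for domain validation errors."""


class StoichiometryError(PhredoxError):
    """Half-reaction cannot be balanced under the reduction convention."""


class MissingComponentError(PhredoxError):
    """A free-energy component required by the selected variant is absent."""


class LadderError(PhredoxError):
    """A pKa ladder is inconsistent with the species' hydrogen count."""


class DomainError(PhredoxError):
    """Evaluation requested outside a curve's pH domain."""


def nernst_slope_at(T: float) -> float:
    """Nernst slope kB*T*ln(10)/e in eV per pH unit.

    Numerically equal to the potential shift in volts per pH unit for a
    couple transferring one proton per electron; 0.0591597 eV at 298.15 K.

    Parameters
    ----------
    T : float
        Temperature in kelvin; must be strictly positive.
    """
    if T <= 0:
        raise PhredoxError(f"temperature must be positive, got {T}")
    return BOLTZMANN_EV * T * LN10


@dataclass
class Constants:
    """Physical constants and conventions of the protocol.

    The defaults are the conventional literature values for aqueous systems:
    an absolute SHE potential of 4.43 V and a proton solvation free energy
    of -11.38 eV.  Both values are debated in the literature and which pair
    is consistent with a given implicit-solvation model is an open question,
    so they are run-time configuration, not hard-coded literals.

    ``kT_eV`` and ``nernst_slope`` are derived properties of ``T`` and are
    recomputed on every access, so mutating ``T`` keeps them consistent.
    """

    U_SHE: float = 4.43  #: absolute SHE potential, volts
    dG_solv_proton: float = -11.38  #: proton solvation free energy, eV
    T: float = 298.15  #: temperature, kelvin
    water_molarity: float = 55.34  #: concentration of liquid water, mol/L
    gas_to_molar: float = 24.46  #: ideal-gas molar volume at 1 atm, L/mol

    def __post_init__(self) -> None:
        if self.U_SHE <= 0:
            raise PhredoxError("U_SHE must be strictly positive")
        if self.dG_solv_proton >= 0:
            raise PhredoxError("dG_solv_proton must be strictly negative")
        if self.T <= 0:
            raise PhredoxError("temperature must be strictly positive")
        if self.water_molarity <= 0 or self.gas_to_molar <= 0:
            raise PhredoxError("standard-state concentrations must be positive")

    @property
    def kT_eV(self) -> float:
        """Thermal energy kB*T in eV."""
        return BOLTZMANN_EV * self.T

    @property
    def nernst_slope(self) -> float:
        """kB*T*ln(10) in eV per pH unit (0.0591597 at 298.15 K)."""
        return nernst_slope_at(self.T)


def _smiles_hydrogen_count(smiles: str) -> Optional[int]:
    """Total hydrogen count (explicit + implicit) of a SMILES, or None if
    RDKit is not installed."""
    try:
        from rdkit import Chem
    except ImportError:  # pragma: no cover - rdkit optional
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PhredoxError(f"invalid SMILES string: {smiles!r}")
    mol = Chem.AddHs(mol)
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() == 1)


@dataclass
class SpeciesState:
    """One molecule in a fixed protonation/redox state.

    Free-energy components are all optional because different assembly
    variants need different subsets; at least one variant must be satisfiable
    or the species is useless.  Energies in eV.

    Attributes
    ----------
    id : str
        Opaque identifier; keys the species tables.
    smiles : str, optional
        Structure string.  When present the hydrogen count is cross-checked
        against ``n_hydrogens`` (a mismatch is an error, not a warning).
    n_hydrogens : int
        Hydrogen-atom count of this protonation state (>= 0).
    charge : int
        Formal charge.
    energy_solvent_opt : float, optional
        Electronic energy from a geometry optimization in implicit solvent.
    energy_gas : float, optional
        Gas-phase electronic energy.
    thermal_correction_gas : float, optional
        Gas-phase thermal contribution to the Gibbs free energy (zero-point
        energy + vibrational enthalpy + entropy term).
    thermal_correction_solvent : float, optional
        Solvent-phase thermal contribution; used only when explicitly
        selected (the gas phase is the default and slightly preferred).
    dG_solvation : float, optional
        Stand-alone solvation free energy from a post-hoc solvation model,
        to be added to the gas-phase energy.
    """

    id: str
    n_hydrogens: int
    charge: int
    smiles: Optional[str] = None
    energy_solvent_opt: Optional[float] = None
    energy_gas: Optional[float] = None
    thermal_correction_gas: Optional[float] = None
    thermal_correction_solvent: Optional[float] = None
    dG_solvation: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.n_hydrogens) != self.n_hydrogens or self.n_hydrogens < 0:
            raise PhredoxError(
                f"species {self.id!r}: n_hydrogens must be a non-negative "
                f"integer, got {self.n_hydrogens}"
            )
        self.n_hydrogens = int(self.n_hydrogens)
        self.charge = int(self.charge)
        for name in (
            "energy_solvent_opt",
            "energy_gas",
            "thermal_correction_gas",
            "thermal_correction_solvent",
            "dG_solvation",
        ):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise PhredoxError(f"species {self.id!r}: {name} is not finite")
        if self.smiles is not None:
            nh = _smiles_hydrogen_count(self.smiles)
            if nh is not None and nh != self.n_hydrogens:
                raise PhredoxError(
                    f"species {self.id!r}: SMILES implies {nh} hydrogens but "
                    f"n_hydrogens = {self.n_hydrogens}"
                )


def derive_stoichiometry(ox: SpeciesState, red: SpeciesState) -> tuple[int, int]:
    """Electron and proton counts (n, np) of Ox + n e- + np H+ -> Red.

    Atom balance fixes np = NH(Red) - NH(Ox); charge balance then fixes
    n = np + q(Ox) - q(Red).  Under the reduction convention Red must not
    have fewer hydrogens than Ox (np >= 0) and at least one electron must be
    transferred (n >= 1); anything else is rejected.
    """
    n_protons = red.n_hydrogens - ox.n_hydrogens
    if n_protons < 0:
        raise StoichiometryError(
            f"couple {ox.id!r}/{red.id!r}: Red has fewer hydrogens than Ox "
            f"({red.n_hydrogens} < {ox.n_hydrogens}); not a reduction"
        )
    n_electrons = n_protons + ox.charge - red.charge
    if n_electrons < 1:
        raise StoichiometryError(
            f"couple {ox.id!r}/{red.id!r}: derived electron count "
            f"{n_electrons} < 1; no electron transfer"
        )
    return n_electrons, n_protons


@dataclass
class RedoxCouple:
    """An Ox/Red pair with its derived half-reaction stoichiometry."""

    ox: SpeciesState
    red: SpeciesState
    n_electrons: int = field(init=False)
    n_protons: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_electrons, self.n_protons = derive_stoichiometry(self.ox, self.red)
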