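"""Cluster-continuum solvation: the monomer thermodynamic cycle.

Mixed explicit-implicit solvation embeds a solute-(H2O)n cluster in an
implicit solvent.  The monomer cycle decomposes the solute's solvation free
energy into three pieces:

    dGs_cc(A) = dG_bind(gas) + dGs(A(H2O)n) + n * dG_vap(H2O)

where dG_bind is the gas-phase binding energy of the cluster relative to its
isolated components, dGs(A(H2O)n) is the implicit solvation free energy of
the whole cluster (solvent-phase minus gas-phase energy), and dG_vap is the
free-energy cost of returning each explicit water to the gas phase at the
1 M standard state:

    dG_vap(H2O) = -dGs(H2O) - kT ln(55.34) - kT ln(24.46).

The two logarithmic terms place liquid water (55.34 M) and the 1 atm ideal
gas (24.46 L/mol) in the common 1 M standard state, so the cycle closes.

Several candidate cluster geometries usually exist for each n; their
solvation free energies are Boltzmann-averaged, and the averaged values are
profiled against n to judge convergence to a plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Constants, PhredoxError, RedoxCouple


@dataclass(frozen=True)
class ClusterRecord:
    """Energetics of one solute-(H2O)n cluster candidate (all in eV)."""

    solute_id: str
    n_waters: int
    e_cluster_gas: float
    e_cluster_solvent: float
    e_solute_gas: float
    e_water_gas: float  # per monomer
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_waters < 0:
            raise PhredoxError("n_waters must be >= 0")
        for name in ("e_cluster_gas", "e_cluster_solvent", "e_solute_gas", "e_water_gas"):
            if not math.isfinite(getattr(self, name)):
                raise PhredoxError(f"cluster {self.label!r}: {name} not finite")


@dataclass(frozen=True)
class WaterParams:
    """Water monomer parameters for the cycle: the implicit solvation free
    energy of one water in water (eV)."""

    dG_solv_water: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG_solv_water):
            raise PhredoxError("dG_solv_water must be finite")


def vaporization_dG(w: WaterParams, c: Constants) -> float:
    """Free energy of moving one water from liquid to 1 M gas phase, eV."""
    return (
        -w.dG_solv_water
        - c.kT_eV * math.log(c.water_molarity)
        - c.kT_eV * math.log(c.gas_to_molar)
    )


def cluster_dGs(r: ClusterRecord, w: WaterParams, c: Constants) -> float:
    """Cluster-continuum solvation free energy of the solute, eV.

    At n_waters = 0 the binding and vaporization terms vanish and the result
    degenerates to the plain implicit solvation free energy of the solute.
    """
    binding = r.e_cluster_gas - (r.e_solute_gas + r.n_waters * r.e_water_gas)
    cluster_solvation = r.e_cluster_solvent - r.e_cluster_gas
    return binding + cluster_solvation + r.n_waters * vaporization_dG(w, c)


def boltzmann_average(
    values: Sequence[float], weight_energies: Sequence[float], c: Constants
) -> float:
    """Boltzmann-weighted mean of ``values``.

    Weights are exp(-(E_i - min E) / kT) over ``weight_energies``; the
    min-shift keeps the exponentials in range regardless of the absolute
    energy scale, and the result is invariant under adding a constant to all
    weighting energies.
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(weight_energies, dtype=float)
    if v.size == 0:
        raise PhredoxError("boltzmann_average requires at least one entry")
    if v.shape != e.shape:
        raise PhredoxError("values and weighting energies must have equal length")
    w = np.exp(-(e - e.min()) / c.kT_eV)
    return float(np.sum(v * w) / np.sum(w))


def convergence_profile(
    records: Sequence[ClusterRecord],
    w: WaterParams,
    c: Constants,
    plateau_tol: float = 0.02,
) -> pd.DataFrame:
    """Boltzmann-averaged dGs_cc per explicit-water count, with plateau flags.

    Candidates at the same n share all monomer reference energies, so their
    dGs_cc differences equal their total-free-energy differences; the
    candidates' own dGs_cc values therefore serve as the Boltzmann weighting
    energies.  A row's ``plateau`` flag is True when its averaged value
    differs from the previous n's by less than ``plateau_tol`` (eV); the
    first row is never flagged.

    Returns a DataFrame with columns solute_id, n_waters, dGs_cc_ev, plateau.
    """
    if not records:
        raise PhredoxError("convergence_profile requires at least one record")
    solute_ids = {r.solute_id for r in records}
    if len(solute_ids) > 1:
        raise PhredoxError(f"records mix solutes: {sorted(solute_ids)}")
    by_n: dict[int, list[float]] = {}
    for r in records:
        by_n.setdefault(r.n_waters, []).append(cluster_dGs(r, w, c))
    rows = []
    prev = None
    for n in sorted(by_n):
        avg = boltzmann_average(by_n[n], by_n[n], c)
        plateau = prev is not None and abs(avg - prev) < plateau_tol
        rows.append(
            {
                "solute_id": next(iter(solute_ids)),
                "n_waters": n,
                "dGs_cc_ev": avg,
                "plateau": plateau,
            }
        )
        prev = avg
    return pd.DataFrame(rows)


def cc_potential(
    couple: RedoxCouple,
    g_gas_ox: float,
    g_gas_red: float,
    dGs_cc_ox: float,
    dGs_cc_red: float,
    c: Constants,
) -> float:
    """Redox potential with cluster-continuum solvation, volts.

    Each species' solution free energy is its gas-phase free energy (the
    electronic energy plus thermal contribution, as assembled upstream) plus
    its cluster-continuum solvation free energy; the usual reduction
    free-energy and potential expressions then apply.
    """
    from .thermo import potential_ph0, reduction_free_energy

    g_ox = g_gas_ox + dGs_cc_ox
    g_red = g_gas_red + dGs_cc_red
    dG = reduction_free_energy(g_red, g_ox, couple.n_protons, c)
    return potential_ph0(dG, couple.n_electrons, c)
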