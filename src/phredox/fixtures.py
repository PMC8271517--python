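"""Deterministic synthetic datasets for testing the whole pipeline.

Ground truth is defined in potential space and inverted into energies: each
couple gets a target standard potential U0, a stoichiometry, and pKa
ladders; the generator then solves the potential and reduction-free-energy
expressions backwards for species free energies and splits them arbitrarily
into electronic and thermal components (and into gas + solvation parts, so
every assembly variant is satisfiable).  Running the pipeline forward must
therefore recover U0 exactly at zero noise — the generator and the pipeline
are mutual inverses, which is the basis of the parameter-recovery tests.

Reference "experimental" potentials are the variable-slope Pourbaix curve
values plus Gaussian noise, emulating a benchmark set of proton-coupled
couples spanning a range of potentials; cluster tables are built from a
chosen true solvation plateau plus exponentially decaying deviations.

The numbers are self-consistent, not chemically realistic: no structures,
force fields or electronic-structure data are synthesized.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .benchmark import BenchmarkEntry, mae, mse
from .cluster_continuum import ClusterRecord, WaterParams, vaporization_dG
from .core import Constants, PhredoxError, RedoxCouple, SpeciesState
from .io import (
    PathLike,
    write_benchmark,
    write_clusters,
    write_couples,
    write_pkas,
    write_species,
)
from .protonation import (
    PKaLadder,
    TableProtonationProvider,
    breakpoint_grid,
    midpoint_hydrogens,
)
from .pourbaix import u_curve
from .thermo import STANDARD_VARIANT, couple_potential


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset.

    The defaults emulate the structure of a quinone benchmark set: mostly
    two-electron/two-proton couples with a minority of 1e/1H and 2e/1H
    variants, standard potentials spread over ~0-1.2 V, pKa ladders of up to
    three in-range constants, and 0.1 V Gaussian noise on the reference
    potentials.
    """

    n_couples: int = 20
    seed: int = 0
    u0_range: tuple[float, float] = (0.0, 1.2)
    #: (n_electrons, n_protons) patterns with sampling weights
    stoichiometries: tuple[tuple[int, int], ...] = ((2, 2), (1, 1), (2, 1))
    stoich_weights: tuple[float, ...] = (0.7, 0.15, 0.15)
    max_pkas_red: int = 3
    max_pkas_ox: int = 1
    pka_range: tuple[float, float] = (0.5, 13.5)
    noise_sigma: float = 0.1
    reference_phs: tuple[float, ...] = (0.0, 7.0, 13.0)
    #: explicit-water counts for the cluster tables
    cluster_ns: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    candidates_per_n: int = 3

    def __post_init__(self) -> None:
        if self.n_couples < 1:
            raise PhredoxError("n_couples must be >= 1")
        if len(self.stoichiometries) != len(self.stoich_weights):
            raise PhredoxError("stoichiometries and weights must align")
        if self.noise_sigma < 0:
            raise PhredoxError("noise_sigma must be >= 0")
        for n, np_ in self.stoichiometries:
            if np_ < 0 or n < 1:
                raise PhredoxError(f"invalid stoichiometry ({n}, {np_})")


@dataclass
class FixtureDataset:
    """A generated dataset plus its ground truth."""

    spec: FixtureSpec
    species: dict[str, SpeciesState]
    couples: list[tuple[str, str, str]]
    ladders: dict[str, PKaLadder]
    references: list[BenchmarkEntry]
    clusters: list[ClusterRecord]
    water: WaterParams
    truth: dict

    def couple_objects(self) -> dict[str, RedoxCouple]:
        return {
            cid: RedoxCouple(self.species[ox], self.species[red])
            for cid, ox, red in self.couples
        }

    def write(self, outdir: PathLike) -> None:
        """Emit every interchange schema plus a manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_species(self.species, outdir / "species.csv")
        write_couples(self.couples, outdir / "couples.csv")
        write_pkas(self.ladders, outdir / "pkas.csv")
        write_benchmark(self.references, outdir / "benchmark.csv")
        write_clusters(self.clusters, outdir / "clusters.csv")
        manifest = {
            "spec": dataclasses.asdict(self.spec),
            "water": dataclasses.asdict(self.water),
            "truth": self.truth,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _draw_ladder(
    rng: np.random.Generator,
    species_id: str,
    max_count: int,
    nh: int,
    pka_range: tuple[float, float],
) -> PKaLadder:
    count = int(rng.integers(0, min(max_count, nh) + 1))
    pkas = tuple(sorted(rng.uniform(*pka_range, size=count).tolist()))
    return PKaLadder(species_id, pkas)


def generate(spec: FixtureSpec, c: Optional[Constants] = None) -> FixtureDataset:
    """Build a self-consistent dataset from a :class:`FixtureSpec`.

    Same spec + seed always yields the identical dataset.
    """
    c = c or Constants()
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.stoich_weights, dtype=float)
    weights = weights / weights.sum()

    species: dict[str, SpeciesState] = {}
    couples: list[tuple[str, str, str]] = []
    ladders: dict[str, PKaLadder] = {}
    references: list[BenchmarkEntry] = []
    truth_couples: dict[str, dict] = {}

    for i in range(spec.n_couples):
        cid = f"cpl{i:03d}"
        ox_id, red_id = f"{cid}_ox", f"{cid}_red"
        n, np_ = spec.stoichiometries[rng.choice(len(weights), p=weights)]
        u0 = float(rng.uniform(*spec.u0_range))
        nh_ox = int(rng.integers(4, 9))
        nh_red = nh_ox + np_
        charge_ox = 0
        charge_red = charge_ox + np_ - n

        # invert U0 = -dG/n - U_SHE and dG = g_red - g_ox + np*dGs(H+)
        dG = -n * (u0 + c.U_SHE)
        g_ox = float(rng.uniform(-255.0, -245.0))
        g_red = dG - np_ * c.dG_solv_proton + g_ox

        def split(sid: str, g: float, nh: int, q: int) -> SpeciesState:
            thermal = float(rng.uniform(0.05, 0.25))
            e_solv = g - thermal
            dg_solv = float(rng.uniform(-0.5, -0.1))
            return SpeciesState(
                id=sid,
                n_hydrogens=nh,
                charge=q,
                energy_solvent_opt=e_solv,
                energy_gas=e_solv - dg_solv,
                thermal_correction_gas=thermal,
                dG_solvation=dg_solv,
            )

        species[ox_id] = split(ox_id, g_ox, nh_ox, charge_ox)
        species[red_id] = split(red_id, g_red, nh_red, charge_red)
        ladders[ox_id] = _draw_ladder(
            rng, ox_id, spec.max_pkas_ox, nh_ox, spec.pka_range
        )
        ladders[red_id] = _draw_ladder(
            rng, red_id, spec.max_pkas_red, nh_red, spec.pka_range
        )
        couples.append((cid, ox_id, red_id))
        truth_couples[cid] = {
            "u0_v": u0,
            "n_electrons": n,
            "n_protons": np_,
            "g_sol_ox_ev": g_ox,
            "g_sol_red_ev": g_red,
        }

        couple = RedoxCouple(species[ox_id], species[red_id])
        curve = u_curve(
            couple, g_ox, g_red, ladders[ox_id], ladders[red_id], c, mode="variable"
        )
        # noise goes on the "experimental" reference; u_computed_v holds the
        # noiseless curve value as a placeholder until the pipeline
        # recomputes it
        for ph in spec.reference_phs:
            u_true = curve(ph)
            # draw unconditionally so the rng stream (and hence the rest of
            # the dataset) is identical across noise settings
            noise = float(rng.standard_normal()) * spec.noise_sigma
            references.append(
                BenchmarkEntry(cid, u_true, u_true + noise, ph=ph)
            )

    # cluster tables for the first couple's two species
    water = WaterParams(dG_solv_water=-0.270)
    dG_vap = vaporization_dG(water, c)
    clusters: list[ClusterRecord] = []
    truth_clusters: dict[str, dict] = {}
    first_ox, first_red = couples[0][1], couples[0][2]
    for sid in (first_ox, first_red):
        s = species[sid]
        # n = 0 is the implicit baseline, so the profile starts at the
        # species' own dG_solvation and decays toward a deeper plateau
        plateau = s.dG_solvation - float(rng.uniform(0.2, 0.6))
        amplitude = s.dG_solvation - plateau
        tau = 2.0
        e_water_gas = -470.0
        profile = {}
        for n_w in spec.cluster_ns:
            target = plateau + amplitude * math.exp(-n_w / tau)
            profile[n_w] = target
            n_cand = 1 if n_w == 0 else spec.candidates_per_n
            for k in range(n_cand):
                # candidate spread around the target, first candidate exact
                delta = 0.0 if k == 0 else float(rng.uniform(0.0, 0.01))
                binding = -0.1 * n_w
                e_cluster_gas = s.energy_gas + n_w * e_water_gas + binding
                e_cluster_solvent = (
                    e_cluster_gas + (target + delta) - n_w * dG_vap - binding
                )
                clusters.append(
                    ClusterRecord(
                        solute_id=sid,
                        n_waters=n_w,
                        label=f"{sid}_n{n_w}_c{k}",
                        e_cluster_gas=e_cluster_gas,
                        e_cluster_solvent=e_cluster_solvent,
                        e_solute_gas=s.energy_gas,
                        e_water_gas=e_water_gas,
                    )
                )
        truth_clusters[sid] = {"plateau_ev": plateau, "profile": profile}

    truth = {"couples": truth_couples, "clusters": truth_clusters}
    return FixtureDataset(
        spec=spec,
        species=species,
        couples=couples,
        ladders=ladders,
        references=references,
        clusters=clusters,
        water=water,
        truth=truth,
    )


def protonation_provider(dataset: FixtureDataset) -> TableProtonationProvider:
    """Deterministic provider backed by the generated tables.

    Species ids double as the opaque structure strings (no chemistry is
    synthesized), so the provider is fully canned and reproducible.
    """
    return TableProtonationProvider(
        ladders=dict(dataset.ladders),
        reference_states={
            sid: (sid, s.n_hydrogens, s.charge)
            for sid, s in dataset.species.items()
        },
    )


def _truth_u_curve(
    couple: RedoxCouple,
    u0: float,
    ladder_ox: PKaLadder,
    ladder_red: PKaLadder,
    c: Constants,
) -> tuple[list[float], list[float]]:
    """Potential-space recurrence, independent of the G-space construction:
    U(pH_p) = U(pH_{p-1}) - (NH_red - NH_ox)(mid) * s / n * (pH_p - pH_{p-1})."""
    grid = breakpoint_grid(ladder_ox, ladder_red)
    values = [u0]
    for lo, hi in zip(grid[:-1], grid[1:]):
        d_nh = midpoint_hydrogens(
            couple.red.n_hydrogens, ladder_red, lo, hi
        ) - midpoint_hydrogens(couple.ox.n_hydrogens, ladder_ox, lo, hi)
        values.append(
            values[-1] - d_nh * c.nernst_slope / couple.n_electrons * (hi - lo)
        )
    return grid, values


def recover(dataset: FixtureDataset, c: Optional[Constants] = None) -> dict:
    """Run the full pipeline on a dataset and compare with its ground truth.

    Reports the worst standard-potential error, the worst Pourbaix-curve
    deviation at any breakpoint (against an independent potential-space
    recurrence started from the true U0), and the benchmark statistics of
    the recomputed curves against the stored references.
    """
    c = c or Constants()
    max_du0 = 0.0
    max_curve_dev = 0.0
    entries: list[BenchmarkEntry] = []
    by_ph_ref = {
        (e.couple_id, e.ph): e.u_reference for e in dataset.references
    }
    for cid, ox_id, red_id in dataset.couples:
        couple = RedoxCouple(dataset.species[ox_id], dataset.species[red_id])
        truth = dataset.truth["couples"][cid]
        dG, u0 = couple_potential(couple, c, STANDARD_VARIANT)
        max_du0 = max(max_du0, abs(u0 - truth["u0_v"]))

        from .thermo import assemble_free_energy

        g_ox = assemble_free_energy(couple.ox, STANDARD_VARIANT)
        g_red = assemble_free_energy(couple.red, STANDARD_VARIANT)
        curve = u_curve(
            couple,
            g_ox,
            g_red,
            dataset.ladders[ox_id],
            dataset.ladders[red_id],
            c,
            mode="variable",
        )
        grid, truth_vals = _truth_u_curve(
            couple, truth["u0_v"], dataset.ladders[ox_id], dataset.ladders[red_id], c
        )
        dev = max(abs(curve(p) - v) for p, v in zip(grid, truth_vals))
        max_curve_dev = max(max_curve_dev, dev)
        for ph in dataset.spec.reference_phs:
            entries.append(
                BenchmarkEntry(cid, curve(ph), by_ph_ref[(cid, ph)], ph=ph)
            )
    return {
        "max_abs_du0_v": max_du0,
        "max_curve_dev_v": max_curve_dev,
        "mae_v": mae(entries),
        "mse_v": mse(entries),
        "n_couples": len(dataset.couples),
        "entries": entries,
    }
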