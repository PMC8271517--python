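"""Readers and writers for the tabular interchange schemas, plus run
configuration.

All files are comma-separated UTF-8 with a header row and "." as the decimal
mark.  Energies are exchanged in eV (a ``unit='hartree'`` flag on the
readers converts on load and logs the conversion); potentials in volts.
Missing numeric fields are empty cells.  Unknown columns are preserved on
read but ignored.  Row-level validation errors carry the file line number
(header = line 1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .benchmark import BenchmarkEntry
from .cluster_continuum import ClusterRecord
from .core import HARTREE_EV, PhredoxError, SpeciesState
from .protonation import PKaLadder

logger = logging.getLogger("phredox")

PathLike = Union[str, Path]
Unit = Literal["ev", "hartree"]

SPECIES_COLUMNS = [
    "id",
    "smiles",
    "n_hydrogens",
    "charge",
    "energy_solvent_opt_ev",
    "energy_gas_ev",
    "thermal_correction_gas_ev",
    "dG_solvation_ev",
]
PKA_COLUMNS = ["species_id", "pka"]
COUPLE_COLUMNS = ["couple_id", "ox_id", "red_id"]
CLUSTER_COLUMNS = [
    "solute_id",
    "n_waters",
    "label",
    "e_cluster_gas_ev",
    "e_cluster_solvent_ev",
    "e_solute_gas_ev",
    "e_water_gas_ev",
]
BENCHMARK_COLUMNS = ["couple_id", "ph", "u_computed_v", "u_reference_v"]


def _energy_factor(unit: Unit) -> float:
    if unit == "ev":
        return 1.0
    if unit == "hartree":
        logger.info("converting energies from hartree to eV (x %.6f)", HARTREE_EV)
        return HARTREE_EV
    raise PhredoxError(f"unknown energy unit {unit!r}")


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PhredoxError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PhredoxError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: file contains a header but no rows", path)
    return df


def _cell_float(
    row: pd.Series, col: str, path: PathLike, line: int, optional: bool = False
) -> Optional[float]:
    raw = str(row.get(col, "")).strip()
    if raw == "":
        if optional:
            return None
        raise PhredoxError(f"{path}:{line}: column {col!r} must not be empty")
    try:
        value = float(raw)
    except ValueError:
        raise PhredoxError(
            f"{path}:{line}: malformed numeric cell {raw!r} in column {col!r}"
        ) from None
    if not math.isfinite(value):
        raise PhredoxError(f"{path}:{line}: non-finite value in column {col!r}")
    return value


def _cell_int(row: pd.Series, col: str, path: PathLike, line: int) -> int:
    v = _cell_float(row, col, path, line)
    if v != int(v):
        raise PhredoxError(f"{path}:{line}: column {col!r} must be an integer")
    return int(v)


def read_species(path: PathLike, unit: Unit = "ev") -> dict[str, SpeciesState]:
    """Load a species table into a dict keyed by species id."""
    df = _read_table(path, SPECIES_COLUMNS)
    factor = _energy_factor(unit)
    out: dict[str, SpeciesState] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = str(row["id"]).strip()
        if not sid:
            raise PhredoxError(f"{path}:{line}: empty species id")
        if sid in out:
            raise PhredoxError(f"{path}:{line}: duplicate species id {sid!r}")
        smiles = str(row["smiles"]).strip() or None

        def energy(col: str) -> Optional[float]:
            v = _cell_float(row, col, path, line, optional=True)
            return None if v is None else v * factor

        try:
            out[sid] = SpeciesState(
                id=sid,
                smiles=smiles,
                n_hydrogens=_cell_int(row, "n_hydrogens", path, line),
                charge=_cell_int(row, "charge", path, line),
                energy_solvent_opt=energy("energy_solvent_opt_ev"),
                energy_gas=energy("energy_gas_ev"),
                thermal_correction_gas=energy("thermal_correction_gas_ev"),
                dG_solvation=energy("dG_solvation_ev"),
            )
        except PhredoxError as exc:
            raise PhredoxError(f"{path}:{line}: {exc}") from None
    return out


def read_pkas(path: PathLike) -> dict[str, PKaLadder]:
    """Load a pKa table (one row per constant) into ladders per species."""
    df = _read_table(path, PKA_COLUMNS)
    pkas: dict[str, list[float]] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        sid = str(row["species_id"]).strip()
        if not sid:
            raise PhredoxError(f"{path}:{line}: empty species_id")
        pkas.setdefault(sid, []).append(_cell_float(row, "pka", path, line))
    return {sid: PKaLadder(sid, tuple(vals)) for sid, vals in pkas.items()}


def read_couples(
    path: PathLike, species: Optional[dict[str, SpeciesState]] = None
) -> list[tuple[str, str, str]]:
    """Load a couples manifest as (couple_id, ox_id, red_id) triples.

    When ``species`` is given, every referenced id must resolve.
    """
    df = _read_table(path, COUPLE_COLUMNS)
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2
        cid = str(row["couple_id"]).strip()
        ox_id = str(row["ox_id"]).strip()
        red_id = str(row["red_id"]).strip()
        if not (cid and ox_id and red_id):
            raise PhredoxError(f"{path}:{line}: empty id field")
        if cid in seen:
            raise PhredoxError(f"{path}:{line}: duplicate couple id {cid!r}")
        seen.add(cid)
        if species is not None:
            for sid in (ox_id, red_id):
                if sid not in species:
                    raise PhredoxError(
                        f"{path}:{line}: couple {cid!r} references unknown "
                        f"species {sid!r}"
                    )
        out.append((cid, ox_id, red_id))
    return out


def read_clusters(path: PathLike, unit: Unit = "ev") -> list[ClusterRecord]:
    """Load an explicit-water cluster energy table."""
    df = _read_table(path, CLUSTER_COLUMNS)
    factor = _energy_factor(unit)
    out: list[ClusterRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            out.append(
                ClusterRecord(
                    solute_id=str(row["solute_id"]).strip(),
                    n_waters=_cell_int(row, "n_waters", path, line),
                    label=str(row["label"]).strip(),
                    e_cluster_gas=_cell_float(row, "e_cluster_gas_ev", path, line) * factor,
                    e_cluster_solvent=_cell_float(row, "e_cluster_solvent_ev", path, line) * factor,
                    e_solute_gas=_cell_float(row, "e_solute_gas_ev", path, line) * factor,
                    e_water_gas=_cell_float(row, "e_water_gas_ev", path, line) * factor,
                )
            )
        except PhredoxError as exc:
            raise PhredoxError(f"{path}:{line}: {exc}") from None
    return out


def read_benchmark(path: PathLike) -> list[BenchmarkEntry]:
    """Load computed/reference potential pairs."""
    df = _read_table(path, BENCHMARK_COLUMNS)
    out: list[BenchmarkEntry] = []
    for idx, row in df.iterrows():
        line = idx + 2
        out.append(
            BenchmarkEntry(
                couple_id=str(row["couple_id"]).strip(),
                ph=_cell_float(row, "ph", path, line),
                u_computed=_cell_float(row, "u_computed_v", path, line),
                u_reference=_cell_float(row, "u_reference_v", path, line),
            )
        )
    return out


def write_species(species: dict[str, SpeciesState], path: PathLike) -> None:
    rows = []
    for s in species.values():
        rows.append(
            {
                "id": s.id,
                "smiles": s.smiles or "",
                "n_hydrogens": s.n_hydrogens,
                "charge": s.charge,
                "energy_solvent_opt_ev": s.energy_solvent_opt,
                "energy_gas_ev": s.energy_gas,
                "thermal_correction_gas_ev": s.thermal_correction_gas,
                "dG_solvation_ev": s.dG_solvation,
            }
        )
    pd.DataFrame(rows, columns=SPECIES_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_pkas(ladders: dict[str, PKaLadder], path: PathLike) -> None:
    rows = [
        {"species_id": sid, "pka": p}
        for sid, ladder in ladders.items()
        for p in ladder.pkas
    ]
    pd.DataFrame(rows, columns=PKA_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_couples(couples: Sequence[tuple[str, str, str]], path: PathLike) -> None:
    pd.DataFrame(couples, columns=COUPLE_COLUMNS).to_csv(path, index=False)


def write_clusters(records: Sequence[ClusterRecord], path: PathLike) -> None:
    rows = [
        {
            "solute_id": r.solute_id,
            "n_waters": r.n_waters,
            "label": r.label,
            "e_cluster_gas_ev": r.e_cluster_gas,
            "e_cluster_solvent_ev": r.e_cluster_solvent,
            "e_solute_gas_ev": r.e_solute_gas,
            "e_water_gas_ev": r.e_water_gas,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_benchmark(entries: Sequence[BenchmarkEntry], path: PathLike) -> None:
    rows = [
        {
            "couple_id": e.couple_id,
            "ph": e.ph,
            "u_computed_v": e.u_computed,
            "u_reference_v": e.u_reference,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=BENCHMARK_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Serializes to/from JSON losslessly so every run can log (and later
    replay) the exact constants, variant and transform mode it used.
    """

    u_she: float = 4.43
    dg_solv_proton: float = -11.38
    temperature: float = 298.15
    geometry: str = "solvent"
    solvation: str = "optimized"
    thermal: bool = True
    thermal_phase: str = "gas"
    transform_mode: str = "variable"
    ph_values: list[float] = field(default_factory=lambda: [0.0, 7.0, 13.0])
    plateau_tol: float = 0.02
    seed: int = 0
    energy_unit: str = "ev"

    def to_json(self, path: Optional[PathLike] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, PathLike]) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PhredoxError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def constants(self):
        from .core import Constants

        return Constants(
            U_SHE=self.u_she,
            dG_solv_proton=self.dg_solv_proton,
            T=self.temperature,
        )

    def variant(self):
        from .thermo import AssemblyVariant

        return AssemblyVariant(
            geometry=self.geometry,
            solvation=self.solvation,
            thermal=self.thermal,
            thermal_phase=self.thermal_phase,
        )
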