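"""Protonation-state bookkeeping: pKa ladders and pH-dependent H counts.

The model is deprotonation-only: as pH rises past each acid-dissociation
constant, the major microspecies loses one proton.  A species is described
by its hydrogen count at pH 0 (the reference state of the whole protocol)
plus an ordered ladder of pKa values; the hydrogen count at any pH follows
by counting the pKas crossed.  Only pKas strictly inside (0, 14) are active
— values outside that window are retained but never change a slope.

External pKa predictors and conformer searchers sit behind the
:class:`ProtonationProvider` interface; the package ships a table-backed
provider and a deterministic fixture provider, nothing commercial.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import LadderError, PhredoxError

PH_MIN, PH_MAX = 0.0, 14.0


@dataclass(frozen=True)
class PKaLadder:
    """Ordered deprotonation constants of one species.

    ``pkas`` are stored sorted ascending; duplicates are allowed and mean
    coincident deprotonations.  ``reference_ph`` is the pH at which the
    species' stored hydrogen count applies (always 0 in this protocol).
    """

    species_id: str
    pkas: tuple[float, ...] = ()
    reference_ph: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pkas", tuple(sorted(float(p) for p in self.pkas)))
        if self.reference_ph != 0.0:
            raise PhredoxError(
                "hydrogen counts are referenced to pH 0 in this protocol"
            )

    def in_range(self, lo: float = PH_MIN, hi: float = PH_MAX) -> tuple[float, ...]:
        """pKas strictly inside (lo, hi) — the ones that affect slopes."""
        return tuple(p for p in self.pkas if lo < p < hi)


def hydrogens_at_ph(nh_ref: int, ladder: PKaLadder, ph: float) -> int:
    """Hydrogen count of the major microspecies at ``ph``.

    Counts the pKas strictly between 0 and ``ph`` as crossed (each removes
    one proton from the pH-0 count ``nh_ref``).  A pKa exactly equal to
    ``ph`` is not yet crossed; midpoint evaluation makes this boundary
    convention immaterial for segment slopes.
    """
    if not PH_MIN <= ph <= PH_MAX:
        raise PhredoxError(f"pH {ph} outside [{PH_MIN}, {PH_MAX}]")
    crossed = sum(1 for p in ladder.pkas if PH_MIN < p < ph)
    nh = nh_ref - crossed
    if nh < 0:
        raise LadderError(
            f"ladder for {ladder.species_id!r} implies {crossed} deprotonations "
            f"at pH {ph} but only {nh_ref} hydrogens are available"
        )
    return nh


def breakpoint_grid(
    ladder_ox: Optional[PKaLadder],
    ladder_red: Optional[PKaLadder],
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
) -> list[float]:
    """Sorted, deduplicated pH grid: bounds plus every in-range pKa.

    The union of both ladders' pKas strictly inside (ph_min, ph_max), with
    ``ph_min`` and ``ph_max`` prepended/appended.  Coincident pKas collapse
    to a single grid point; the hydrogen-count drop across it carries the
    multiplicity.
    """
    if not ph_min < ph_max:
        raise PhredoxError(f"need ph_min < ph_max, got ({ph_min}, {ph_max})")
    pts = set()
    for ladder in (ladder_ox, ladder_red):
        if ladder is not None:
            pts.update(p for p in ladder.pkas if ph_min < p < ph_max)
    return [ph_min, *sorted(pts), ph_max]


def midpoint_hydrogens(
    nh_ref: int, ladder: PKaLadder, ph_lo: float, ph_hi: float
) -> int:
    """Hydrogen count at the midpoint of a grid segment.

    Evaluating halfway between consecutive grid points guarantees the count
    reflects the protonation state *inside* the segment, including when the
    lower endpoint is itself a pKa.
    """
    if not ph_lo < ph_hi:
        raise PhredoxError(f"need ph_lo < ph_hi, got ({ph_lo}, {ph_hi})")
    return hydrogens_at_ph(nh_ref, ladder, 0.5 * (ph_lo + ph_hi))


class ProtonationProvider(abc.ABC):
    """Contract for external pKa / microspecies / conformer engines.

    Implementations must be deterministic for fixed input, and the hydrogen
    count they report must be non-increasing in pH.
    """

    @abc.abstractmethod
    def major_microspecies(self, smiles: str, ph: float) -> tuple[str, int, int]:
        """Return (microspecies smiles, hydrogen count, formal charge) of the
        most abundant protonation state at ``ph``."""

    @abc.abstractmethod
    def pka_ladder(self, smiles: str) -> PKaLadder:
        """Return the species' ordered deprotonation constants."""

    def lowest_conformer(self, smiles: str) -> tuple[str, float]:
        """Return (conformer label, relative energy in eV) of the minimum-
        energy conformer.  Optional; the default raises."""
        raise NotImplementedError(
            "conformer search requires an external engine; this provider "
            "does not supply one"
        )


@dataclass
class TableProtonationProvider(ProtonationProvider):
    """Provider backed by user-supplied tables.

    ``ladders`` maps a structure string to its :class:`PKaLadder`;
    ``reference_states`` maps it to the (smiles, n_hydrogens, charge) of the
    pH-0 major microspecies.  Microspecies at pH > 0 are derived by counting
    crossed pKas (charge decreases by one per deprotonation).
    """

    ladders: dict[str, PKaLadder] = field(default_factory=dict)
    reference_states: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    conformers: dict[str, tuple[str, float]] = field(default_factory=dict)

    def pka_ladder(self, smiles: str) -> PKaLadder:
        try:
            return self.ladders[smiles]
        except KeyError:
            raise PhredoxError(f"no pKa ladder on record for {smiles!r}") from None

    def major_microspecies(self, smiles: str, ph: float) -> tuple[str, int, int]:
        try:
            ref_smiles, nh0, q0 = self.reference_states[smiles]
        except KeyError:
            raise PhredoxError(f"no reference state on record for {smiles!r}") from None
        ladder = self.pka_ladder(smiles)
        nh = hydrogens_at_ph(nh0, ladder, ph)
        return ref_smiles, nh, q0 - (nh0 - nh)

    def lowest_conformer(self, smiles: str) -> tuple[str, float]:
        try:
            return self.conformers[smiles]
        except KeyError:
            raise PhredoxError(f"no conformer on record for {smiles!r}") from None
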