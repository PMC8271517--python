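"""Pourbaix curves: transforming pH = 0 free energies to arbitrary pH.

Two transforms are provided.  The constant-slope Alberty-Legendre transform
shifts a species' free energy by its pH-0 hydrogen count,

    G_sol(pH) = G_sol(0) + NH(0) * kT ln10 * pH,

which makes the potential of an n-electron / np-proton couple a straight
line of slope -(np/n) * kT ln10.  The variable-slope refinement updates the
hydrogen count at every pKa: on a grid of pH values containing all in-range
pKas of the species, each segment's slope uses the hydrogen count of the
major microspecies at the segment midpoint,

    G_sol(pH_p) = G_sol(pH_{p-1}) + NH(mid) * kT ln10 * (pH_p - pH_{p-1}),

so the resulting Pourbaix curve is piecewise linear with breakpoints at the
pKas and a slope that flattens as the species deprotonates.  Both curves
feed the same potential expression U = -dG/n - U_SHE segment by segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import Constants, DomainError, PhredoxError, RedoxCouple
from .protonation import (
    PH_MAX,
    PH_MIN,
    PKaLadder,
    breakpoint_grid,
    hydrogens_at_ph,
    midpoint_hydrogens,
)

TransformMode = Literal["constant", "variable"]


@dataclass(frozen=True)
class PiecewiseLinearCurve:
    """A continuous piecewise-linear curve stored as its breakpoints.

    ``ph`` is strictly increasing; between breakpoints the curve is linear
    interpolation, and evaluation outside [ph[0], ph[-1]] is an error (no
    extrapolation).  ``units`` is 'eV' for free-energy curves and 'V' for
    potential curves.
    """

    ph: np.ndarray
    values: np.ndarray
    units: str = "eV"

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ph.ndim != 1 or ph.shape != values.shape or ph.size < 2:
            raise PhredoxError("curve needs matching 1-D ph/value arrays, >= 2 points")
        if not np.all(np.diff(ph) > 0):
            raise PhredoxError("breakpoint pH values must be strictly increasing")
        if not (np.all(np.isfinite(ph)) and np.all(np.isfinite(values))):
            raise PhredoxError("curve breakpoints must be finite")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "values", values)

    def __call__(self, ph: Union[float, Sequence[float]]) -> Union[float, np.ndarray]:
        return evaluate(self, ph)

    @property
    def breakpoints(self) -> list[tuple[float, float]]:
        return list(zip(self.ph.tolist(), self.values.tolist()))


def evaluate(
    curve: PiecewiseLinearCurve, ph: Union[float, Sequence[float]]
) -> Union[float, np.ndarray]:
    """Linear interpolation on the curve; exact at breakpoints.

    Raises :class:`DomainError` for any pH outside the curve's domain.
    """
    arr = np.asarray(ph, dtype=float)
    if np.any(arr < curve.ph[0]) or np.any(arr > curve.ph[-1]):
        raise DomainError(
            f"pH {ph} outside curve domain [{curve.ph[0]}, {curve.ph[-1]}]"
        )
    out = np.interp(arr, curve.ph, curve.values)
    return float(out) if np.isscalar(ph) or arr.ndim == 0 else out


def g_constant_slope(g0: float, nh0: int, ph: float, c: Constants) -> float:
    """Constant-slope transform of a species free energy, in eV."""
    if not PH_MIN <= ph <= PH_MAX:
        raise PhredoxError(f"pH {ph} outside [{PH_MIN}, {PH_MAX}]")
    return g0 + nh0 * c.nernst_slope * ph


def g_variable_slope(
    g0: float,
    nh0: int,
    ladder: PKaLadder,
    c: Constants,
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
) -> PiecewiseLinearCurve:
    """Variable-slope transform of a species free energy.

    Builds the breakpoint grid from the ladder's in-range pKas and applies
    the midpoint-hydrogen recurrence segment by segment.  Rejects ladders
    whose in-range pKas exceed the available hydrogens (the hydrogen count
    would go negative somewhere in the window).
    """
    grid = breakpoint_grid(ladder, None, ph_min, ph_max)
    values = [g0]
    for lo, hi in zip(grid[:-1], grid[1:]):
        nh = midpoint_hydrogens(nh0, ladder, lo, hi)  # raises if inconsistent
        values.append(values[-1] + nh * c.nernst_slope * (hi - lo))
    return PiecewiseLinearCurve(np.array(grid), np.array(values), units="eV")


def _g_on_grid(
    g0: float,
    nh0: int,
    ladder: PKaLadder,
    grid: Sequence[float],
    c: Constants,
    mode: TransformMode,
) -> np.ndarray:
    """Species G values on an externally supplied grid (a superset of the
    species' own breakpoints is required for the variable mode)."""
    if mode == "constant":
        return np.array([g_constant_slope(g0, nh0, p, c) for p in grid])
    values = [g0]
    for lo, hi in zip(grid[:-1], grid[1:]):
        nh = midpoint_hydrogens(nh0, ladder, lo, hi)
        values.append(values[-1] + nh * c.nernst_slope * (hi - lo))
    return np.array(values)


def u_curve(
    couple: RedoxCouple,
    g0_ox: float,
    g0_red: float,
    ladder_ox: PKaLadder,
    ladder_red: PKaLadder,
    c: Constants,
    mode: TransformMode = "variable",
    ph_min: float = PH_MIN,
    ph_max: float = PH_MAX,
) -> PiecewiseLinearCurve:
    """Potential-vs-pH Pourbaix curve of a couple, in volts.

    The grid is the union of both species' breakpoint grids, so every
    segment has a constant slope equal to

        -(NH_red(mid) - NH_ox(mid)) * kT ln10 / n.

    ``mode='constant'`` reproduces the straight Nernst line through U0;
    ``mode='variable'`` (the default, and the recommended method) bends the
    curve at every in-range pKa of either species.
    """
    if mode not in ("constant", "variable"):
        raise PhredoxError(f"unknown transform mode {mode!r}")
    grid = breakpoint_grid(ladder_ox, ladder_red, ph_min, ph_max)
    g_ox = _g_on_grid(g0_ox, couple.ox.n_hydrogens, ladder_ox, grid, c, mode)
    g_red = _g_on_grid(g0_red, couple.red.n_hydrogens, ladder_red, grid, c, mode)
    dG = g_red - g_ox + couple.n_protons * c.dG_solv_proton
    u = -dG / couple.n_electrons - c.U_SHE
    return PiecewiseLinearCurve(np.array(grid), u, units="V")


def segment_table(
    couple_id: str,
    couple: RedoxCouple,
    g0_ox: float,
    g0_red: float,
    ladder_ox: PKaLadder,
    ladder_red: PKaLadder,
    c: Constants,
    mode: TransformMode = "variable",
) -> pd.DataFrame:
    """Per-segment description of a Pourbaix curve for tabular output.

    Columns: couple_id, segment_index, ph_lo, ph_hi, u_lo_v, u_hi_v,
    slope_v_per_ph, nh_ox_mid, nh_red_mid.
    """
    curve = u_curve(couple, g0_ox, g0_red, ladder_ox, ladder_red, c, mode=mode)
    rows = []
    for i, (lo, hi) in enumerate(zip(curve.ph[:-1], curve.ph[1:])):
        u_lo, u_hi = curve.values[i], curve.values[i + 1]
        if mode == "variable":
            nh_ox = midpoint_hydrogens(couple.ox.n_hydrogens, ladder_ox, lo, hi)
            nh_red = midpoint_hydrogens(couple.red.n_hydrogens, ladder_red, lo, hi)
        else:
            nh_ox = couple.ox.n_hydrogens
            nh_red = couple.red.n_hydrogens
        rows.append(
            {
                "couple_id": couple_id,
                "segment_index": i,
                "ph_lo": lo,
                "ph_hi": hi,
                "u_lo_v": u_lo,
                "u_hi_v": u_hi,
                "slope_v_per_ph": (u_hi - u_lo) / (hi - lo),
                "nh_ox_mid": nh_ox,
                "nh_red_mid": nh_red,
            }
        )
    return pd.DataFrame(rows)
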