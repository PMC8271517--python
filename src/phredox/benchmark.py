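"""Error statistics against reference potentials and systematic-error
correction.

Computed potentials are compared with references through the mean absolute
error (MAE) and mean signed error (MSE).  A non-zero MSE is a systematic
offset — typical of a solvation model or functional bias that shifts every
couple by the same amount — and can be removed empirically by subtracting
the MSE from the computed potentials, which zeroes the corrected MSE by
construction and usually shrinks the MAE when the errors are
offset-dominated.  A leave-one-out variant of the correction is available
for an honest estimate of how the correction generalizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import PhredoxError


@dataclass(frozen=True)
class BenchmarkEntry:
    """One computed/reference potential pair at a given pH (volts)."""

    couple_id: str
    u_computed: float
    u_reference: float
    ph: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_computed", "u_reference", "ph"):
            if not math.isfinite(getattr(self, name)):
                raise PhredoxError(f"entry {self.couple_id!r}: {name} not finite")

    @property
    def error(self) -> float:
        return self.u_computed - self.u_reference


def _errors(entries: Sequence[BenchmarkEntry]) -> np.ndarray:
    if not entries:
        raise PhredoxError("benchmark statistics require at least one entry")
    return np.array([e.error for e in entries])


def mae(entries: Sequence[BenchmarkEntry]) -> float:
    """Mean absolute error in volts."""
    return float(np.mean(np.abs(_errors(entries))))


def mse(entries: Sequence[BenchmarkEntry]) -> float:
    """Mean signed error in volts (sign preserved; positive = computed
    potentials are too high on average)."""
    return float(np.mean(_errors(entries)))


def apply_systematic_correction(
    entries: Sequence[BenchmarkEntry],
    cross_validated: bool = False,
) -> tuple[list[BenchmarkEntry], dict[str, float]]:
    """Subtract the systematic offset from the computed potentials.

    By default the MSE of the full set is subtracted from every entry, which
    makes the corrected MSE exactly zero.  With ``cross_validated=True``
    each entry is corrected by the MSE of all *other* entries (leave-one-out),
    so the corrected statistics estimate out-of-sample performance instead;
    the corrected MSE is then generally small but not identically zero.

    Returns the corrected entries and a report dict with before/after MAE
    and MSE (volts) and the entry count.
    """
    errs = _errors(entries)
    n = errs.size
    if cross_validated:
        if n < 2:
            raise PhredoxError("leave-one-out correction needs >= 2 entries")
        # offset for entry i = mean of the other n-1 errors
        offsets = (errs.sum() - errs) / (n - 1)
    else:
        offsets = np.full(n, errs.mean())
    corrected = [
        replace(e, u_computed=e.u_computed - off)
        for e, off in zip(entries, offsets)
    ]
    report = {
        "n_entries": n,
        "mae_v": mae(list(entries)),
        "mse_v": mse(list(entries)),
        "corrected_mae_v": mae(corrected),
        "corrected_mse_v": mse(corrected),
    }
    return corrected, report
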