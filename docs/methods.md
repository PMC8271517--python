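# Methods

## Scope and division of labor

`phredox` implements the thermodynamic bookkeeping of pH-dependent redox
potential prediction: free-energy assembly, stoichiometry, the pH
transforms, the cluster–continuum cycle, and benchmarking.  Everything that
requires an electronic-structure, force-field or pKa engine is an *input*:
the package defines the tabular contracts (CSV schemas in `phredox.io`) and
the `ProtonationProvider` interface, and consumes numbers.  This keeps the
package free of heavyweight or commercial dependencies and makes every code
path exactly testable.

## Units and constants

All internal energies are in eV and potentials in volts, so
`U = −ΔG/n − U_SHE` needs no unit factor; hartree input is converted at the
I/O boundary only (1 hartree = 27.211386 eV).  Defaults: `U_SHE = 4.43 V`,
`ΔG_s(H⁺) = −11.38 eV`, `T = 298.15 K`, water molarity 55.34 mol/L,
ideal-gas molar volume 24.46 L/mol at 1 atm.  `U_SHE` and `ΔG_s(H⁺)` are
deliberately configuration rather than literals: their "correct" values are
debated and depend on which implicit-solvation model produced the energies,
and shifting either moves every computed potential by the same amount.
`kT` and the Nernst slope `kT·ln10` (0.0591597 eV at 298.15 K) are derived
properties of `T` and recompute on any temperature change; curves must be
regenerated, not rescaled, when `T` changes, because the breakpoint values
themselves depend on the slope.

A note on nomenclature: the constant multiplying `T·ln10` in the transform
is the molar gas constant (equivalently Boltzmann's constant in eV), as
dimensional analysis and the printed 0.0592 V value require; one sometimes
sees it misnamed the Rydberg constant in this context.

## Stoichiometry

`(n_electrons, n_protons)` is derived, not declared: atom balance gives
`n_p = N_H(Red) − N_H(Ox)` and charge balance `n = n_p + q(Ox) − q(Red)`.
The derivation is kept fully general rather than assuming the common
2e⁻/2H⁺ quinone pattern.  Under the reduction convention, `n_p < 0`
(hydrogen loss on reduction) and `n < 1` (no electron transfer) are
rejected.  When a SMILES string is supplied, its implicit+explicit hydrogen
count must agree with the declared `n_hydrogens`; a mismatch is an error,
not a warning, because a silent one-proton discrepancy shifts slopes by
59 mV/pH.

## Free-energy assembly

An `AssemblyVariant` names the approximation level: gas-phase electronic
energy only; energy optimized in implicit solvent; or gas-phase energy plus
a separately computed solvation term (`single_point` for an implicit
single-point at the gas geometry, `additive` for a post-hoc model such as a
statistical-mechanics solvation method — the arithmetic is identical, the
label preserves provenance).  The thermal contribution (zero-point +
vibrational enthalpy + entropy) defaults to the gas phase, which is
marginally preferable and much cheaper to obtain; a solvent-phase thermal
field is accepted but must be selected explicitly.  The recommended
standard is solvent-optimized electronic energy + gas-phase thermal
correction (`STANDARD_VARIANT`).

Potentials outside ±3 V trigger a log warning rather than an error: the
protocol targets aqueous organics, but the arithmetic is general.

## Protonation model

Deprotonation-only as pH rises: each pKa strictly inside (0, 14) removes
one proton from the pH-0 hydrogen count.  Basic protonation events (proton
*gain* above pH 0) are rejected as unsupported input.  Out-of-range pKas
are retained on the ladder but never affect a slope.  Boundary convention:
a pKa exactly equal to the evaluation pH counts as not yet crossed (strict
inequality); since segment slopes are evaluated at segment midpoints, the
choice cannot affect any curve.  Coincident pKas collapse to one grid point
and the hydrogen-count drop across it carries the multiplicity.

The midpoint rule is the load-bearing refinement: on each grid segment the
hydrogen count is taken halfway between the endpoints, so the slope always
reflects the microspecies *inside* the segment, including when the lower
endpoint is itself a pKa.

## Pourbaix construction

Species G-curves are piecewise linear on the breakpoint grid (bounds plus
in-range pKas).  The potential curve is built on the *union* grid of both
species, which is equivalent to building per-species curves and combining
them, but guarantees each U-segment has one constant slope

    −(N_H^Red(mid) − N_H^Ox(mid)) · kT ln10 / n.

Both transform modes are kept — `constant` for the classic straight line,
`variable` (default) for the pKa-aware refinement — because comparing them
is itself informative: they agree exactly whenever no pKa of either species
lies in the pH window, which is typically the case below pH ≈ 7.

Numerical notes: curves are exact at breakpoints by construction and
linearly interpolated between them via `numpy.interp`; evaluation outside
[0, 14] raises (no extrapolation).  For deprotonation-only ladders the
segment slopes `N_H·kT ln10` are non-increasing, so G-curves are concave —
asserted as a property test in that regime only.

## Cluster–continuum cycle

The monomer cycle with 1 M standard states throughout.  The vaporization
term `−ΔG_s(H₂O) − kT ln 55.34 − kT ln 24.46` removes the liquid-water
(55.34 M → 1 M) and ideal-gas (1 atm → 1 M) concentration mismatches.
Candidate geometries at the same n are Boltzmann-averaged; the weighting
energy is each candidate's own ΔG_s^cc, because at fixed n all candidates
share the monomer reference energies, so ΔG_s^cc differences equal
total-free-energy differences.  (Whether a published average used
electronic energies or the full cycle value as weights is generally
ambiguous; this choice is the one that is gauge-invariant under energy
offsets.)  Averaging is strictly per n — no cross-n pooling.  The plateau
flag compares successive per-n averages against a configurable tolerance,
default 0.02 eV, chosen as roughly the chemical-accuracy scale (~0.5
kcal/mol); profiles that decrease monotonically faster than that are
correctly reported as unconverged.  Cluster thermal corrections are not
added separately: the input energies are taken as given.  The min-shifted
exponential in the Boltzmann weight is mandatory for overflow safety.

At n = 0 the cycle degenerates to `E_solvent − E_gas`, the plain implicit
solvation free energy, and the cc potential reproduces the implicit-route
potential exactly — asserted as an acceptance-level test.

## Benchmarking

MAE and MSE in volts (millivolts in log summaries).  The systematic
correction subtracts the set's own MSE from every computed potential —
deliberately leave-nothing-out, reproducing the common practice of
reporting "corrected" MAEs; a leave-one-out variant is available behind
`cross_validated=True` for an honest generalization estimate.  The
corrected MSE is zero by construction (to floating-point roundoff,
~1e-17 V).

## Synthetic data generator

Ground truth is defined in potential space and inverted into energies:
each couple draws a target U⁰ uniform on 0–1.2 V (the span of typical
aqueous quinone couples), a stoichiometry (70% 2e⁻/2H⁺, 15% 1e⁻/1H⁺, 15%
2e⁻/1H⁺ — the minority patterns exercise the general slope formula), pKa
ladders of up to three in-range constants for the reduced form and one for
the oxidized form (reduced, more protonated species carry more acidic
protons), and free energies that are split arbitrarily into
electronic/thermal and gas/solvation parts so every assembly variant is
satisfiable and mutually consistent.  Reference "experimental" potentials
are variable-slope curve values at pH 0/7/13 plus Gaussian noise of
σ = 0.1 V, the scale of typical prediction errors for such methods.  The
noise draw happens unconditionally so the same seed yields the same
couples at any σ.  Cluster tables start at the species' own implicit
solvation free energy at n = 0 and decay exponentially (τ = 2 waters) to a
0.2–0.6 eV deeper plateau, with small (≤0.01 eV) candidate spreads.

What the generator does *not* emulate: real electronic-structure error
(which is structured, not Gaussian), correlated errors between Ox and Red,
conformer and tautomer ambiguity, ionic-strength effects, and any actual
chemistry behind the numbers.  Passing the recovery tests therefore shows
the *bookkeeping* is exact — generator and pipeline are mutual inverses to
1e-9 V — not that potentials of real molecules will be accurate; that
depends entirely on the quality of the input energies.

## Design choices in brief

- Library + thin CLI: the five subcommands wrap library calls 1:1.
- CSV as primary interchange, 17-significant-digit floats for lossless
  round-trips; JSON for nested results and the run config.
- Per-run resolved configuration is logged; fixture generation is
  byte-deterministic given (spec, seed).
- Ionic-strength dependence of the transform is omitted.
- No internal reference-electrode conversions: SHE only.

## Problem sizes

The test suite and acceptance script use 100–500 synthetic couples per
check and dense-grid oracles at 0.01 pH steps; the whole suite runs in a
few seconds, and all quantities are already converged at these sizes (the
recovery and equivalence checks are exact identities, not statistical
estimates).

## Known limitations

- No microspecies enumeration or tautomer handling; the ladder model is the
  literal majority-count reading of the midpoint rule, and near-degenerate
  microspecies at a midpoint pH are not resolved.
- Deprotonation-only: species that protonate above pH 0 are out of scope.
- The conformer-search contract is interface-only; hydrogen-bond-aware
  conformer ranking (which matters for real quinones) is documented here
  but not implemented.
- 2-D Pourbaix phase fields (disproportionation regions) are not built.
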