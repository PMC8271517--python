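# phredox

Predicting pH-dependent redox potentials of proton-coupled organic redox
couples — quinones and their relatives, the workhorse electrolytes of
aqueous redox flow batteries.  Given externally computed free-energy
components for the oxidized and reduced forms of a molecule, `phredox`
assembles standard potentials, transforms them to any pH with a
pKa-aware piecewise-linear construction (an approximate Pourbaix diagram),
refines solvation with an explicit-water cluster–continuum cycle, and
benchmarks predictions against reference potentials.

`phredox` runs **no** electronic-structure or force-field calculations.  It
consumes numeric outputs of external engines (DFT energies, thermal
corrections, solvation free energies, pKa ladders) through plain CSV
schemas, and ships a synthetic-data generator so the entire pipeline is
testable without any external software.

## The model

For a proton-coupled reduction `Ox + n e⁻ + n_p H⁺ → Red`, the standard
potential against the standard hydrogen electrode (SHE) is

    U⁰ = −ΔG⁰_sol / n − U_SHE,
    ΔG⁰_sol = G⁰_sol(Red) − G⁰_sol(Ox) + n_p ΔG⁰_s(H⁺),

with free energies in eV, `U_SHE = 4.43 V`, and `ΔG⁰_s(H⁺) = −11.38 eV`
(both overridable — the literature does not agree on which pair is
consistent with a given solvation model).  The stoichiometry `(n, n_p)` is
derived from hydrogen counts and formal charges, never supplied by hand.

pH enters through the Alberty–Legendre transform.  The classic
constant-slope form shifts each species' free energy by its pH-0 hydrogen
count N_H:

    G_sol(pH) = G_sol(0) + N_H · kT ln10 · pH,

giving a straight U-vs-pH line of slope −(N_H(Red) − N_H(Ox))/n · 0.0592 V
at 298.15 K.  This ignores that species deprotonate above their pKa values.
The variable-slope refinement evaluates G on a pH grid containing every pKa
in (0, 14) and uses, on each segment, the hydrogen count of the major
microspecies at the segment *midpoint*:

    G_sol(pH_p) = G_sol(pH_{p−1}) + N_H(pH_half) · kT ln10 · (pH_p − pH_{p−1}).

The resulting Pourbaix curve is piecewise linear, bending at every pKa of
either redox form — flattening as the reduced form deprotonates, steepening
as the oxidized form does.

For cases where implicit solvation fails (specific solute–solvent hydrogen
bonds), the monomer cluster–continuum cycle computes

    ΔG_s^cc(A) = ΔG_bind(gas) + ΔG_s(A(H₂O)_n) + n ΔG_vap(H₂O),
    ΔG_vap(H₂O) = −ΔG_s(H₂O) − kT ln 55.34 − kT ln 24.46,

Boltzmann-averages over candidate cluster geometries, and profiles the
result against n until it plateaus.

## Worked example

A 2-electron/2-proton couple with U⁰ = 0.730 V whose reduced form has one
pKa at 10.0:

```python
import phredox as px

c = px.Constants()                      # U_SHE=4.43 V, ΔGs(H+)=−11.38 eV, 298.15 K
ox  = px.SpeciesState("ox",  n_hydrogens=4, charge=0)
red = px.SpeciesState("red", n_hydrogens=6, charge=0)
couple = px.RedoxCouple(ox, red)        # derives n=2, np=2

g_ox = -250.0                           # eV, from your DFT engine
g_red = -2*(0.730 + c.U_SHE) - 2*c.dG_solv_proton + g_ox

curve = px.u_curve(couple, g_ox, g_red,
                   px.PKaLadder("ox"), px.PKaLadder("red", (10.0,)), c)
print(f"U(0)  = {curve(0.0):.4f} V")
print(f"U(10) = {curve(10.0):.4f} V")
print(f"U(13) = {curve(13.0):.4f} V")
```

prints

```
U(0)  = 0.7300 V
U(10) = 0.1384 V
U(13) = 0.0497 V
```

Below pH 10 the slope is the full −59.2 mV/pH (two protons per two
electrons); at the pKa the reduced form loses a proton and the slope halves,
so the potential at pH 13 sits 89 mV below the pH-10 value instead of 177 mV.

The same pipeline is scriptable from the shell:

```sh
phredox fixtures --seed 7 --outdir data/          # synthetic dataset
phredox potential --species data/species.csv --couples data/couples.csv --out u0.csv
phredox pourbaix  --species data/species.csv --couples data/couples.csv \
                  --pkas data/pkas.csv --mode variable --ph 0 --ph 7 --ph 13 \
                  --out-segments segments.csv --out-grid grid.csv
phredox benchmark --input data/benchmark.csv --correct --out report.json
```

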