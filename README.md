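# solvcontact

Solvation free energies of organic molecules from a solvent-contact model
with an intramolecular **self-solvation** term, plus the machinery used to
build and refit such models: Sybyl-style atom typing, Monte Carlo van der
Waals volumes, genetic-algorithm parameterization, and the conversion of
(solubility, vapor pressure) data into reference solvation free energies.

It is aimed at cheminformatics and drug-discovery work where a fast,
parameter-driven estimate of the aqueous solvation free energy ΔG_sol — and
hence of desolvation costs, solubility trends, and related properties — is
needed for many 3-D structures at a time, without quantum chemistry or
explicit-solvent simulation.

## The model

Each atom *i* of a solute contributes additively:

```
ΔG_sol = Σᵢ [ Sᵢ · (Oᵢᵐᵃˣ − Oᵢ)  +  Pᵢ · Oᵢ ]

Oᵢ = Σ_{j≠i} V_j · exp( −r²ᵢⱼ / 2σ² ),   σ = 3.5 Å
```

* **Oᵢ** — occupied volume around atom *i*: the Gaussian-weighted sum of the
  fragmental volumes **V_j** of all other solute atoms; the region solvent
  cannot reach.
* **Oᵢᵐᵃˣ − Oᵢ = Fᵢ** — solvent-exposed volume; **Sᵢ** (kcal mol⁻¹ Å⁻³)
  scales its solute–solvent interaction.
* **Pᵢ·Oᵢ** — the self-solvation term: intramolecular stabilization
  (negative P) or destabilization (positive P) by the atoms occupying the
  space around *i*. Dropping it recovers the older purely additive model.

Every atom carries one of 37 extended atom types (element + hybridization +
aromaticity/functional context + heavy-substituent count, e.g. `C.3_2`,
`N.am_1`, `H.O`) or one of 23 basic types without the substituent
subdivision. Both published parameter tables ship with the package
(`builtin_table("extended37")`, 148 parameters; `builtin_table("basic23")`,
69 parameters). The extended table was parameterized against molecules of
roughly 200–500 amu; far smaller solutes are outside its calibrated domain
and their absolute energies grow large.

Supporting components:

* **Volumes** — V_mol estimated by Monte Carlo hit counting in the tight
  axis-aligned box around the union of van der Waals spheres
  (`V_mol = V_box · N_hits/N_trials`), with binomial standard errors.
* **Fitting** — a two-stage elitist GA: fragmental volumes V_j against
  molecular volumes (fitness F_V = Σ|V_mol − Σ V_j|), then S, O_max, P with
  V frozen against reference energies (F_s = Σ|ΔG_ref − ΔG_calc|).
* **Thermodynamics** — ΔG_sol = −2.303 RT log₁₀(M·p⁰/p) from equilibrium
  solubility M and vapor pressure p, with p⁰ the pressure of an ideal gas at
  1 M (≈ 24.45 atm at 298.15 K).

## Worked example

```bash
$ solvcontact fixtures molecule --template ethanol --out ethanol.mol2
$ solvcontact typing ethanol.mol2 | head -5
index   element type
0       C       C.3_1
1       C       C.3_2
2       O       O.3_1
3       H       H.C
$ solvcontact volume ethanol.mol2 --trials 1000000 --seed 1
name    V_mol   std_error       N_trials        seed
ethanol 42.879  0.049   1000000 1
$ solvcontact convert -m 10 -p 24.465295 --unit atm
-1.3645
```

Reading the numbers: the hydroxyl oxygen of ethanol types as `O.3_1` (sp³
oxygen, one heavy substituent) and its proton as `H.O`; the Monte Carlo
van der Waals volume is 42.9 ± 0.05 Å³; and a solute whose solubility/vapor
pressure ratio M·p⁰/p is one decade above 1 gains −1.364 kcal/mol
(−2.303 RT) of solvation free energy.

Scoring, in Python, of a hand-checkable case — an isolated bromine atom has
zero occupancy, so its energy is exactly S·O_max = 0.185 × 330.4:

```python
>>> from solvcontact import builtin_table, fixtures, solvation_energy
>>> br = fixtures.make_toy("single_atom", element="Br")
>>> solvation_energy(br, builtin_table("extended37")).total
61.123999999999995
```

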