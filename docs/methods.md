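# Methods

## Model

The solvation free energy of a rigid, single-conformer solute is a sum of
per-atom contributions. For atom *i* with type parameters
(V, O_max, S, P):

```
O_i  = Σ_{j≠i} V_{type(j)} · exp(−r_ij² / 2σ²)        occupied volume, Å³
F_i  = O_max,i − O_i                                   solvent-exposed volume, Å³
ΔG_i = S_i·F_i + P_i·O_i                               kcal/mol
```

Assumptions inherited from the solvent-contact framework:

* **Additivity over atoms.** Nonadditivity of solute–solvent interactions
  enters only through the self-solvation term P·O, which rewards or
  penalizes intramolecular occlusion (intramolecular hydrogen bonds,
  hydrophobic contacts) without modeling those interactions explicitly.
* **Occupancy as a Gaussian-smeared volume.** Every other solute atom,
  hydrogens included, contributes its fragmental volume attenuated by
  exp(−r²/2σ²) with σ = 3.5 Å. All j ≠ i pairs enter the sum — bonded
  neighbors are not excluded. Both conventions matter numerically and are
  fixed here: H types carry fitted V in both published tables, and the
  occupancy definition makes no exception for 1-2/1-3 pairs.
* **Single conformer.** Energies refer to the input geometry; no ensemble
  averaging.
* **Water at 298.15 K.** The shipped parameter tables have no temperature
  or solvent dependence.

The kernel evaluates the full n×n distance matrix; no cutoff is applied by
default (an optional cutoff exists for batch work and is recorded in the
result when used). F_i is used as-is when O_i > O_max (possible for deeply
buried atoms or refit parameters); the condition is warned about, never
clamped, so the energy stays a smooth function of the parameters.

### Domain of validity of the shipped tables

The extended 37-type table was calibrated on organic molecules of roughly
200–500 amu, whose atoms are substantially occluded (O_i comparable to
O_max). For very small solutes the S·O_max products do not cancel and
absolute energies become large — the toy ethanol scores in the thousands of
kcal/mol. This is the published model faithfully evaluated outside its
fitted size range, not a defect of the implementation; single-atom and
diatomic cases remain exactly hand-checkable and are used as such in the
tests.

## Atom typing

Types follow Sybyl MOL2 conventions: element + hybridization
(C.3/C.2/C.1/C.ar, N.3/N.2/N.1/N.am/N.ar/N.pl3, O.3/O.2,
S.3/S.2/S.O/S.O2, P, halogens), hydrogens typed by their bonded heavy atom
(H.C/H.N/H.O). The extended scheme subdivides sp³/sp²/aromatic carbon,
sp³/amide/planar nitrogen and sp³ oxygen by **heavy-substituent count** —
a *substituent* is a non-hydrogen bonded neighbor, the only convention
under which a hydroxyl oxygen has one substituent and an ether oxygen two.
Counts outside the published range (methane's carbon: zero heavy
neighbors) are clamped to the nearest available subdivision with a
recorded warning rather than rejected.

Decisions where Sybyl practice leaves latitude:

* **N.am** = nitrogen single-bonded to a carbon that bears a double bond to
  O or S; **N.pl3** = other trigonal nitrogen conjugated to an sp²/aromatic
  carbon (aniline, guanidine).
* **Aromaticity**: MOL2 `ar` bond records are trusted verbatim when
  present; otherwise (SDF Kekulé input) RDKit perceives aromaticity, and
  the perception source is noted in the assignment warnings.
* Charged atoms, iodine, and hydrogens on sulfur have no rows in either
  published table and are rejected (or left untyped in permissive mode,
  which scoring then refuses). Custom JSON tables can extend coverage.

## Monte Carlo volumes

V_mol = V_box·N_hits/N_trials with uniform sampling in the tight
axis-aligned box enclosing all van der Waals spheres (radii: C 1.53, N
1.45, O 1.36, S 1.70, H 1.08, F 1.30, Cl 1.65, Br 1.80, I 2.05 Å). The
estimator is unbiased for any enclosing box, so the input-frame orientation
affects only variance. Boundary points count as hits (closed spheres) — a
measure-zero convention fixed for determinism. The binomial standard error
V_box·√(p̂(1−p̂)/N) is always reported; the default 10⁶ trials puts the
relative error well below 1% for drug-sized molecules. Phosphorus has
parameters in the energy tables but no radius in the list above; volume
calls must supply one explicitly (`--radius P=…`). The generator is seeded
and bitwise reproducible.

## Genetic-algorithm fitting

Fragmental volumes converge badly when optimized jointly with the
energetic parameters, so fitting is two-staged: V_j first against Monte
Carlo molecular volumes (F_V = Σ_k |V_mol,k − Σ_atoms V|), then S, O_max
and optionally P with V frozen (F_s = Σ_k |ΔG_ref,k − ΔG_calc,k|). With V
frozen the occupancies are constants, so stage 2 precomputes per-molecule,
per-type atom counts and occupancy sums and evaluates F_s as a small
matrix expression; a test pins this fast path to molecule-by-molecule
evaluation through the energy module.

The optimizer is an elitist real-coded GA: population 100, the best 50
kept each generation by truncation (tournament selection is a config
option), the other 50 refilled from survivors by crossover then point
mutation. Operator design, where the classic recipe is under-specified:

* **Crossover** (probability 0.6 per child): either uniform entry swapping
  or, with probability 0.5, an arithmetic blend that samples the child
  along the parent difference (u ~ U(−0.25, 1.25), clipped to bounds). The
  blend supplies correlated moves — e.g. along the S·O_max valley of the
  stage-2 surface — that coordinate-wise swapping cannot generate.
* **Mutation** (per-entry probability, default 0.01): with probability 0.7
  a local Gaussian nudge whose sd is drawn log-uniformly over six decades
  below 0.1× the bound width (so the search can refine far below the bound
  scale), otherwise a uniform resample within bounds (global escape).
  The 0.01 default corresponds to ~1.5 mutations per child for a
  148-entry genome; for small genomes scale it to a few mutations per
  child (the recovery experiments use 0.5 for 6-entry genomes).
* **Bounds** default to V ∈ (0, 40] Å³, O_max ∈ [250, 420] Å³,
  S, P ∈ [−30, 30] kcal mol⁻¹ Å⁻³, bracketing the published tables with
  margin; every genome ever evaluated is kept within bounds by
  construction.
* **Initialization**: uniform random within bounds; the template genome's
  own values occupy one slot (warm start from the builtin table when
  schemes match).
* **Termination**: generation cap (default 10 000), or a plateau — best
  fitness improving by < 1e−6 over 500 consecutive generations. Elitism
  makes the per-generation best fitness non-increasing, which is asserted
  on the recorded history.
* A non-finite fitness aborts the run with the offending genome in the
  message. The full (seed, config, data) triple determines the result;
  stage seeds are derived from the pipeline seed via `SeedSequence`.

F_s is reported both as the raw sum and as the per-molecule mean, since
the sum scales with dataset size and only the mean is comparable across
datasets.

## Synthetic datasets and what recovery experiments show

`fixtures.make_synthetic_dataset` emits random self-avoiding 3-D chains of
typed pseudo-atoms (default 30 molecules of 2–6 atoms, 4.5 Å steps,
self-avoidance at 4.2 Å) with two kinds of targets computed by the
package's own modules: ΔG under a known truth table (plus optional
Gaussian noise from an independent stream, default sd 0) and Monte Carlo
volumes at 10⁶ trials with per-molecule derived seeds.

The default two-type truth (`two_type_truth`) sets V to the isolated vdW
sphere volumes of the mapped elements, so the disjoint-sphere chain
volumes decompose exactly over atoms and the stage-1 fit has a zero-error
optimum at the truth; S and P are small enough that the nearly fully
exposed chain atoms produce per-molecule energies in the realistic
−35…+5 kcal/mol range. (Published-magnitude S and P would give
thousands of kcal/mol on sparse chains; those values balance only for
densely packed real molecules.)

These experiments are *self-referential*: they demonstrate that the
pipeline recovers the energies implied by known generating parameters —
identifiability of the parameterization, correctness of the fitness
plumbing, convergence of the optimizer — typically to a mean absolute
error of ~0.005 kcal/mol (worst ~0.03 across seeds). They do **not**
demonstrate accuracy against experimental solvation data, which requires
real reference sets of quantum-optimized structures with measured
energies; nor do the chain pseudo-molecules exercise bonded-distance
occupancies, conformational strain, or realistic type co-occurrence.

## Numerical conventions

* Coordinates and all volumes in Å/Å³, energies kcal/mol, pressures
  converted to atm (760 mmHg = 101 325 Pa = 1 atm).
* R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; p⁰ = (1 mol/L)·R·T ≈ 24.465 atm at
  298.15 K. The conversion implements
  ΔG = −2.303·R·T·log₁₀(M·p⁰/p) — the reading under which high solubility
  and low volatility give favorable (negative) ΔG, consistent with the
  definition of p⁰; the inverted literal ratio M·p/p⁰ is available behind
  `strict_literal` for auditing only.
* Per-atom totals accumulate in float64; tests hold vectorized-vs-naive
  agreement and rigid-motion/permutation invariance to 1e−9 kcal/mol.
* MOL2 written with 4-decimal coordinates; scoring never depends on writer
  precision. XYZ bond perception (optional) bonds atoms at
  r < 1.2 × (sum of covalent radii) and yields single bonds only.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on generated
inputs: 200 random ≤8-atom molecules for the kernel audit, 100 random
rigid motions, 10⁶-trial Monte Carlo volumes, and one 30-molecule
two-type recovery fit capped at 2000 generations per stage — a few tens of
seconds end to end on one CPU.

## Known limitations

* Typing covers neutral organics over {C, N, O, S, P, H, F, Cl, Br};
  charged species, iodine (which has a radius but no energy parameters),
  and exotic groups need custom tables.
* No conformer ensembles, no forces/gradients, no solvent or temperature
  generalization, no protein-scale scoring.
* The GA is a global heuristic: convergence to the listed tolerances is
  demonstrated for the small recovery problems, not guaranteed for
  arbitrary refits; the plateau detector and per-stage fitness metadata
  exist so users can judge each run.
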