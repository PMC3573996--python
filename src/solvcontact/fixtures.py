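"""Deterministic toy molecules and synthetic fitting datasets.

The toy templates use idealized geometry (C-C 1.54 A, C-O 1.43 A, C-H
1.09 A, tetrahedral/trigonal angles) rather than quantum-optimized
structures; declared bond lengths are reproduced to 1e-6 A.  The synthetic
dataset generator emits random self-avoiding chains of typed pseudo-atoms
whose solvation targets are computed with the energy module under a known
("truth") parameter table, enabling parameter-recovery experiments in
which the fitted model is checked against its own generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from solvcontact.atomtypes import TypeAssignment
from solvcontact.energy import solvation_energy
from solvcontact.ga import FitDataset
from solvcontact.mol import Atom, Bond, Molecule
from solvcontact.parameters import AtomParameters, ParameterTable
from solvcontact.volume import DEFAULT_RADII, mc_volume

TEMPLATES = ("single_atom", "diatomic", "linear_chain", "methane", "ethanol",
             "benzene", "acetamide", "dimethyl_ether")

_TET = math.acos(-1.0 / 3.0)  # tetrahedral angle, 109.471 deg


@dataclass
class ToyMoleculeSpec:
    template: str
    element: str = "C"                      # single_atom
    elements: tuple[str, ...] | None = None  # diatomic / linear_chain
    bond_length: float = 1.54               # diatomic / chain spacing, A


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = _unit(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(a, ref))
    return u, np.cross(a, u)


def _tetra_dirs(axis: np.ndarray, n: int = 3, phase: float = 0.0) -> list[np.ndarray]:
    """Unit vectors at the tetrahedral angle from `axis`, 120 deg apart."""
    a = _unit(axis)
    u, v = _orthonormal(a)
    out = []
    for k in range(n):
        phi = phase + 2.0 * math.pi * k / 3.0
        out.append(-a / 3.0 + (math.sqrt(8.0) / 3.0) * (math.cos(phi) * u + math.sin(phi) * v))
    return out


def _bend(anchor: np.ndarray, center: np.ndarray, length: float, angle_deg: float,
          out_of_plane: np.ndarray | None = None) -> np.ndarray:
    """Point at `length` from `center` making `angle_deg` with center->anchor, in-plane."""
    b = _unit(anchor - center)
    u, v = _orthonormal(b)
    n = u if out_of_plane is None else _unit(np.cross(b, out_of_plane))
    ang = math.radians(angle_deg)
    return center + length * (math.cos(ang) * b + math.sin(ang) * n)


def make_toy(spec: ToyMoleculeSpec | str, **overrides) -> Molecule:
    """Build a toy molecule from a named template."""
    if isinstance(spec, str):
        spec = ToyMoleculeSpec(template=spec, **overrides)
    builder = _BUILDERS.get(spec.template)
    if builder is None:
        raise ValueError(f"unknown template {spec.template!r}; choose from {TEMPLATES}")
    return builder(spec)


def _mk(name: str, elements: list[str], coords: list, bonds: list[tuple]) -> Molecule:
    atoms = [Atom(index=i, element=el, coords=np.asarray(c, float))
             for i, (el, c) in enumerate(zip(elements, coords))]
    return Molecule(name=name, atoms=atoms,
                    bonds=[Bond(a=a, b=b, order=o) for a, b, o in bonds])


def _single_atom(spec: ToyMoleculeSpec) -> Molecule:
    return _mk(f"{spec.element}-atom", [spec.element], [(0.0, 0.0, 0.0)], [])


def _diatomic(spec: ToyMoleculeSpec) -> Molecule:
    els = spec.elements or ("Cl", "Cl")
    return _mk("-".join(els), list(els),
               [(0.0, 0.0, 0.0), (0.0, 0.0, spec.bond_length)], [(0, 1, 1)])


def _linear_chain(spec: ToyMoleculeSpec) -> Molecule:
    els = spec.elements or ("C", "C", "C")
    coords = [(0.0, 0.0, k * spec.bond_length) for k in range(len(els))]
    bonds = [(k, k + 1, 1) for k in range(len(els) - 1)]
    return _mk("chain", list(els), coords, bonds)


def _methane(spec: ToyMoleculeSpec) -> Molecule:
    c = np.zeros(3)
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3.0)
    coords = [c] + [c + 1.09 * d for d in dirs]
    bonds = [(0, k, 1) for k in range(1, 5)]
    return _mk("methane", ["C", "H", "H", "H", "H"], coords, bonds)


def _ethanol(spec: ToyMoleculeSpec) -> Molecule:
    c1 = np.zeros(3)
    c2 = np.array([1.54, 0.0, 0.0])
    o = _bend(c1, c2, 1.43, math.degrees(_TET))
    h_c1 = [c1 + 1.09 * d for d in _tetra_dirs(c2 - c1)]
    # the two methylene hydrogens: tetrahedral directions from C2 avoiding C1 and O
    axis = -((_unit(c1 - c2) + _unit(o - c2)))
    u = _unit(np.cross(c1 - c2, o - c2))
    half = _TET / 2.0
    h_c2 = [c2 + 1.09 * (math.cos(half) * _unit(axis) + s * math.sin(half) * u)
            for s in (1.0, -1.0)]
    h_o = _bend(c2, o, 0.96, 104.5)
    elements = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    coords = [c1, c2, o, *h_c1, *h_c2, h_o]
    bonds = [(0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
             (1, 6, 1), (1, 7, 1), (2, 8, 1)]
    return _mk("ethanol", elements, coords, bonds)


def _benzene(spec: ToyMoleculeSpec) -> Molecule:
    # regular hexagon: ring radius equals the 1.40 A aromatic C-C bond
    r_c, r_h = 1.40, 1.40 + 1.09
    coords, elements = [], []
    for k in range(6):
        ang = math.pi * k / 3.0
        coords.append((r_c * math.cos(ang), r_c * math.sin(ang), 0.0))
        elements.append("C")
    for k in range(6):
        ang = math.pi * k / 3.0
        coords.append((r_h * math.cos(ang), r_h * math.sin(ang), 0.0))
        elements.append("H")
    bonds = [(k, (k + 1) % 6, "ar") for k in range(6)] + [(k, k + 6, 1) for k in range(6)]
    return _mk("benzene", elements, coords, bonds)


def _acetamide(spec: ToyMoleculeSpec) -> Molecule:
    c1 = np.zeros(3)
    c2 = np.array([1.52, 0.0, 0.0])
    o = _bend(c1, c2, 1.23, 120.0)
    n = _bend(c1, c2, 1.35, -120.0)
    h_c1 = [c1 + 1.09 * d for d in _tetra_dirs(c2 - c1)]
    h_n = [_bend(c2, n, 1.01, 120.0), _bend(c2, n, 1.01, -120.0)]
    elements = ["C", "C", "O", "N", "H", "H", "H", "H", "H"]
    coords = [c1, c2, o, n, *h_c1, *h_n]
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, "am"), (0, 4, 1), (0, 5, 1), (0, 6, 1),
             (3, 7, 1), (3, 8, 1)]
    return _mk("acetamide", elements, coords, bonds)


def _dimethyl_ether(spec: ToyMoleculeSpec) -> Molecule:
    o = np.zeros(3)
    half = math.radians(111.0 / 2.0)
    c1 = 1.43 * np.array([math.sin(half), math.cos(half), 0.0])
    c2 = 1.43 * np.array([-math.sin(half), math.cos(half), 0.0])
    h1 = [c1 + 1.09 * d for d in _tetra_dirs(o - c1)]
    h2 = [c2 + 1.09 * d for d in _tetra_dirs(o - c2, phase=0.5)]
    elements = ["O", "C", "C"] + ["H"] * 6
    coords = [o, c1, c2, *h1, *h2]
    bonds = [(0, 1, 1), (0, 2, 1), (1, 3, 1), (1, 4, 1), (1, 5, 1),
             (2, 6, 1), (2, 7, 1), (2, 8, 1)]
    return _mk("dimethyl-ether", elements, coords, bonds)


_BUILDERS = {
    "single_atom": _single_atom,
    "diatomic": _diatomic,
    "linear_chain": _linear_chain,
    "methane": _methane,
    "ethanol": _ethanol,
    "benzene": _benzene,
    "acetamide": _acetamide,
    "dimethyl_ether": _dimethyl_ether,
}


# --------------------------------------------------------------------------
# Synthetic fitting datasets
# --------------------------------------------------------------------------

@dataclass
class SyntheticDatasetSpec:
    """Recipe for a self-consistent synthetic fitting dataset.

    Molecules are random self-avoiding 3-D chains of pseudo-atoms typed
    directly from the truth table's labels (``type_elements`` maps each
    label to a real element for van der Waals radii).  The default 4.5 A
    step keeps all sphere pairs disjoint, so molecular volumes decompose
    additively over atoms, while the sigma = 3.5 A occupancy envelope still
    couples every pair energetically.
    """

    truth: ParameterTable
    type_elements: dict[str, str]
    n_molecules: int = 30
    atoms_per_molecule: tuple[int, int] = (2, 6)
    noise_sd: float = 0.0          # kcal/mol, Gaussian noise on dG targets
    spacing: float = 4.5           # chain step, A
    min_separation: float = 4.2    # self-avoidance cutoff, A
    mc_trials: int = 1_000_000     # Monte Carlo volume trials per molecule
    seed: int = 0


def two_type_truth(seed: int = 0) -> tuple[ParameterTable, dict[str, str]]:
    """A small two-type truth table for recovery experiments.

    The fragmental volumes equal the isolated vdW sphere volumes of the
    mapped elements (C and O), so that disjoint-sphere chain volumes are
    exactly decomposable and stage-1 volume fitting has a zero-error
    optimum at the truth.  S and P are chosen so that sparse chain
    pseudo-molecules — whose atoms are almost fully solvent-exposed —
    get per-molecule energies in the habitual few-tens-of-kcal/mol range
    of real solvation data, with both terms contributing.
    """
    v_c = 4.0 / 3.0 * math.pi * DEFAULT_RADII["C"] ** 3  # 15.002 A^3
    v_o = 4.0 / 3.0 * math.pi * DEFAULT_RADII["O"] ** 3  # 10.536 A^3
    entries = {
        "X.c": AtomParameters(V=v_c, O_max=330.0, S=0.010, P=-0.12),
        "X.o": AtomParameters(V=v_o, O_max=360.0, S=-0.025, P=0.25),
    }
    truth = ParameterTable(scheme="custom", entries=entries)
    return truth, {"X.c": "C", "X.o": "O"}


def _random_chain(rng: np.random.Generator, n_atoms: int, labels: list[str],
                  type_elements: dict[str, str], spacing: float,
                  min_sep: float, name: str) -> tuple[Molecule, TypeAssignment]:
    pos = [np.zeros(3)]
    while len(pos) < n_atoms:
        for _attempt in range(200):
            step = rng.normal(size=3)
            cand = pos[-1] + spacing * step / np.linalg.norm(step)
            if all(np.linalg.norm(cand - p) >= min_sep for p in pos):
                pos.append(cand)
                break
        else:  # pragma: no cover - effectively unreachable at these densities
            raise RuntimeError("self-avoiding walk failed to place an atom")
    chosen = [labels[k] for k in rng.integers(0, len(labels), size=n_atoms)]
    atoms = [Atom(index=i, element=type_elements[lbl], coords=p)
             for i, (lbl, p) in enumerate(zip(chosen, pos))]
    bonds = [Bond(a=k, b=k + 1, order=1) for k in range(n_atoms - 1)]
    mol = Molecule(name=name, atoms=atoms, bonds=bonds)
    asg = TypeAssignment(scheme="custom", labels=list(chosen))
    return mol, asg


def make_synthetic_dataset(spec: SyntheticDatasetSpec) -> FitDataset:
    """Generate a FitDataset with dG and Monte Carlo volume targets.

    Targets come from the energy and volume modules themselves (single
    source of truth): dG = model energy under the truth table plus optional
    Gaussian noise; V_mol from :func:`mc_volume` with per-molecule seeds
    derived from the dataset seed.  Regeneration from the same spec is
    bitwise identical.
    """
    labels = sorted(spec.truth.entries)
    missing = set(labels) - set(spec.type_elements)
    if missing:
        raise ValueError(f"type_elements lacks entries for {sorted(missing)}")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lo, hi = spec.atoms_per_molecule
    if not 1 <= lo <= hi:
        raise ValueError("invalid atoms_per_molecule range")

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    # separate streams so the noise level never perturbs geometry or volumes
    noise_rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 2))
    mc_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                for c in np.random.SeedSequence(spec.seed + 1).spawn(spec.n_molecules)]

    include_self = spec.truth.has_self_solvation
    molecules: list[tuple[Molecule, TypeAssignment]] = []
    dg = np.empty(spec.n_molecules)
    vol = np.empty(spec.n_molecules)
    for k in range(spec.n_molecules):
        n_atoms = int(rng.integers(lo, hi + 1))
        mol, asg = _random_chain(rng, n_atoms, labels, spec.type_elements,
                                 spec.spacing, spec.min_separation, f"synthetic-{k}")
        res = solvation_energy(mol, spec.truth, include_self=include_self, assignment=asg)
        dg[k] = res.total + (noise_rng.normal(0.0, spec.noise_sd)
                             if spec.noise_sd > 0 else 0.0)
        vol[k] = mc_volume(mol, n_trials=spec.mc_trials, seed=mc_seeds[k]).V_mol
        molecules.append((mol, asg))
    return FitDataset(molecules=molecules, dg_targets=dg, volume_targets=vol,
                      metadata={"seed": spec.seed, "noise_sd": spec.noise_sd,
                                "mc_trials": spec.mc_trials,
                                "truth_checksum": spec.truth.checksum()})
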