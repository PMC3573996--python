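"""The solvation free energy kernel.

For atom i with type parameters (V, O_max, S, P):

    O_i     = sum_{j != i} V_{type(j)} * exp(-r_ij^2 / (2 sigma^2))   (occupied volume)
    F_i     = O_max_i - O_i                                           (solvent-exposed volume)
    dG_i    = S_i * F_i            (solute-solvent term)
            + P_i * O_i            (intramolecular self-solvation term, optional)
    dG_sol  = sum_i dG_i

Hydrogens participate in the occupancy sums (both tables parameterize H
types), all j != i pairs are included regardless of bonding, and F_i is
used as-is even when O_i exceeds O_max (a warning is recorded instead of
clamping).  The kernel is vectorized over the full distance matrix; no
distance cutoff is applied by default because the sigma = 3.5 A Gaussian
decays slowly on molecular length scales.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from solvcontact.atomtypes import TypeAssignment, assign_types
from solvcontact.mol import Molecule
from solvcontact.parameters import ParameterTable, builtin_table


@dataclass
class AtomContribution:
    index: int
    element: str
    type_label: str
    O: float        # occupied volume, A^3
    F: float        # solvent-exposed volume, A^3
    dG_solv: float  # S * F, kcal/mol
    dG_self: float  # P * O, kcal/mol (0 when the self term is off)


@dataclass
class SolvationResult:
    total: float  # kcal/mol
    per_atom: list[AtomContribution]
    scheme: str
    include_self: bool
    warnings: list[str] = field(default_factory=list)


def envelope(r, sigma: float):
    """Gaussian envelope weight exp(-r^2 / (2 sigma^2)); 1 at contact, ->0 at infinity."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(r, dtype=float)
    out = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    return float(out) if out.ndim == 0 else out


def _weight_matrix(coords: np.ndarray, sigma: float, cutoff: float | None) -> np.ndarray:
    delta = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", delta, delta)
    w = np.exp(-r2 / (2.0 * sigma ** 2))
    np.fill_diagonal(w, 0.0)
    if cutoff is not None:
        w[np.sqrt(r2) > cutoff] = 0.0
    return w


def _volumes_vector(assignment: TypeAssignment, table: ParameterTable) -> np.ndarray:
    vols = np.empty(len(assignment.labels))
    for i, lbl in enumerate(assignment.labels):
        if lbl is None:
            raise ValueError(f"atom {i} is untyped; scoring requires full type coverage")
        if lbl not in table:
            raise KeyError(f"atom {i}: type {lbl!r} has no entry in the parameter table")
        vols[i] = table[lbl].V
    return vols


def occupancies(mol: Molecule, assignment: TypeAssignment, table: ParameterTable,
                cutoff: float | None = None) -> np.ndarray:
    """Occupied volume O_i for every atom, A^3 (vectorized)."""
    if len(assignment.labels) != mol.n_atoms:
        raise ValueError("assignment does not cover the molecule")
    vols = _volumes_vector(assignment, table)
    if mol.n_atoms == 0:
        return np.zeros(0)
    w = _weight_matrix(mol.coords, table.sigma, cutoff)
    return w @ vols


def occupancy(mol: Molecule, assignment: TypeAssignment, table: ParameterTable,
              i: int) -> float:
    """Occupied volume around atom ``i``: sum_{j != i} V_type(j) * envelope(r_ij)."""
    if not 0 <= i < mol.n_atoms:
        raise IndexError(f"atom index {i} out of range")
    return float(occupancies(mol, assignment, table)[i])


def solvation_energy(mol: Molecule, table: ParameterTable | None = None,
                     include_self: bool = True,
                     assignment: TypeAssignment | None = None,
                     cutoff: float | None = None) -> SolvationResult:
    """Total and per-atom solvation free energy of a molecule, kcal/mol.

    ``include_self`` adds the P_i * O_i intramolecular term and requires a
    table in which every type carries P.  When no assignment is given the
    molecule is typed for the table's scheme (custom tables then need an
    explicit assignment).
    """
    if table is None:
        table = builtin_table("extended37")
    if assignment is None:
        if table.scheme not in ("basic23", "extended37"):
            raise ValueError("custom parameter tables need an explicit TypeAssignment")
        assignment = assign_types(mol, scheme=table.scheme)
    if len(assignment.labels) != mol.n_atoms:
        raise ValueError("assignment does not cover the molecule")
    if include_self and not table.has_self_solvation:
        raise ValueError("include_self requires P for every type in the table")

    O = occupancies(mol, assignment, table, cutoff=cutoff)
    result_warnings = list(assignment.warnings)
    per_atom: list[AtomContribution] = []
    total = 0.0
    for i, lbl in enumerate(assignment.labels):
        p = table[lbl]
        F = p.O_max - O[i]
        if F < 0:
            msg = f"atom {i} ({lbl}): occupied volume {O[i]:.1f} exceeds O_max {p.O_max:.1f}"
            result_warnings.append(msg)
            _warnings.warn(msg, stacklevel=2)
        dG_solv = p.S * F
        dG_self = (p.P * O[i]) if include_self else 0.0
        total += dG_solv + dG_self
        per_atom.append(AtomContribution(index=i, element=mol.atoms[i].element,
                                         type_label=lbl, O=float(O[i]), F=float(F),
                                         dG_solv=float(dG_solv), dG_self=float(dG_self)))
    return SolvationResult(total=float(total), per_atom=per_atom,
                           scheme=assignment.scheme, include_self=include_self,
                           warnings=result_warnings)


def compare_models(mol: Molecule) -> dict:
    """Score one molecule under both published models.

    Returns ``{"dG_basic": ..., "dG_full": ...}`` — the legacy 23-type model
    without the self-solvation term and the 37-type model with it — from a
    single extended typing pass (the basic assignment is the collapsed one,
    so both energies refer to identical perception decisions).
    """
    from solvcontact.atomtypes import collapse_to_basic

    ext = assign_types(mol, scheme="extended37")
    basic = collapse_to_basic(ext)
    res_basic = solvation_energy(mol, builtin_table("basic23"), include_self=False,
                                 assignment=basic)
    res_full = solvation_energy(mol, builtin_table("extended37"), include_self=True,
                                assignment=ext)
    return {"dG_basic": res_basic.total, "dG_full": res_full.total,
            "result_basic": res_basic, "result_full": res_full}
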