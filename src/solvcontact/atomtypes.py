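"""Sybyl-style atom typing for the solvent-contact solvation model.

Two closed schemes are supported:

* ``basic23`` — 23 types distinguishing element and hybridization
  (C.3, C.2, C.1, C.ar, N.3, ..., H.C, H.N, H.O);
* ``extended37`` — 37 types that additionally subdivide sp3/sp2/aromatic
  carbon, sp3/amide/planar nitrogen and sp3 oxygen by the number of heavy
  (non-hydrogen) substituents, e.g. ``C.3_2`` = sp3 carbon with 2 heavy
  neighbors.

A *substituent* is a non-hydrogen bonded neighbor.  This is the only
counting convention under which a hydroxyl oxygen has 1 substituent and an
ether oxygen 2, matching the published type descriptions.  Substituent
counts outside the published range (e.g. methane's carbon with 0 heavy
neighbors) are clamped to the nearest available count with a warning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from solvcontact.mol import Molecule

BASIC23_LABELS = (
    "C.3", "C.2", "C.1", "C.ar",
    "N.3", "N.2", "N.1", "N.am", "N.ar", "N.pl3",
    "O.3", "O.2",
    "S.3", "S.2", "S.O", "S.O2",
    "P", "F", "Cl", "Br",
    "H.C", "H.N", "H.O",
)

# parent basic type -> substituent counts that exist in the extended scheme
_SUBDIVIDED = {
    "C.3": (1, 2, 3, 4),
    "C.2": (1, 2, 3),
    "C.1": (1, 2),
    "C.ar": (2, 3),
    "N.3": (1, 2, 3),
    "N.am": (1, 2, 3),
    "N.pl3": (1, 2, 3),
    "O.3": (1, 2),
}

EXTENDED37_LABELS = tuple(
    f"{base}_{n}"
    for base in ("C.3", "C.2", "C.1", "C.ar", "N.3", "N.am", "N.pl3", "O.3")
    for n in _SUBDIVIDED[base]
) + ("N.2", "N.1", "N.ar", "O.2", "S.3", "S.2", "S.O", "S.O2",
     "P", "F", "Cl", "Br", "H.C", "H.N", "H.O")


class TypingError(ValueError):
    """Atom(s) fall outside the requested type scheme."""


@dataclass
class TypeAssignment:
    scheme: str  # "basic23", "extended37" or "custom"
    labels: list[str | None]
    warnings: list[str] = field(default_factory=list)

    def type_counts(self) -> Counter:
        return Counter(lbl for lbl in self.labels if lbl is not None)


def count_substituents(mol: Molecule, i: int) -> int:
    """Number of non-hydrogen bonded neighbors of atom ``i``."""
    return sum(1 for j in mol.neighbors(i) if mol.atoms[j].element != "H")


def _bond_orders(mol: Molecule, i: int) -> list:
    return [b.order for b in mol.bonds_of(i)]


def _aromatic_flags(mol: Molecule, warnings: list[str]) -> list[bool]:
    """Per-atom aromaticity.

    MOL2 ``ar`` bond annotations are trusted when the molecule carries any;
    otherwise aromaticity is perceived with RDKit from the Kekule structure
    (the perception source is recorded in the warnings).
    """
    if any(b.order == "ar" for b in mol.bonds):
        flags = [False] * mol.n_atoms
        for b in mol.bonds:
            if b.order == "ar":
                flags[b.a] = flags[b.b] = True
        return flags
    if not any(o == 2 for o in (b.order for b in mol.bonds)):
        return [False] * mol.n_atoms  # no unsaturation, nothing to perceive
    try:
        flags = _rdkit_aromaticity(mol)
        if any(flags):
            warnings.append("aromaticity perceived by RDKit from Kekule bond orders")
        return flags
    except Exception as exc:  # pragma: no cover - sanitization failures are molecule-specific
        warnings.append(f"RDKit aromaticity perception failed ({exc}); assuming non-aromatic")
        return [False] * mol.n_atoms


def _rdkit_aromaticity(mol: Molecule) -> list[bool]:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE,
                 "am": Chem.BondType.SINGLE, "ar": Chem.BondType.AROMATIC}
    for b in mol.bonds:
        rw.AddBond(b.a, b.b, order_map[b.order])
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    return [a.GetIsAromatic() for a in m.GetAtoms()]


def _base_type(mol: Molecule, i: int, aromatic: list[bool]) -> str:
    """Element + hybridization/context type in the 23-type vocabulary."""
    atom = mol.atoms[i]
    el = atom.element
    if atom.formal_charge != 0:
        raise TypingError(f"atom {i} ({el}): charged atoms are outside both schemes")
    orders = _bond_orders(mol, i)

    if el == "H":
        nbrs = mol.neighbors(i)
        if len(nbrs) != 1:
            raise TypingError(f"atom {i} (H): hydrogen must have exactly one bond")
        partner = mol.atoms[nbrs[0]].element
        if partner in ("C", "N", "O"):
            return f"H.{partner}"
        raise TypingError(f"atom {i} (H): hydrogen bonded to {partner} is not parameterized")

    if el == "C":
        if aromatic[i]:
            return "C.ar"
        n_triple = orders.count(3)
        n_double = orders.count(2)
        if n_triple or n_double >= 2:
            return "C.1"
        if n_double:
            return "C.2"
        return "C.3"

    if el == "N":
        if _is_amide_nitrogen(mol, i):
            return "N.am"
        if aromatic[i]:
            return "N.ar"
        if 3 in orders:
            return "N.1"
        if 2 in orders:
            return "N.2"
        if _is_planar_nitrogen(mol, i, aromatic):
            return "N.pl3"
        return "N.3"

    if el == "O":
        if 2 in orders:
            return "O.2"
        return "O.3"  # Sybyl types ether, hydroxyl and furan-like O as O.3

    if el == "S":
        n_terminal_o = sum(
            1 for j in mol.neighbors(i)
            if mol.atoms[j].element == "O" and count_substituents(mol, j) == 1
            and not any(mol.atoms[k].element == "H" for k in mol.neighbors(j))
        )
        if n_terminal_o >= 2:
            return "S.O2"
        if n_terminal_o == 1:
            return "S.O"
        if 2 in orders or aromatic[i]:
            return "S.2"
        return "S.3"

    if el in ("P", "F", "Cl", "Br"):
        return el

    raise TypingError(f"atom {i} ({el}): element outside both type schemes")


def _is_amide_nitrogen(mol: Molecule, i: int) -> bool:
    """N single-bonded to a carbon that bears a double bond to O or S."""
    for b in mol.bonds_of(i):
        j = b.b if b.a == i else b.a
        if mol.atoms[j].element != "C" or b.order not in (1, "am"):
            continue
        for bc in mol.bonds_of(j):
            k = bc.b if bc.a == j else bc.a
            if bc.order == 2 and mol.atoms[k].element in ("O", "S"):
                return True
    return False


def _is_planar_nitrogen(mol: Molecule, i: int, aromatic: list[bool]) -> bool:
    """Non-amide trigonal N conjugated to an sp2/aromatic system (aniline, guanidine)."""
    for j in mol.neighbors(i):
        nbr = mol.atoms[j]
        if nbr.element != "C":
            continue
        if aromatic[j] or any(b.order == 2 for b in mol.bonds_of(j)):
            return True
    return False


def assign_types(mol: Molecule, scheme: str = "extended37",
                 permissive: bool = False) -> TypeAssignment:
    """Assign each atom one solvent-contact atom type.

    In strict mode (default), any atom outside the scheme raises
    :class:`TypingError` listing the offenders; ``permissive`` instead marks
    those atoms untyped (``None``) and records a warning, so scoring — which
    requires full coverage — will refuse later.
    """
    if scheme not in ("basic23", "extended37"):
        raise ValueError(f"unknown scheme {scheme!r}; expected 'basic23' or 'extended37'")
    if mol.n_atoms and not mol.bonds and mol.n_atoms > 1:
        raise TypingError("typing requires connectivity; supply bonds or perceive them")

    warnings: list[str] = []
    aromatic = _aromatic_flags(mol, warnings)
    labels: list[str | None] = []
    failures: list[str] = []
    for i in range(mol.n_atoms):
        try:
            base = _base_type(mol, i, aromatic)
        except TypingError as exc:
            if permissive:
                warnings.append(str(exc))
                labels.append(None)
                continue
            failures.append(str(exc))
            labels.append(None)
            continue
        if scheme == "basic23":
            labels.append(base)
            continue
        available = _SUBDIVIDED.get(base)
        if available is None:
            labels.append(base)
            continue
        n_sub = count_substituents(mol, i)
        if n_sub in available:
            labels.append(f"{base}_{n_sub}")
        else:
            clamped = min(available, key=lambda v: abs(v - n_sub))
            warnings.append(
                f"atom {i} ({base}): {n_sub} heavy substituents outside published "
                f"range {available}; clamped to {clamped}")
            labels.append(f"{base}_{clamped}")
    if failures:
        raise TypingError("; ".join(failures))
    return TypeAssignment(scheme=scheme, labels=labels, warnings=warnings)


def collapse_to_basic(assignment: TypeAssignment) -> TypeAssignment:
    """Map extended 37-type labels onto their 23-type parents (strip the suffix)."""
    if assignment.scheme != "extended37":
        raise ValueError("collapse_to_basic expects an extended37 assignment")
    labels = [lbl.split("_")[0] if lbl is not None else None for lbl in assignment.labels]
    return TypeAssignment(scheme="basic23", labels=labels,
                          warnings=list(assignment.warnings))
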