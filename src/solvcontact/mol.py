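"""Molecule data model and structure-file I/O (Sybyl MOL2, SDF/MOL V2000, XYZ).

Coordinates are always in Angstrom; no unit autodetection is attempted.
The MOL2 reader is format-faithful: unknown or dummy Sybyl atom types are
kept verbatim and rejected only when typing or scoring is requested.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np

# Elements parameterized by the solvation model (iodine has a vdW radius but
# no solvation parameters; it is accepted here and rejected at typing time).
SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "S", "P", "H", "F", "Cl", "Br", "I"})

# Covalent radii (A) for optional distance-based bond perception on XYZ input.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

BondOrder = Union[int, str]  # 1, 2, 3, "ar" (aromatic), "am" (amide)


class ParseError(ValueError):
    """Malformed structure file; message names the offending line when known."""


@dataclass
class Atom:
    index: int
    element: str
    coords: np.ndarray
    sybyl_type: str | None = None
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coordinates must be 3 finite numbers")


@dataclass
class Bond:
    a: int
    b: int
    order: BondOrder = 1

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"bond connects atom {self.a} to itself")


@dataclass
class Molecule:
    """A single-conformer solute: ordered atoms plus a connectivity graph."""

    name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise ValueError(f"bond ({b.a}, {b.b}) references atom outside 0..{n - 1}")
            key = (min(b.a, b.b), max(b.a, b.b))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {b.a} and {b.b}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        if not 0 <= i < self.n_atoms:
            raise IndexError(f"atom index {i} out of range")
        out = []
        for b in self.bonds:
            if b.a == i:
                out.append(b.b)
            elif b.b == i:
                out.append(b.a)
        return out

    def bonds_of(self, i: int) -> list[Bond]:
        return [b for b in self.bonds if i in (b.a, b.b)]

    def is_supported(self) -> bool:
        return all(a.element in SUPPORTED_ELEMENTS for a in self.atoms)


def distance(mol: Molecule, i: int, j: int) -> float:
    """Euclidean distance r_ij between atom centers, Angstrom."""
    n = mol.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range for {n}-atom molecule")
    return float(np.linalg.norm(mol.atoms[i].coords - mol.atoms[j].coords))


def _normalize_element(sym: str) -> str:
    return sym[:1].upper() + sym[1:].lower()


def _element_from_sybyl(sybyl_type: str, atom_name: str) -> str:
    head = sybyl_type.split(".")[0]
    el = _normalize_element(head)
    if el in SUPPORTED_ELEMENTS or len(el) <= 2 and el.isalpha():
        return el
    # fall back on the leading letters of the atom name
    letters = "".join(c for c in atom_name if c.isalpha())
    return _normalize_element(letters[:2] if letters[:2] in ("Cl", "Br") else letters[:1])


# --------------------------------------------------------------------------
# Sybyl MOL2
# --------------------------------------------------------------------------

_MOL2_ORDER_IN = {"1": 1, "2": 2, "3": 3, "ar": "ar", "am": "am", "du": 1, "un": 1, "nc": 1}
_MOL2_ORDER_OUT = {1: "1", 2: "2", 3: "3", "ar": "ar", "am": "am"}


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_mol2_all(source: Union[str, TextIO]) -> Iterator[Molecule]:
    """Yield every molecule record in a Tripos MOL2 stream."""
    lines = _as_stream(source).read().splitlines()
    starts = [k for k, ln in enumerate(lines) if ln.strip() == "@<TRIPOS>MOLECULE"]
    if not starts:
        raise ParseError("no @<TRIPOS>MOLECULE record found")
    starts.append(len(lines))
    for rec in range(len(starts) - 1):
        yield _parse_mol2_record(lines, starts[rec], starts[rec + 1])


def read_mol2(source: Union[str, TextIO]) -> Molecule:
    """Read the first molecule of a Tripos MOL2 stream."""
    return next(read_mol2_all(source))


def _parse_mol2_record(lines: Sequence[str], start: int, stop: int) -> Molecule:
    # locate sections within [start, stop)
    sections: dict[str, int] = {}
    for k in range(start, stop):
        s = lines[k].strip()
        if s.startswith("@<TRIPOS>"):
            sections[s[len("@<TRIPOS>"):]] = k
    mstart = sections["MOLECULE"]
    # MOLECULE section: name line then counts line, up to the next section marker
    content = []
    for k in range(mstart + 1, stop):
        s = lines[k].strip()
        if s.startswith("@<TRIPOS>"):
            break
        if s.startswith("#"):
            continue
        content.append((k, lines[k]))
    if len(content) < 2:
        raise ParseError(f"line {mstart + 1}: truncated MOLECULE section")
    name = content[0][1].strip() or "unnamed"
    counts_lineno, counts_line = content[1]
    fields = counts_line.split()
    if not fields:
        raise ParseError(f"line {counts_lineno + 1}: empty counts line")
    try:
        n_atoms = int(fields[0])
        n_bonds = int(fields[1]) if len(fields) > 1 else 0
    except ValueError as exc:
        raise ParseError(f"line {counts_lineno + 1}: non-integer atom/bond counts") from exc

    atoms: list[Atom] = []
    if "ATOM" not in sections:
        if n_atoms:
            raise ParseError(f"line {mstart + 1}: missing @<TRIPOS>ATOM section")
    else:
        k = sections["ATOM"] + 1
        while len(atoms) < n_atoms:
            if k >= stop or lines[k].strip().startswith("@<TRIPOS>"):
                raise ParseError(
                    f"line {k}: ATOM section ended after {len(atoms)} of {n_atoms} atoms")
            ln = lines[k].strip()
            k += 1
            if not ln or ln.startswith("#"):
                continue
            f = ln.split()
            if len(f) < 6:
                raise ParseError(f"line {k}: ATOM record needs id, name, x, y, z, type")
            try:
                xyz = [float(v) for v in f[2:5]]
            except ValueError as exc:
                raise ParseError(f"line {k}: non-numeric coordinate") from exc
            sybyl = f[5]
            charge = 0
            if len(f) >= 9:
                try:
                    charge = int(round(float(f[8])))
                except ValueError:
                    charge = 0
            atoms.append(Atom(index=len(atoms), element=_element_from_sybyl(sybyl, f[1]),
                              coords=np.array(xyz), sybyl_type=sybyl, formal_charge=charge))

    bonds: list[Bond] = []
    if "BOND" not in sections:
        if n_bonds:
            raise ParseError(f"line {mstart + 1}: missing @<TRIPOS>BOND section")
    else:
        k = sections["BOND"] + 1
        while len(bonds) < n_bonds:
            if k >= stop or lines[k].strip().startswith("@<TRIPOS>"):
                raise ParseError(
                    f"line {k}: BOND section ended after {len(bonds)} of {n_bonds} bonds")
            ln = lines[k].strip()
            k += 1
            if not ln or ln.startswith("#"):
                continue
            f = ln.split()
            if len(f) < 4:
                raise ParseError(f"line {k}: BOND record needs id, origin, target, type")
            try:
                a, b = int(f[1]) - 1, int(f[2]) - 1
            except ValueError as exc:
                raise ParseError(f"line {k}: non-integer atom index in bond") from exc
            if not (0 <= a < n_atoms and 0 <= b < n_atoms):
                raise ParseError(f"line {k}: bond references atom outside 1..{n_atoms}")
            order = _MOL2_ORDER_IN.get(f[3].lower())
            if order is None:
                raise ParseError(f"line {k}: unknown bond type {f[3]!r}")
            bonds.append(Bond(a=a, b=b, order=order))

    return Molecule(name=name, atoms=atoms, bonds=bonds)


def write_mol2(mol: Molecule, stream: TextIO | None = None) -> str:
    """Serialize to Tripos MOL2 with 4-decimal coordinates.

    Scoring never depends on writer precision; the written record round-trips
    through :func:`read_mol2` up to that precision.
    """
    out = io.StringIO()
    out.write("@<TRIPOS>MOLECULE\n")
    out.write(f"{mol.name}\n")
    out.write(f"{mol.n_atoms} {len(mol.bonds)} 0 0 0\n")
    out.write("SMALL\nNO_CHARGES\n")
    out.write("@<TRIPOS>ATOM\n")
    counts: dict[str, int] = {}
    for a in mol.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        name = f"{a.element}{counts[a.element]}"
        styp = a.sybyl_type or a.element
        x, y, z = a.coords
        out.write(f"{a.index + 1:>7d} {name:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                  f"{styp:<8s} 1 UNL {float(a.formal_charge):>8.4f}\n")
    out.write("@<TRIPOS>BOND\n")
    for k, b in enumerate(mol.bonds):
        out.write(f"{k + 1:>6d} {b.a + 1:>5d} {b.b + 1:>5d} {_MOL2_ORDER_OUT[b.order]:>4s}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# --------------------------------------------------------------------------
# MDL SDF / MOL V2000 (via RDKit)
# --------------------------------------------------------------------------

_RDKIT_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": "ar"}


def read_sdf_all(source: Union[str, TextIO]) -> Iterator[Molecule]:
    """Yield every V2000 record of an SDF stream."""
    text = _as_stream(source).read()
    if not text.strip():
        raise ParseError("empty SDF stream")
    blocks = [b for b in text.split("$$$$") if b.strip()]
    for block in blocks:
        yield _parse_molblock(block)


def read_sdf(source: Union[str, TextIO]) -> Molecule:
    """Read the first molecule of an SDF/MOL stream; Sybyl types are left unset."""
    return next(read_sdf_all(source))


def _parse_molblock(block: str) -> Molecule:
    from rdkit import Chem

    lines = block.lstrip("\n").splitlines()
    if len(lines) >= 4 and "V3000" in lines[3]:
        raise ParseError("V3000 MOL blocks are not supported; supply V2000")
    rdmol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
    if rdmol is None:
        raise ParseError("RDKit could not parse the MOL block (malformed counts line?)")
    name = (lines[0].strip() if lines else "") or "unnamed"
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx()) if conf is not None else None
        xyz = (pos.x, pos.y, pos.z) if pos is not None else (0.0, 0.0, 0.0)
        atoms.append(Atom(index=a.GetIdx(), element=a.GetSymbol(), coords=np.array(xyz),
                          sybyl_type=None, formal_charge=a.GetFormalCharge()))
    bonds = []
    for b in rdmol.GetBonds():
        order = _RDKIT_ORDER.get(b.GetBondType().name)
        if order is None:
            raise ParseError(f"unsupported bond type {b.GetBondType().name} in MOL block")
        bonds.append(Bond(a=b.GetBeginAtomIdx(), b=b.GetEndAtomIdx(), order=order))
    return Molecule(name=name, atoms=atoms, bonds=bonds)


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def read_xyz(source: Union[str, TextIO], perceive_bonds_flag: bool = False,
             tolerance: float = 1.2) -> Molecule:
    """Read an XYZ record (no connectivity).

    With ``perceive_bonds_flag`` atoms are bonded when their distance is below
    ``tolerance`` times the sum of covalent radii; all perceived bonds are
    single bonds, so downstream typing of unsaturated systems needs a format
    that carries bond orders.
    """
    lines = _as_stream(source).read().splitlines()
    if not lines:
        raise ParseError("empty XYZ stream")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError("line 1: expected the atom count") from exc
    name = lines[1].strip() if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(f"declared {n} atoms but found {len(atom_lines)} atom lines")
    atoms = []
    for k, ln in enumerate(atom_lines[:n]):
        f = ln.split()
        if len(f) < 4:
            raise ParseError(f"line {k + 3}: expected 'element x y z'")
        try:
            xyz = [float(v) for v in f[1:4]]
        except ValueError as exc:
            raise ParseError(f"line {k + 3}: non-numeric coordinate") from exc
        atoms.append(Atom(index=k, element=_normalize_element(f[0]), coords=np.array(xyz)))
    mol = Molecule(name=name or "unnamed", atoms=atoms, bonds=[])
    if perceive_bonds_flag:
        mol.bonds = perceive_bonds(mol, tolerance=tolerance)
    return mol


def perceive_bonds(mol: Molecule, tolerance: float = 1.2) -> list[Bond]:
    """Distance-based single-bond perception: bonded iff r < tolerance * (r_cov_i + r_cov_j)."""
    bonds = []
    for i in range(mol.n_atoms):
        ri = COVALENT_RADII.get(mol.atoms[i].element)
        for j in range(i + 1, mol.n_atoms):
            rj = COVALENT_RADII.get(mol.atoms[j].element)
            if ri is None or rj is None:
                continue
            if distance(mol, i, j) < tolerance * (ri + rj):
                bonds.append(Bond(a=i, b=j, order=1))
    return bonds
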