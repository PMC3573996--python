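"""Atomic parameter tables for the solvent-contact solvation model.

Two built-in tables are shipped:

* ``basic23`` — the legacy 23-type model (V, O_max, S; 69 parameters, no
  self-solvation term);
* ``extended37`` — the full 37-type model (V, O_max, S, P; 148 parameters)
  with the intramolecular self-solvation parameter P.

Units: V and O_max in A^3; S and P in kcal/(mol*A^3).  The Gaussian
envelope width sigma (default 3.5 A) is stored with the table rather than
hard-coded in the energy kernel, so refit parameter sets may vary it.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, TextIO, Union

DEFAULT_SIGMA = 3.5  # A


@dataclass(frozen=True)
class AtomParameters:
    """Per-type record: fragmental volume V, maximum occupancy O_max,
    solvation parameter S and (optionally) self-solvation parameter P."""

    V: float          # A^3
    O_max: float      # A^3
    S: float          # kcal/(mol*A^3)
    P: float | None = None  # kcal/(mol*A^3); None in the basic scheme

    def __post_init__(self) -> None:
        for name in ("V", "O_max", "S"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.V <= 0:
            raise ValueError(f"V must be positive, got {self.V}")
        if self.O_max <= 0:
            raise ValueError(f"O_max must be positive, got {self.O_max}")
        if self.P is not None and not math.isfinite(self.P):
            raise ValueError("P must be finite when present")


# label: (V, O_max, S) — legacy 23-type model, no self-solvation
_BASIC23 = {
    "C.3":   (8.276, 322.8, 1.619),
    "C.2":   (8.571, 328.9, -0.730),
    "C.1":   (10.952, 335.5, -1.958),
    "C.ar":  (8.968, 352.4, -0.036),
    "N.3":   (6.984, 326.4, -0.938),
    "N.2":   (8.344, 328.7, -3.952),
    "N.1":   (8.622, 364.3, -4.857),
    "N.am":  (8.462, 357.8, -8.439),
    "N.ar":  (8.133, 338.3, -2.707),
    "N.pl3": (8.175, 331.8, -6.063),
    "O.3":   (6.851, 368.5, -5.429),
    "O.2":   (7.381, 344.3, -4.968),
    "S.3":   (16.856, 340.6, -0.905),
    "S.2":   (17.619, 348.3, 2.254),
    "S.O":   (13.547, 345.2, -2.159),
    "S.O2":  (13.563, 338.2, -0.952),
    "P":     (12.381, 330.3, -1.841),
    "F":     (6.190, 327.0, -2.143),
    "Cl":    (16.325, 327.3, -0.397),
    "Br":    (22.064, 330.4, 0.714),
    "H.C":   (3.143, 367.3, 0.905),
    "H.N":   (2.571, 364.8, -4.381),
    "H.O":   (2.763, 362.1, -7.429),
}

# label: (V, O_max, S, P) — full 37-type model with self-solvation
_EXTENDED37 = {
    "C.3_4":   (6.342, 316.5, 0.310, -0.905),
    "C.3_3":   (7.977, 321.4, 0.302, -1.432),
    "C.3_2":   (9.365, 334.2, 0.270, -2.055),
    "C.3_1":   (11.341, 343.0, 1.937, -3.095),
    "C.2_3":   (8.571, 322.3, -0.429, -1.397),
    "C.2_2":   (9.365, 338.2, 1.914, -2.476),
    "C.2_1":   (10.952, 352.5, -1.381, -3.846),
    "C.1_2":   (8.968, 325.3, -0.730, -3.201),
    "C.1_1":   (17.698, 342.8, 1.857, -3.286),
    "C.ar_3":  (7.342, 346.9, 1.324, -3.095),
    "C.ar_2":  (9.762, 354.2, 0.032, -3.787),
    "N.3_3":   (6.587, 314.5, -9.680, 20.746),
    "N.3_2":   (7.853, 327.3, -15.984, 19.305),
    "N.3_1":   (10.952, 341.5, -16.776, 10.095),
    "N.2":     (8.275, 328.7, -8.079, 5.643),
    "N.1":     (10.952, 364.3, -8.540, 9.968),
    "N.am_3":  (6.164, 348.2, -10.619, 7.286),
    "N.am_2":  (8.653, 356.2, -12.571, 16.220),
    "N.am_1":  (11.349, 368.3, -20.952, 20.048),
    "N.ar":    (8.243, 338.3, -7.937, 8.397),
    "N.pl3_3": (6.984, 321.8, -1.587, 5.873),
    "N.pl3_2": (8.245, 330.6, -14.021, 9.143),
    "N.pl3_1": (10.556, 338.4, -14.571, 9.422),
    "O.3_2":   (6.532, 363.8, -7.831, 9.571),
    "O.3_1":   (5.397, 371.6, -15.089, 12.857),
    "O.2":     (7.833, 344.3, -5.032, 4.873),
    "S.3":     (16.896, 340.6, -1.905, -2.307),
    "S.2":     (17.143, 348.3, 1.190, 9.397),
    "S.O":     (13.810, 345.2, -5.857, 1.381),
    "S.O2":    (11.905, 338.2, 4.315, 3.984),
    "P":       (10.029, 330.2, 5.286, -17.857),
    "F":       (8.454, 326.0, 1.365, -2.303),
    "Cl":      (16.905, 326.3, 0.435, -2.937),
    "Br":      (22.460, 330.4, 0.185, -5.073),
    "H.C":     (2.714, 366.4, -0.476, -6.048),
    "H.N":     (1.786, 364.8, 4.730, -17.863),
    "H.O":     (5.571, 362.1, 6.524, -22.032),
}


@dataclass
class ParameterTable:
    scheme: str  # "basic23", "extended37" or "custom"
    entries: dict[str, AtomParameters]
    sigma: float = DEFAULT_SIGMA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.scheme == "basic23":
            if len(self.entries) != 23 or any(p.P is not None for p in self.entries.values()):
                raise ValueError("basic23 requires exactly 23 entries without P")
        elif self.scheme == "extended37":
            if len(self.entries) != 37 or any(p.P is None for p in self.entries.values()):
                raise ValueError("extended37 requires exactly 37 entries with P")
        elif self.scheme != "custom":
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def has_self_solvation(self) -> bool:
        return all(p.P is not None for p in self.entries.values())

    @property
    def n_parameters(self) -> int:
        return sum(3 + (p.P is not None) for p in self.entries.values())

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> AtomParameters:
        return self.entries[label]

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        entries = {}
        for label, p in self.entries.items():
            d = {"V": p.V, "O_max": p.O_max, "S": p.S}
            if p.P is not None:
                d["P"] = p.P
            entries[label] = d
        out = {"scheme": self.scheme, "sigma": self.sigma, "entries": entries}
        if self.metadata:
            out["metadata"] = self.metadata
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def checksum(self) -> str:
        """SHA-256 over the canonical JSON serialization (metadata excluded)."""
        payload = {"scheme": self.scheme, "sigma": self.sigma,
                   "entries": self.to_dict()["entries"]}
        canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()


def builtin_table(scheme: str = "extended37") -> ParameterTable:
    """The published parameter table for the requested scheme."""
    if scheme == "basic23":
        entries = {lbl: AtomParameters(V=v, O_max=o, S=s)
                   for lbl, (v, o, s) in _BASIC23.items()}
    elif scheme == "extended37":
        entries = {lbl: AtomParameters(V=v, O_max=o, S=s, P=p)
                   for lbl, (v, o, s, p) in _EXTENDED37.items()}
    else:
        raise ValueError(f"no builtin table for scheme {scheme!r}")
    return ParameterTable(scheme=scheme, entries=entries)


_ALLOWED_TOP = {"scheme", "sigma", "entries", "metadata"}
_ALLOWED_ENTRY = {"V", "O_max", "S", "P"}


def load_custom(source: Union[str, TextIO, Mapping]) -> ParameterTable:
    """Load a (possibly refit) parameter table from JSON text, stream or mapping."""
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        text = source if isinstance(source, str) else source.read()
        data = json.loads(text)
    unknown = set(data) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown top-level fields: {sorted(unknown)}")
    for key in ("scheme", "entries"):
        if key not in data:
            raise ValueError(f"missing required field {key!r}")
    entries = {}
    for label, rec in data["entries"].items():
        bad = set(rec) - _ALLOWED_ENTRY
        if bad:
            raise ValueError(f"entry {label!r}: unknown fields {sorted(bad)}")
        for key in ("V", "O_max", "S"):
            if key not in rec:
                raise ValueError(f"entry {label!r}: missing field {key!r}")
        entries[label] = AtomParameters(V=float(rec["V"]), O_max=float(rec["O_max"]),
                                        S=float(rec["S"]),
                                        P=float(rec["P"]) if "P" in rec else None)
    return ParameterTable(scheme=data["scheme"], entries=entries,
                          sigma=float(data.get("sigma", DEFAULT_SIGMA)),
                          metadata=data.get("metadata", {}))
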