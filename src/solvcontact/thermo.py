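"""Solvation free energies from (solubility, vapor pressure) pairs.

For a pure solid solute at equilibrium, the transfer free energy from an
ideal gas at 1 M to a 1 M aqueous solution is

    dG_sol = -2.303 R T log10( M * p0 / p )

where M is the equilibrium solubility (mol/L), p the vapor pressure and
p0 = (1 mol/L) R T ~ 24.45 atm the pressure of an ideal gas at 1 M and
298.15 K.  High solubility and low volatility therefore give a negative
(favorable) dG_sol; one decade of M*p0/p changes dG by 2.303 R T = 1.364
kcal/mol at 298.15 K.

A strict-literal mode evaluating -2.303 R T log10(M * p / p0) is kept for
auditability; it inverts the pressure ratio and is *not* thermodynamically
consistent with the definition of p0 (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_KCAL = 1.9872e-3      # gas constant, kcal/(mol*K)
R_L_ATM = 0.082057      # gas constant, L*atm/(mol*K)

_ATM_PER_UNIT = {
    "atm": 1.0,
    "mmHg": 1.0 / 760.0,
    "Pa": 1.0 / 101325.0,
    "kPa": 1000.0 / 101325.0,
}


@dataclass
class ThermoConstants:
    R: float = R_KCAL     # kcal/(mol*K)
    T: float = 298.15     # K

    @property
    def p0(self) -> float:
        """Pressure (atm) of an ideal gas at 1 mol/L and temperature T."""
        return R_L_ATM * self.T


@dataclass
class SolubilityVaporRecord:
    M: float          # equilibrium solubility, mol/L
    p: float          # vapor pressure, in `unit`
    unit: str = "atm"

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("solubility must be positive")
        if self.p <= 0:
            raise ValueError("vapor pressure must be positive")


def convert_pressure(value: float, unit: str) -> float:
    """Convert a pressure to atm (760 mmHg = 101325 Pa = 1 atm)."""
    if value <= 0:
        raise ValueError("pressure must be positive")
    try:
        return value * _ATM_PER_UNIT[unit]
    except KeyError:
        raise ValueError(
            f"unknown pressure unit {unit!r}; expected one of {sorted(_ATM_PER_UNIT)}"
        ) from None


def dg_from_solubility_vapor(rec: SolubilityVaporRecord,
                             consts: ThermoConstants | None = None,
                             strict_literal: bool = False) -> float:
    """Solvation free energy (kcal/mol) from a solubility/vapor-pressure pair.

    ``strict_literal`` switches to the inverted ratio M*p/p0 (audit mode only).
    """
    consts = consts or ThermoConstants()
    p_atm = convert_pressure(rec.p, rec.unit)
    ratio = rec.M * p_atm / consts.p0 if strict_literal else rec.M * consts.p0 / p_atm
    return -2.303 * consts.R * consts.T * math.log10(ratio)
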