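"""Elemental formulas, molar masses and molar volumes.

Atomic masses are the IUPAC standard atomic weights (abridged to five
significant figures, conventional values for elements with an interval),
embedded as a pinned constant table.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

__all__ = [
    "ATOMIC_MASS",
    "parse_formula",
    "molar_mass",
    "molar_volume",
    "UnknownElementError",
]

#: IUPAC standard atomic weights (g mol-1), conventional values.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.90,
}


class UnknownElementError(ValueError):
    """Raised when a formula contains an element outside the pinned table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-order elemental formula such as ``"C29H60"``.

    Accepts an already-parsed mapping unchanged (after validation).
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
        for sym, n in counts.items():
            if sym not in ATOMIC_MASS:
                raise UnknownElementError(sym)
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"element count for {sym} must be a positive integer, got {n!r}")
        return counts

    formula = formula.strip()
    if not formula:
        raise ValueError("empty elemental formula")
    counts: Counter[str] = Counter()
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        sym, digits = m.groups()
        if sym not in ATOMIC_MASS:
            raise UnknownElementError(sym)
        counts[sym] += int(digits) if digits else 1
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return dict(counts)


def molar_mass(formula: str | Mapping[str, int]) -> float:
    """Molar mass in g mol-1 from the pinned standard atomic weights."""
    counts = parse_formula(formula)
    return sum(ATOMIC_MASS[sym] * n for sym, n in counts.items())


def molar_volume(mass: float, density: float) -> float:
    """Molar volume v = M / rho in cm3 mol-1 (mass g mol-1, density g cm-3)."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    if mass <= 0:
        raise ValueError(f"molar mass must be positive, got {mass}")
    return mass / density
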