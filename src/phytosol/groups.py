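"""The van Krevelen-Hoftyzer group-contribution table.

Each structural group carries a dispersion molar attraction constant F_d and a
polar one F_p (both in (MJ m-3)^(1/2) mol-1, numerically (J cm-3)^(1/2) mol-1
when divided by a molar volume in cm3 mol-1) and a hydrogen-bonding energy E_h
(J mol-1).  Molecular symmetry reduces the effective polar component: one plane
of symmetry halves it, two quarter it, higher symmetry cancels it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GroupEntry",
    "GroupContributionTable",
    "VAN_KREVELEN_TABLE",
    "SYMMETRY_FACTORS",
    "UnknownGroupError",
]


class UnknownGroupError(KeyError):
    """Raised when a group label is not in the contribution table."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unknown structural group label: {label!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return self.args[0]


@dataclass(frozen=True)
class GroupEntry:
    """Contribution constants of one structural group."""

    f_d: float  # dispersion molar attraction, (MJ/m3)^1/2 mol-1
    f_p: float  # polar molar attraction, (MJ/m3)^1/2 mol-1
    e_h: float  # hydrogen-bond energy, J mol-1
    #: elemental content of the group, used for the formula consistency check
    elements: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.f_p < 0:
            raise ValueError("F_p must be non-negative")
        if self.e_h < 0:
            raise ValueError("E_h must be non-negative")


def _e(**kw: int) -> dict[str, int]:
    return kw


#: Canonical group constants.  F_d < 0 occurs only for the quaternary >C<.
_CANONICAL: dict[str, GroupEntry] = {
    "-CH3": GroupEntry(420, 0, 0, _e(C=1, H=3)),
    "-CH2-": GroupEntry(270, 0, 0, _e(C=1, H=2)),
    ">CH-": GroupEntry(80, 0, 0, _e(C=1, H=1)),
    "=C<": GroupEntry(70, 0, 0, _e(C=1)),
    "=CH-": GroupEntry(200, 0, 0, _e(C=1, H=1)),
    ">C<": GroupEntry(-70, 0, 0, _e(C=1)),
    "C6H5": GroupEntry(1430, 110, 0, _e(C=6, H=5)),  # phenyl
    "C6H4": GroupEntry(1270, 110, 0, _e(C=6, H=4)),  # phenylene
    "-F": GroupEntry(220, 0, 0, _e(F=1)),
    "-Cl": GroupEntry(450, 550, 400, _e(Cl=1)),
    "-OH": GroupEntry(210, 500, 20000, _e(O=1, H=1)),
    "-O-": GroupEntry(100, 400, 3000, _e(O=1)),
    "-CO-": GroupEntry(290, 770, 2000, _e(C=1, O=1)),
    "-COO-": GroupEntry(390, 490, 7000, _e(C=1, O=2)),
    "-COOH": GroupEntry(530, 420, 10000, _e(C=1, O=2, H=1)),
    "-CHO": GroupEntry(470, 800, 4500, _e(C=1, O=1, H=1)),  # aldehyde (-COH)
    "-CN": GroupEntry(430, 1100, 2500, _e(C=1, N=1)),
    ">N-": GroupEntry(20, 800, 5000, _e(N=1)),
    "-NH2": GroupEntry(280, 0, 8400, _e(N=1, H=2)),
    "-NH-": GroupEntry(160, 210, 3100, _e(N=1, H=1)),
}

#: Accepted spelling variants -> canonical label.
_ALIASES: dict[str, str] = {
    "CH3": "-CH3",
    "CH2": "-CH2-",
    "CH": ">CH-",
    ">CH": ">CH-",
    "=C": "=C<",
    "=CH": "=CH-",
    "C": ">C<",
    ">C": ">C<",
    "phenyl": "C6H5",
    "phenylene": "C6H4",
    "F": "-F",
    "Cl": "-Cl",
    "OH": "-OH",
    "O": "-O-",
    "CO": "-CO-",
    "COO": "-COO-",
    "COOH": "-COOH",
    "CHO": "-CHO",
    "COH": "-CHO",
    "-COH": "-CHO",
    "CN": "-CN",
    "N": ">N-",
    ">N": ">N-",
    "NH2": "-NH2",
    "NH": "-NH-",
}

#: Polar reduction factor by number of symmetry planes.
SYMMETRY_FACTORS: dict[int | str, float] = {0: 1.0, 1: 0.50, 2: 0.25, "many": 0.0}


@dataclass(frozen=True)
class GroupContributionTable:
    """A set of group constants plus the symmetry-factor rules."""

    entries: Mapping[str, GroupEntry]
    symmetry_factors: Mapping[int | str, float] = field(
        default_factory=lambda: dict(SYMMETRY_FACTORS)
    )
    canonical: bool = True  # False once user extensions are added

    def resolve(self, label: str) -> str:
        """Return the canonical label for ``label`` (aliases accepted)."""
        if label in self.entries:
            return label
        alias = _ALIASES.get(label) or _ALIASES.get(label.strip())
        if alias is not None and alias in self.entries:
            return alias
        raise UnknownGroupError(label)

    def __getitem__(self, label: str) -> GroupEntry:
        return self.entries[self.resolve(label)]

    def __contains__(self, label: str) -> bool:
        try:
            self.resolve(label)
        except UnknownGroupError:
            return False
        return True

    def labels(self) -> Iterable[str]:
        return self.entries.keys()

    def symmetry_factor(self, planes: int | str) -> float:
        """Polar reduction factor for 0, 1, 2 or 'many' symmetry planes."""
        key: int | str = planes
        if isinstance(planes, str) and planes != "many":
            key = int(planes)
        if isinstance(key, int) and key > 2:
            key = "many"
        try:
            return self.symmetry_factors[key]
        except KeyError:
            raise ValueError(f"symmetry plane count must be 0, 1, 2 or 'many'; got {planes!r}")

    def extended(self, extra: Mapping[str, GroupEntry]) -> "GroupContributionTable":
        """A new table with user-supplied groups, flagged non-canonical."""
        merged = dict(self.entries)
        for label, entry in extra.items():
            if label != ">C<" and entry.f_d < 0:
                raise ValueError(
                    f"negative F_d is only tabulated for '>C<'; refusing {label!r}"
                )
            merged[label] = entry
        return GroupContributionTable(merged, dict(self.symmetry_factors), canonical=False)


#: The canonical table shipped with the package.
VAN_KREVELEN_TABLE = GroupContributionTable(dict(_CANONICAL))
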