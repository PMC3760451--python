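"""Group-contribution Hansen solubility parameters.

The three components for a molecule with molar volume v (cm3 mol-1) and a
structural-group inventory {g: n_g} are

    delta_d = sum_g n_g F_d(g) / v
    delta_p = f_sym * sqrt( sum_g (n_g F_p(g))^2 ) / v
    delta_h = sqrt( sum_g n_g E_h(g) / v )
    delta   = sqrt(delta_d^2 + delta_p^2 + delta_h^2)

all in MJ^1/2 m^-3/2 (numerically equal to MPa^1/2).  Identical polar groups
add coherently (n_g multiplies F_p inside the square); the alternative
per-instance quadrature sum sqrt(sum n_g F_p^2) is available through
``polar_combination="per_group_instance"``.  The symmetry reduction f_sym
(0.50 for one plane, 0.25 for two, 0 for more) multiplies delta_p itself by
default; ``symmetry_mode="on_squared_sum"`` applies it inside the square root
instead (an effective sqrt(f) on delta_p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .elements import molar_mass, molar_volume, parse_formula
from .groups import GroupContributionTable, UnknownGroupError, VAN_KREVELEN_TABLE

__all__ = [
    "HansenParameters",
    "MoleculeSpec",
    "HansenResult",
    "dispersion_component",
    "polar_component",
    "hbond_component",
    "total_parameter",
    "compute_hansen",
]

PolarCombination = Literal["per_group_type", "per_group_instance"]
SymmetryMode = Literal["on_delta_p", "on_squared_sum"]

ROLES = {"wax", "agrochemical", "cutin_monomer", "polysaccharide_monomer", "other"}


@dataclass(frozen=True)
class HansenParameters:
    """Solubility parameter components and total, MJ^1/2 m^-3/2."""

    delta_d: float
    delta_p: float
    delta_h: float
    delta_total: float

    def __post_init__(self):
        expected = math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)
        if abs(self.delta_total - expected) > 1e-9 * max(1.0, expected):
            raise ValueError(
                f"delta_total {self.delta_total} inconsistent with components "
                f"(expected {expected})"
            )

    @classmethod
    def from_components(cls, delta_d: float, delta_p: float, delta_h: float) -> "HansenParameters":
        return cls(delta_d, delta_p, delta_h, total_parameter(delta_d, delta_p, delta_h))

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float, float]:
        return (
            round(self.delta_d, ndigits),
            round(self.delta_p, ndigits),
            round(self.delta_h, ndigits),
            round(self.delta_total, ndigits),
        )


@dataclass
class MoleculeSpec:
    """A molecule described by formula, molar volume and group inventory.

    At least one of ``density`` (g cm-3) or ``molar_volume`` (cm3 mol-1) is
    required; an explicit molar volume takes precedence.  ``symmetry_planes``
    is 0, 1, 2 or ``"many"``.
    """

    name: str
    formula: str | Mapping[str, int]
    groups: Mapping[str, int]
    density: float | None = None
    molar_volume: float | None = None
    symmetry_planes: int | str = 0
    role: str = "other"

    def __post_init__(self):
        if self.density is None and self.molar_volume is None:
            raise ValueError(f"{self.name}: one of density or molar_volume is required")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.molar_volume is not None and self.molar_volume <= 0:
            raise ValueError(f"{self.name}: molar volume must be positive")
        if not self.groups:
            raise ValueError(f"{self.name}: empty group inventory")
        for label, count in self.groups.items():
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"{self.name}: group count for {label!r} must be a positive "
                    f"integer, got {count!r}"
                )
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r} (allowed: {sorted(ROLES)})")
        parse_formula(self.formula)  # validates element symbols

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)

    def resolve_molar_volume(self) -> tuple[float, list[str]]:
        """Molar volume in cm3 mol-1 plus any consistency warnings.

        An explicit molar_volume wins; if a density is also given the two are
        cross-checked via the molar mass and a >1 % mismatch is flagged.
        """
        flags: list[str] = []
        if self.molar_volume is not None:
            if self.density is not None:
                v_rho = molar_volume(self.molar_mass, self.density)
                if abs(v_rho - self.molar_volume) > 0.01 * self.molar_volume:
                    flags.append(
                        f"molar_volume {self.molar_volume:.1f} and density-derived "
                        f"{v_rho:.1f} cm3/mol disagree by more than 1%"
                    )
            return self.molar_volume, flags
        return molar_volume(self.molar_mass, self.density), flags


@dataclass(frozen=True)
class HansenResult:
    """Computed parameters plus provenance of the inputs actually used."""

    name: str
    parameters: HansenParameters
    molar_volume: float
    symmetry_factor: float
    flags: tuple[str, ...] = field(default=())


def _normalise(groups: Mapping[str, int], table: GroupContributionTable) -> dict[str, int]:
    if not groups:
        raise ValueError("empty group inventory")
    out: dict[str, int] = {}
    for label, count in groups.items():
        canon = table.resolve(label)  # raises UnknownGroupError with the label named
        out[canon] = out.get(canon, 0) + count
    return out


def dispersion_component(
    groups: Mapping[str, int],
    v: float,
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
) -> float:
    """delta_d = sum(n F_d) / v.  Negative results are reported as computed."""
    if v <= 0:
        raise ValueError(f"molar volume must be positive, got {v}")
    inv = _normalise(groups, table)
    return sum(n * table[g].f_d for g, n in inv.items()) / v


def polar_component(
    groups: Mapping[str, int],
    v: float,
    symmetry_planes: int | str = 0,
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
    polar_combination: PolarCombination = "per_group_type",
    symmetry_mode: SymmetryMode = "on_delta_p",
) -> float:
    """Polar component with symmetry reduction (see module docstring)."""
    if v <= 0:
        raise ValueError(f"molar volume must be positive, got {v}")
    inv = _normalise(groups, table)
    if polar_combination == "per_group_type":
        ssq = sum((n * table[g].f_p) ** 2 for g, n in inv.items())
    elif polar_combination == "per_group_instance":
        ssq = sum(n * table[g].f_p ** 2 for g, n in inv.items())
    else:
        raise ValueError(f"unknown polar_combination {polar_combination!r}")
    factor = table.symmetry_factor(symmetry_planes)
    if symmetry_mode == "on_delta_p":
        return factor * math.sqrt(ssq) / v
    if symmetry_mode == "on_squared_sum":
        return math.sqrt(factor * ssq) / v
    raise ValueError(f"unknown symmetry_mode {symmetry_mode!r}")


def hbond_component(
    groups: Mapping[str, int],
    v: float,
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
) -> float:
    """delta_h = sqrt(sum(n E_h) / v)."""
    if v <= 0:
        raise ValueError(f"molar volume must be positive, got {v}")
    inv = _normalise(groups, table)
    total_eh = sum(n * table[g].e_h for g, n in inv.items())
    return math.sqrt(total_eh / v)


def total_parameter(delta_d: float, delta_p: float, delta_h: float) -> float:
    """delta = sqrt(delta_d^2 + delta_p^2 + delta_h^2)."""
    return math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)


def _element_consistency_flags(spec: MoleculeSpec, table: GroupContributionTable) -> list[str]:
    """Warn (not error) on C/N/O mismatches between formula and groups.

    Full validation would need connectivity; heavy-atom counts catch most
    transcription slips.  Hydrogen is skipped because esterified fixtures
    legitimately differ.
    """
    flags = []
    formula = parse_formula(spec.formula)
    inv = _normalise(spec.groups, table)
    for elem in ("C", "N", "O"):
        from_groups = sum(n * table[g].elements.get(elem, 0) for g, n in inv.items())
        if from_groups != formula.get(elem, 0):
            flags.append(
                f"{elem} count mismatch: formula has {formula.get(elem, 0)}, "
                f"group inventory has {from_groups}"
            )
    return flags


def compute_hansen(
    spec: MoleculeSpec,
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
    polar_combination: PolarCombination = "per_group_type",
    symmetry_mode: SymmetryMode = "on_delta_p",
    check_formula: bool = True,
) -> HansenResult:
    """All four solubility-parameter values for one molecule, with provenance."""
    v, flags = spec.resolve_molar_volume()
    dd = dispersion_component(spec.groups, v, table)
    dp = polar_component(
        spec.groups, v, spec.symmetry_planes, table, polar_combination, symmetry_mode
    )
    dh = hbond_component(spec.groups, v, table)
    if dd < 0:
        flags.append("negative_delta_d")
        warnings.warn(
            f"{spec.name}: computed delta_d is negative ({dd:.2f}); reported as-is",
            stacklevel=2,
        )
    if check_formula:
        flags.extend(_element_consistency_flags(spec, table))
    params = HansenParameters.from_components(dd, dp, dh)
    return HansenResult(
        name=spec.name,
        parameters=params,
        molar_volume=v,
        symmetry_factor=table.symmetry_factor(spec.symmetry_planes),
        flags=tuple(flags),
    )
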