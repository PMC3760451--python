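"""Built-in compound, cutin-monomer and surface fixtures.

Ships every compound in the source inventory tables (13 epicuticular waxes,
4 cutin monomers, 2 cell-wall polysaccharide monomers, 11 agrochemicals =
30 entries) together with the printed solubility-parameter values, the
three model surfaces with their measured contact angles, the cutin
esterification variants, and the layered solubility-gradient report.

A fixture is *verified* when the group-contribution engine reproduces every
printed field to within one unit of the printed 0.1 precision
(|round(computed, 1) - printed| <= 0.1); fixtures whose printed rows cannot
be reproduced are stored as printed with ``verification == "non_verified"``
and an explanatory note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .groups import GroupContributionTable, VAN_KREVELEN_TABLE
from .hansen import HansenResult, MoleculeSpec, compute_hansen
from .wettability import ContactAngleSet

__all__ = [
    "CompoundFixture",
    "CutinMonomer",
    "EsterVariant",
    "SurfaceFixture",
    "GradientLayer",
    "VERIFICATION_TOLERANCE",
    "builtin_compounds",
    "builtin_cutin_monomers",
    "builtin_surfaces",
    "get_compound",
    "get_surface",
    "esterification_variants",
    "gradient_profile",
    "gradient_report",
]

#: A printed field verifies when |round(computed, 1) - printed| <= this.
VERIFICATION_TOLERANCE = 0.1

_PRINTED_FIELDS = ("delta_d", "delta_p", "delta_h", "delta_total")


@dataclass(frozen=True)
class CompoundFixture:
    """One registry molecule with its printed values and verification state."""

    spec: MoleculeSpec
    printed: Mapping[str, float] | None
    verified_fields: tuple[str, ...]
    notes: str = ""
    supplementary: bool = False

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def verification(self) -> str:
        if self.printed and set(self.verified_fields) == set(self.printed):
            return "verified"
        return "non_verified"

    def recompute(self, table: GroupContributionTable = VAN_KREVELEN_TABLE, **kw) -> HansenResult:
        return compute_hansen(self.spec, table, **kw)

    def check_printed(
        self, table: GroupContributionTable = VAN_KREVELEN_TABLE, **kw
    ) -> dict[str, bool]:
        """Per-field agreement of recomputed vs printed values."""
        if not self.printed:
            return {}
        params = self.recompute(table, **kw).parameters
        return {
            f: abs(round(getattr(params, f), 1) - self.printed[f])
            <= VERIFICATION_TOLERANCE + 1e-9
            for f in _PRINTED_FIELDS
            if f in self.printed
        }


@dataclass(frozen=True)
class EsterVariant:
    """A cutin monomer with k ester bonds formed (2 <= k <= sites)."""

    k: int
    label: str
    groups: Mapping[str, int]
    printed: Mapping[str, float] | None
    verified_fields: tuple[str, ...]
    notes: str = ""


@dataclass(frozen=True)
class CutinMonomer:
    """A hydroxy fatty acid and its esterification variants.

    ``sites`` counts the esterifiable positions (the carboxyl plus each free
    hydroxyl).  A variant with k bonds keeps the acid as -COO-, one bridging
    -O- per hydroxyl-side bond, and ``sites - k`` free -OH; its inventory
    therefore conserves the base acid's C and O and removes k hydrogens.
    """

    name: str
    formula: str
    molar_volume: float
    sites: int
    variants: tuple[EsterVariant, ...]

    def __post_init__(self):
        if self.sites < 2:
            raise ValueError(f"{self.name}: a cutin monomer needs >= 2 esterifiable sites")
        ks = [v.k for v in self.variants]
        if ks != sorted(ks) or any(not 2 <= k <= self.sites for k in ks):
            raise ValueError(f"{self.name}: variant k values must be sorted within [2, sites]")


@dataclass(frozen=True)
class SurfaceFixture:
    """A model plant surface: measured angles, printed energetics, wax basis."""

    name: str
    description: str
    angle_set: ContactAngleSet
    dominant_wax: str
    printed: Mapping[str, object]
    notes: str = ""

    @property
    def printed_delta_theta(self) -> float:
        return float(self.printed["delta_theta"])

    @property
    def printed_gamma_total(self) -> float:
        return float(self.printed["gamma_total"])


@dataclass(frozen=True)
class GradientLayer:
    """One layer of the cuticle/cell-wall solubility gradient."""

    layer: str  # epicuticular_wax | cuticle_proper | cuticular_layer | cell_wall
    delta_min: float
    delta_max: float
    constituents: tuple[str, ...]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.delta_min + self.delta_max)


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("phytosol.data").joinpath("registry.json").open() as fh:
        return json.load(fh)


def _fixture(rec: dict, supplementary: bool = False) -> CompoundFixture:
    spec = MoleculeSpec(
        name=rec["name"],
        formula=rec["formula"],
        groups=rec["groups"],
        molar_volume=rec["molar_volume"],
        density=rec.get("density"),
        symmetry_planes=rec.get("symmetry_planes", 0),
        role=rec["role"],
    )
    return CompoundFixture(
        spec=spec,
        printed=rec.get("printed"),
        verified_fields=tuple(rec.get("verified_fields", ())),
        notes=rec.get("notes", ""),
        supplementary=supplementary,
    )


@lru_cache(maxsize=None)
def _compounds(include_supplementary: bool) -> tuple[CompoundFixture, ...]:
    raw = _raw()
    out = [_fixture(r) for r in raw["compounds"]]
    if include_supplementary:
        out += [_fixture(r, supplementary=True) for r in raw["supplementary_compounds"]]
    return tuple(out)


def builtin_compounds(
    role: str | None = None, include_supplementary: bool = False
) -> list[CompoundFixture]:
    """The packaged registry, optionally filtered by role.

    Without a filter the 30 canonical inventory-table entries are returned;
    ``include_supplementary`` adds the cross-referenced extras (hexacosanal).
    """
    fixtures = _compounds(include_supplementary)
    if role is None:
        return list(fixtures)
    from .hansen import ROLES

    if role not in ROLES:
        raise ValueError(f"unknown role filter {role!r} (allowed: {sorted(ROLES)})")
    return [f for f in fixtures if f.spec.role == role]


def get_compound(name: str) -> CompoundFixture:
    for f in _compounds(True):
        if f.name.lower() == name.lower():
            return f
    raise KeyError(f"no built-in compound named {name!r}")


@lru_cache(maxsize=1)
def builtin_cutin_monomers() -> tuple[CutinMonomer, ...]:
    out = []
    for rec in _raw()["cutin_monomers"]:
        variants = tuple(
            EsterVariant(
                k=v["k"],
                label=v["label"],
                groups=v["groups"],
                printed=v.get("printed"),
                verified_fields=tuple(v.get("verified_fields", ())),
                notes=v.get("notes", ""),
            )
            for v in rec["variants"]
        )
        out.append(
            CutinMonomer(
                name=rec["name"],
                formula=rec["formula"],
                molar_volume=rec["molar_volume"],
                sites=rec["sites"],
                variants=variants,
            )
        )
    return tuple(out)


@lru_cache(maxsize=1)
def builtin_surfaces() -> tuple[SurfaceFixture, ...]:
    out = []
    for rec in _raw()["surfaces"]:
        angles = ContactAngleSet.from_mapping(
            rec["name"], {liq: tuple(v) for liq, v in rec["angles"].items()}
        )
        out.append(
            SurfaceFixture(
                name=rec["name"],
                description=rec.get("description", ""),
                angle_set=angles,
                dominant_wax=rec["dominant_wax"],
                printed=rec["printed"],
                notes=rec.get("notes", ""),
            )
        )
    return tuple(out)


def get_surface(name: str) -> SurfaceFixture:
    for s in builtin_surfaces():
        if s.name.lower() == name.lower():
            return s
    raise KeyError(f"no built-in surface named {name!r}")


def esterification_variants(
    monomer: CutinMonomer,
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
    **hansen_kw,
) -> list[tuple[int, HansenResult]]:
    """(k, HansenResult) per esterification variant, ordered by k.

    The total parameter strictly decreases with k: every additional ester
    bond replaces a free hydroxyl (E_h = 20 kJ/mol) by a bridging ether
    (3 kJ/mol), lowering delta_h.  The free-acid molar volume is used for
    every variant (no esterified volumes are tabulated) - a known
    approximation.
    """
    if monomer.sites < 2:
        raise ValueError(f"{monomer.name}: fewer than two esterifiable sites")
    out = []
    for variant in monomer.variants:
        spec = MoleculeSpec(
            name=f"{monomer.name} (k={variant.k}: {variant.label})",
            formula=monomer.formula,
            groups=variant.groups,
            molar_volume=monomer.molar_volume,
            role="cutin_monomer",
        )
        out.append((variant.k, compute_hansen(spec, table, check_formula=False, **hansen_kw)))
    return out


def _delta_for(fix: CompoundFixture, prefer_printed: bool) -> float:
    if prefer_printed and fix.printed and "delta_total" in fix.printed:
        return float(fix.printed["delta_total"])
    return fix.recompute().parameters.delta_total


def gradient_profile(
    compounds: Sequence[CompoundFixture] | None = None,
    monomers: Sequence[CutinMonomer] | None = None,
    prefer_printed: bool = True,
) -> list[GradientLayer]:
    """Ordered solubility-parameter layers from the wax surface inward.

    Epicuticular wax layer (EWL) <- wax fixtures; cuticle proper (CP) <-
    waxes + cutin esterification variants; cuticular layer (CL) <- cutin
    variants + polysaccharide monomers; cell wall <- polysaccharides.
    Printed totals are used where available (``prefer_printed``), computed
    totals otherwise.  A registry without cutin or polysaccharide values
    yields a degenerate single-layer profile with a warning.
    """
    compounds = list(compounds) if compounds is not None else builtin_compounds()
    monomers = list(monomers) if monomers is not None else list(builtin_cutin_monomers())
    if not compounds:
        raise ValueError("empty registry: no compounds to build a gradient from")

    wax = [
        (f.name, _delta_for(f, prefer_printed))
        for f in compounds
        if f.spec.role == "wax" and (f.printed or not prefer_printed)
    ]
    if not wax:  # fall back to computed values
        wax = [(f.name, _delta_for(f, False)) for f in compounds if f.spec.role == "wax"]
    cutin = []
    for m in monomers:
        for variant, (_, res) in zip(m.variants, esterification_variants(m)):
            if prefer_printed and variant.printed and "delta_total" in variant.printed:
                cutin.append((variant.label, float(variant.printed["delta_total"])))
            else:
                cutin.append((variant.label, res.parameters.delta_total))
    poly = [
        (f.name, _delta_for(f, prefer_printed))
        for f in compounds
        if f.spec.role == "polysaccharide_monomer"
    ]

    def layer(tag: str, items: list[tuple[str, float]]) -> GradientLayer:
        vals = [v for _, v in items]
        return GradientLayer(tag, min(vals), max(vals), tuple(n for n, _ in items))

    if not wax:
        raise ValueError("gradient requires at least one wax fixture")
    layers = [layer("epicuticular_wax", wax)]
    if cutin:
        layers.append(layer("cuticle_proper", wax + cutin))
        if poly:
            layers.append(layer("cuticular_layer", cutin + poly))
    if poly:
        layers.append(layer("cell_wall", poly))
    if len(layers) == 1:
        warnings.warn(
            "degenerate gradient: only wax constituents available, single-layer profile",
            stacklevel=2,
        )
    return layers


def gradient_report(layers: Iterable[GradientLayer] | None = None) -> str:
    """Plain-text rendering of the layered gradient, outermost first."""
    layers = list(layers) if layers is not None else gradient_profile()
    titles = {
        "epicuticular_wax": "Epicuticular wax layer (EWL)",
        "cuticle_proper": "Cuticle proper (CP)",
        "cuticular_layer": "Cuticular layer (CL)",
        "cell_wall": "Cell wall",
    }
    lines = ["Solubility-parameter gradient (MJ^1/2 m^-3/2), outer -> inner:", ""]
    for lay in layers:
        lines.append(
            f"  {titles.get(lay.layer, lay.layer):34s} delta in "
            f"[{lay.delta_min:5.1f}, {lay.delta_max:5.1f}]  "
            f"({len(lay.constituents)} constituents)"
        )
    lines += [
        "",
        "The parameter increases monotonically with depth: apolar waxes at the",
        "air interface, esterified cutin beneath, hydrogen-bonding",
        "polysaccharides against the cell wall.",
    ]
    return "\n".join(lines)
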