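"""Chemical-surface affinity from solubility-parameter differences.

The affinity of an agrochemical (delta_m) for a surface is the absolute
solubility-parameter difference

    delta_diff = sqrt((delta_m - delta_s)^2) = |delta_m - delta_s|

against either the dominant epicuticular-wax value (delta_wax basis) or the
contact-angle-derived surface value (delta_theta basis).  Smaller differences
mean higher affinity.  The Greenhalgh miscibility bands classify a pair as
miscible below 7 MJ^1/2 m^-3/2 and immiscible above 10; the closed interval
[7, 10] is intermediate (the thresholds are worded strictly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MiscibilityThresholds",
    "SurfaceBasisSet",
    "AffinityRecord",
    "delta_difference",
    "classify_miscibility",
    "affinity_matrix",
    "records_to_dataframe",
    "plot_affinity",
]


@dataclass(frozen=True)
class MiscibilityThresholds:
    """Greenhalgh band limits, MJ^1/2 m^-3/2.

    ``boundary`` controls where the exact threshold values fall; the default
    assigns them to the intermediate band.
    """

    miscible_below: float = 7.0
    immiscible_above: float = 10.0
    boundary: str = "intermediate"  # or "outer": 7 -> miscible, 10 -> immiscible

    def __post_init__(self):
        if not 0 < self.miscible_below < self.immiscible_above:
            raise ValueError(
                "thresholds must satisfy 0 < miscible_below < immiscible_above"
            )
        if self.boundary not in ("intermediate", "outer"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")


DEFAULT_THRESHOLDS = MiscibilityThresholds()


@dataclass(frozen=True)
class SurfaceBasisSet:
    """Per-surface solubility-parameter values available for screening."""

    name: str
    delta_wax: float | None = None  # dominant-wax basis
    delta_theta: float | None = None  # contact-angle basis

    def __post_init__(self):
        if self.delta_wax is None and self.delta_theta is None:
            raise ValueError(f"{self.name}: at least one basis value is required")


@dataclass(frozen=True)
class AffinityRecord:
    """One (chemical, surface, basis) screening result."""

    chemical: str
    delta_chemical: float
    surface: str
    basis: str  # "wax" | "contact_angle"
    delta_surface: float
    delta_diff: float
    miscibility: str
    uncertainty: float | None = None


def delta_difference(delta_a: float, delta_b: float) -> float:
    """|delta_a - delta_b|, symmetric, MJ^1/2 m^-3/2."""
    for d in (delta_a, delta_b):
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"solubility parameters must be finite and >= 0, got {d}")
    return abs(delta_a - delta_b)


def classify_miscibility(
    delta_diff: float, thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Greenhalgh class of a solubility-parameter difference."""
    if delta_diff < 0:
        raise ValueError(f"delta_diff must be non-negative, got {delta_diff}")
    lo, hi = thresholds.miscible_below, thresholds.immiscible_above
    if thresholds.boundary == "outer":
        if delta_diff <= lo:
            return "miscible"
        if delta_diff >= hi:
            return "immiscible"
        return "intermediate"
    if delta_diff < lo:
        return "miscible"
    if delta_diff > hi:
        return "immiscible"
    return "intermediate"


def affinity_matrix(
    chemicals: Sequence[tuple[str, float]],
    surfaces: Sequence[SurfaceBasisSet],
    thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS,
    uncertainties: dict[tuple[str, str], float] | None = None,
) -> list[AffinityRecord]:
    """One record per (chemical, surface, available basis) triple.

    ``chemicals`` are (name, delta_m) pairs; ``uncertainties`` optionally maps
    (surface, basis) to a +/- value propagated onto the records.
    """
    if not chemicals or not surfaces:
        raise ValueError("chemicals and surfaces must both be non-empty")
    records = []
    for name, dm in chemicals:
        if not math.isfinite(dm) or dm < 0:
            raise ValueError(f"{name}: delta_m must be finite and >= 0, got {dm}")
        for surf in surfaces:
            for basis, ds in (("wax", surf.delta_wax), ("contact_angle", surf.delta_theta)):
                if ds is None:
                    continue
                diff = delta_difference(dm, ds)
                unc = (uncertainties or {}).get((surf.name, basis))
                records.append(
                    AffinityRecord(
                        chemical=name,
                        delta_chemical=dm,
                        surface=surf.name,
                        basis=basis,
                        delta_surface=ds,
                        delta_diff=diff,
                        miscibility=classify_miscibility(diff, thresholds),
                        uncertainty=unc,
                    )
                )
    return records


def records_to_dataframe(records: Iterable[AffinityRecord]):
    """Affinity records as a pandas DataFrame sorted by increasing delta_diff."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "chemical": r.chemical,
                "surface": r.surface,
                "basis": r.basis,
                "delta_chemical": r.delta_chemical,
                "delta_surface": r.delta_surface,
                "delta_diff": r.delta_diff,
                "miscibility": r.miscibility,
                "uncertainty": r.uncertainty,
            }
            for r in records
        ]
    )
    return df.sort_values("delta_diff", kind="stable").reset_index(drop=True)


def plot_affinity(records: Sequence[AffinityRecord], path: str) -> None:
    """Grouped bar chart of delta_diff per chemical, one panel per surface.

    Wax-basis bars light grey, contact-angle-basis bars dark grey, with the
    miscibility band limits drawn as horizontal lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    surfaces = sorted({r.surface for r in records})
    chems = list(dict.fromkeys(r.chemical for r in records))
    fig, axes = plt.subplots(
        len(surfaces), 1, figsize=(max(6, 0.7 * len(chems)), 3.0 * len(surfaces)),
        squeeze=False,
    )
    for ax, surf in zip(axes[:, 0], surfaces):
        xs = np.arange(len(chems))
        for off, basis, colour in ((-0.2, "wax", "0.75"), (0.2, "contact_angle", "0.35")):
            vals, errs = [], []
            for c in chems:
                rec = next(
                    (r for r in records if r.surface == surf and r.chemical == c
                     and r.basis == basis),
                    None,
                )
                vals.append(rec.delta_diff if rec else float("nan"))
                errs.append(rec.uncertainty if rec and rec.uncertainty else 0.0)
            ax.bar(xs + off, vals, width=0.4, color=colour, yerr=errs, capsize=2,
                   label={"wax": "Δδ_wax", "contact_angle": "Δδ_θ"}[basis])
        for y in (7.0, 10.0):
            ax.axhline(y, ls="--", lw=0.8, color="k")
        ax.set_xticks(xs)
        ax.set_xticklabels(chems, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("Δδ (MJ$^{1/2}$ m$^{-3/2}$)")
        ax.set_title(surf)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
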