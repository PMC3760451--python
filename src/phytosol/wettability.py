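"""Surface energetics from three-liquid contact angles.

Implements the van Oss-Chaudhury-Good (vOCG) acid-base decomposition.  For a
probe liquid L on a solid S, the Young-Dupre work of adhesion

    W_a = gamma_L (1 + cos theta)

equals twice the sum of the geometric-mean interaction terms

    W_a = 2 [ sqrt(gamma_S^LW gamma_L^LW) + sqrt(gamma_S^+ gamma_L^-)
              + sqrt(gamma_S^- gamma_L^+) ].

An apolar probe (diiodomethane) yields gamma_S^LW in closed form; the two
polar probes (water, glycerol) then give a 2x2 linear system in
sqrt(gamma_S^+), sqrt(gamma_S^-).  Negative roots are squared and flagged
rather than clamped (a clamp mode is available), matching how a slightly
non-physical solve manifests on very hydrophobic surfaces.

The surface solubility parameter is delta_theta = sqrt(e_c) with the
cohesive energy density taken from the empirical power law
e_c = (gamma_S / 0.75)^(3/2) (gamma_S in mJ m-2, e_c in MJ m-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProbeLiquid",
    "ContactAngleMeasurement",
    "ContactAngleSet",
    "SurfaceEnergyProfile",
    "DEFAULT_PROBE_LIQUIDS",
    "work_of_adhesion",
    "lw_from_apolar_probe",
    "solve_acid_base",
    "acid_base_component",
    "surface_polarity",
    "cohesive_energy_density",
    "delta_theta",
    "analyze_surface",
    "angles_from_components",
    "resample_profiles",
]

_APOLAR_TOL = 1e-9


@dataclass(frozen=True)
class ProbeLiquid:
    """Probe-liquid surface tension components, mJ m-2."""

    name: str
    gamma_total: float
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float

    def __post_init__(self):
        for f in ("gamma_total", "gamma_lw", "gamma_plus", "gamma_minus"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be non-negative")
        recomposed = self.gamma_lw + 2 * math.sqrt(self.gamma_plus * self.gamma_minus)
        if abs(recomposed - self.gamma_total) > 0.02 * self.gamma_total:
            raise ValueError(
                f"{self.name}: gamma_total {self.gamma_total} differs from "
                f"gamma_lw + 2 sqrt(gamma+ gamma-) = {recomposed:.2f} by more than 2%"
            )

    @property
    def is_apolar(self) -> bool:
        return self.gamma_plus < _APOLAR_TOL and self.gamma_minus < _APOLAR_TOL


#: Standard vOCG probe-liquid constants (mJ m-2), overridable by config.
DEFAULT_PROBE_LIQUIDS: dict[str, ProbeLiquid] = {
    "water": ProbeLiquid("water", 72.8, 21.8, 25.5, 25.5),
    "glycerol": ProbeLiquid("glycerol", 64.0, 34.0, 3.92, 57.4),
    "diiodomethane": ProbeLiquid("diiodomethane", 50.8, 50.8, 0.0, 0.0),
}


@dataclass(frozen=True)
class ContactAngleMeasurement:
    """Mean advancing contact angle of one liquid on one surface."""

    liquid: str
    theta_mean: float  # degrees
    theta_sd: float = 0.0
    n: int = 1

    def __post_init__(self):
        if not 0.0 < self.theta_mean < 180.0:
            raise ValueError(
                f"{self.liquid}: contact angle must lie in (0, 180) degrees, "
                f"got {self.theta_mean}"
            )
        if self.theta_sd < 0:
            raise ValueError(f"{self.liquid}: sd must be non-negative")
        if self.n < 1:
            raise ValueError(f"{self.liquid}: n must be >= 1")


@dataclass(frozen=True)
class ContactAngleSet:
    """Per-surface contact angles for up to three probe liquids."""

    surface_name: str
    measurements: tuple[ContactAngleMeasurement, ...]

    @classmethod
    def from_mapping(
        cls,
        surface_name: str,
        angles: Mapping[str, float | tuple[float, float, int]],
    ) -> "ContactAngleSet":
        ms = []
        for liquid, val in angles.items():
            if isinstance(val, (int, float)):
                ms.append(ContactAngleMeasurement(liquid, float(val)))
            else:
                mean, sd, n = val
                ms.append(ContactAngleMeasurement(liquid, float(mean), float(sd), int(n)))
        return cls(surface_name, tuple(ms))

    def angle(self, liquid: str) -> float:
        for m in self.measurements:
            if m.liquid == liquid:
                return m.theta_mean
        raise KeyError(f"{self.surface_name}: no angle recorded for {liquid!r}")


@dataclass(frozen=True)
class SurfaceEnergyProfile:
    """vOCG surface energetics of one surface.

    Energies in mJ m-2, cohesive energy density in MJ m-3, delta_theta in
    MJ^1/2 m^-3/2, polarity in %.
    """

    surface_name: str
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float
    gamma_ab: float
    gamma_total: float
    polarity: float
    cohesive_energy_density: float
    delta_theta: float
    work_of_adhesion: Mapping[str, float]
    flags: frozenset[str] = field(default_factory=frozenset)
    liquids_used: tuple[str, ...] = ()

    def __post_init__(self):
        if abs(self.gamma_ab - 2 * math.sqrt(self.gamma_plus * self.gamma_minus)) > 1e-9:
            raise ValueError("gamma_ab inconsistent with gamma_plus/gamma_minus")
        if abs(self.gamma_total - (self.gamma_lw + self.gamma_ab)) > 1e-9:
            raise ValueError("gamma_total inconsistent with gamma_lw + gamma_ab")


def _check_theta(theta: float) -> float:
    if not 0.0 < theta < 180.0:
        raise ValueError(f"contact angle must lie in (0, 180) degrees, got {theta}")
    return math.radians(theta)


def work_of_adhesion(theta: float, liquid: ProbeLiquid) -> float:
    """Young-Dupre work of adhesion W_a = gamma_L (1 + cos theta), mJ m-2."""
    rad = _check_theta(theta)
    return liquid.gamma_total * (1.0 + math.cos(rad))


def lw_from_apolar_probe(theta: float, liquid: ProbeLiquid) -> float:
    """gamma_S^LW = gamma_L (1 + cos theta)^2 / 4 for a fully dispersive probe."""
    if not liquid.is_apolar:
        raise ValueError(
            f"{liquid.name} is not apolar (gamma+ = {liquid.gamma_plus}, "
            f"gamma- = {liquid.gamma_minus}); the closed form requires "
            "gamma+ = gamma- = 0 (e.g. diiodomethane)"
        )
    rad = _check_theta(theta)
    return liquid.gamma_total * (1.0 + math.cos(rad)) ** 2 / 4.0


def solve_acid_base(
    theta_w: float,
    theta_g: float,
    gamma_lw: float,
    water: ProbeLiquid | None = None,
    glycerol: ProbeLiquid | None = None,
    clamp_negative: bool = False,
) -> tuple[float, float, frozenset[str]]:
    """Solve the two-polar-liquid system for (gamma_S^+, gamma_S^-).

    Returns the squared roots plus flags naming any negative root.  With
    ``clamp_negative`` a negative root is set to zero instead of squared.
    """
    water = water or DEFAULT_PROBE_LIQUIDS["water"]
    glycerol = glycerol or DEFAULT_PROBE_LIQUIDS["glycerol"]
    if gamma_lw < 0:
        raise ValueError("gamma_lw must be non-negative")
    for liq in (water, glycerol):
        if liq.gamma_plus <= 0 or liq.gamma_minus <= 0:
            raise ValueError(f"{liq.name}: polar probe needs positive acid and base parts")

    rows, rhs = [], []
    for theta, liq in ((theta_w, water), (theta_g, glycerol)):
        rad = _check_theta(theta)
        rows.append([math.sqrt(liq.gamma_minus), math.sqrt(liq.gamma_plus)])
        rhs.append(
            liq.gamma_total * (1.0 + math.cos(rad)) / 2.0
            - math.sqrt(gamma_lw * liq.gamma_lw)
        )
    a = np.array(rows)
    if abs(np.linalg.det(a)) < 1e-8:
        raise ValueError(
            f"degenerate probe-liquid pair ({water.name}, {glycerol.name}): "
            "acid-base system is singular"
        )
    x, y = np.linalg.solve(a, np.array(rhs))
    # snap numerically-zero roots so exactly dispersive surfaces stay unflagged
    scale = max(1.0, abs(rhs[0]), abs(rhs[1]))
    if -1e-9 * scale < x < 0:
        x = 0.0
    if -1e-9 * scale < y < 0:
        y = 0.0

    flags = set()
    if x < 0:
        flags.add("negative_root_plus")
    if y < 0:
        flags.add("negative_root_minus")
    if clamp_negative:
        gp = max(x, 0.0) ** 2
        gm = max(y, 0.0) ** 2
    else:
        gp, gm = x * x, y * y
    return float(gp), float(gm), frozenset(flags)


def acid_base_component(gamma_plus: float, gamma_minus: float) -> float:
    """gamma^AB = 2 sqrt(gamma+ gamma-), mJ m-2."""
    if gamma_plus < 0 or gamma_minus < 0:
        raise ValueError("acid and base components must be non-negative")
    return 2.0 * math.sqrt(gamma_plus * gamma_minus)


def surface_polarity(gamma_ab: float, gamma_total: float) -> float:
    """Surface polarity 100 * gamma^AB / gamma, in %."""
    if gamma_total <= 0:
        raise ValueError("total surface free energy must be positive")
    if gamma_ab < 0 or gamma_ab > gamma_total:
        raise ValueError("gamma_ab must lie in [0, gamma_total]")
    return 100.0 * gamma_ab / gamma_total


def cohesive_energy_density(gamma_total: float) -> float:
    """e_c = (gamma_S / 0.75)^(3/2), MJ m-3 for gamma_S in mJ m-2."""
    if gamma_total <= 0:
        raise ValueError("total surface free energy must be positive")
    return (gamma_total / 0.75) ** 1.5


def delta_theta(e_c: float) -> float:
    """Surface solubility parameter sqrt(e_c), MJ^1/2 m^-3/2."""
    if e_c < 0:
        raise ValueError("cohesive energy density must be non-negative")
    return math.sqrt(e_c)


def _classify_liquids(
    angles: ContactAngleSet, liquids: Mapping[str, ProbeLiquid]
) -> tuple[ContactAngleMeasurement, list[ContactAngleMeasurement]]:
    apolar, polar = [], []
    for m in angles.measurements:
        liq = liquids.get(m.liquid)
        if liq is None:
            raise KeyError(
                f"{angles.surface_name}: no probe-liquid constants for {m.liquid!r}"
            )
        (apolar if liq.is_apolar else polar).append(m)
    if len(apolar) != 1 or len(polar) != 2:
        raise ValueError(
            f"{angles.surface_name}: need exactly one apolar and two polar "
            f"probe liquids, got {len(apolar)} apolar and {len(polar)} polar"
        )
    return apolar[0], polar


def analyze_surface(
    angles: ContactAngleSet,
    liquids: Mapping[str, ProbeLiquid] | None = None,
    clamp_negative: bool = False,
) -> SurfaceEnergyProfile:
    """Full vOCG profile of one surface from its three contact angles."""
    liquids = dict(liquids or DEFAULT_PROBE_LIQUIDS)
    apolar_m, polar_ms = _classify_liquids(angles, liquids)
    glw = lw_from_apolar_probe(apolar_m.theta_mean, liquids[apolar_m.liquid])
    # stable order: water-like (most symmetric acid/base) first if present
    polar_ms = sorted(polar_ms, key=lambda m: m.liquid != "water")
    gp, gm, flags = solve_acid_base(
        polar_ms[0].theta_mean,
        polar_ms[1].theta_mean,
        glw,
        liquids[polar_ms[0].liquid],
        liquids[polar_ms[1].liquid],
        clamp_negative=clamp_negative,
    )
    gab = acid_base_component(gp, gm)
    gtot = glw + gab
    wa = {
        m.liquid: work_of_adhesion(m.theta_mean, liquids[m.liquid])
        for m in angles.measurements
    }
    ec = cohesive_energy_density(gtot)
    return SurfaceEnergyProfile(
        surface_name=angles.surface_name,
        gamma_lw=glw,
        gamma_plus=gp,
        gamma_minus=gm,
        gamma_ab=gab,
        gamma_total=gtot,
        polarity=surface_polarity(gab, gtot),
        cohesive_energy_density=ec,
        delta_theta=delta_theta(ec),
        work_of_adhesion=wa,
        flags=flags,
        liquids_used=tuple(m.liquid for m in angles.measurements),
    )


def angles_from_components(
    gamma_lw: float,
    gamma_plus: float,
    gamma_minus: float,
    liquids: Mapping[str, ProbeLiquid] | None = None,
) -> dict[str, float]:
    """Forward model: contact angles (degrees) implied by a component triple.

    Inverse of :func:`analyze_surface`; raises if a liquid would be out of
    the physical cos-theta range (complete wetting or dewetting).
    """
    liquids = dict(liquids or DEFAULT_PROBE_LIQUIDS)
    out = {}
    for name, liq in liquids.items():
        wa = 2.0 * (
            math.sqrt(gamma_lw * liq.gamma_lw)
            + math.sqrt(gamma_plus * liq.gamma_minus)
            + math.sqrt(gamma_minus * liq.gamma_plus)
        )
        cos = wa / liq.gamma_total - 1.0
        if not -1.0 < cos < 1.0:
            raise ValueError(
                f"component triple implies cos(theta) = {cos:.3f} for {name}; "
                "no finite contact angle exists"
            )
        out[name] = math.degrees(math.acos(cos))
    return out


def resample_profiles(
    angles: ContactAngleSet,
    liquids: Mapping[str, ProbeLiquid] | None = None,
    draws: int = 10_000,
    seed: int = 20121114,
    clamp_negative: bool = False,
) -> dict[str, tuple[float, float]]:
    """Parametric uncertainty on derived quantities.

    Angles are redrawn from Normal(mean, sd) per liquid (truncated to the
    open (0, 180) degree interval) and the profile recomputed; returns
    {quantity: (mean, sd)} for the scalar outputs.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    keys = ("gamma_lw", "gamma_plus", "gamma_minus", "gamma_ab", "gamma_total",
            "polarity", "delta_theta")
    samples: dict[str, list[float]] = {k: [] for k in keys}
    eps = 1e-6
    for _ in range(draws):
        ms = tuple(
            ContactAngleMeasurement(
                m.liquid,
                float(np.clip(rng.normal(m.theta_mean, m.theta_sd), eps, 180.0 - eps)),
                m.theta_sd,
                m.n,
            )
            for m in angles.measurements
        )
        prof = analyze_surface(
            ContactAngleSet(angles.surface_name, ms), liquids, clamp_negative
        )
        for k in keys:
            samples[k].append(getattr(prof, k))
    return {
        k: (float(np.mean(vals)), float(np.std(vals, ddof=1) if draws > 1 else 0.0))
        for k, vals in samples.items()
    }
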