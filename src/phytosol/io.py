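"""File parsing and writing: compound definitions, contact angles, results.

Compound files are JSON (a list of objects with keys ``name``, ``formula``,
``density`` and/or ``molar_volume``, ``groups`` mapping label -> count,
``symmetry_planes``, ``role``) or CSV with one column per structural-group
label.  Schema violations are aggregated: every offending record is listed,
none silently dropped.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .groups import VAN_KREVELEN_TABLE, GroupContributionTable
from .hansen import HansenResult, MoleculeSpec
from .wettability import ContactAngleSet, ProbeLiquid

__all__ = [
    "CompoundFileError",
    "parse_compounds",
    "write_compounds",
    "write_parameters_csv",
    "read_parameters_csv",
    "parse_contact_angles",
    "write_profiles_csv",
    "load_probe_liquids",
]

_SPEC_KEYS = {"name", "formula", "density", "molar_volume", "groups", "symmetry_planes", "role"}


class CompoundFileError(ValueError):
    """Aggregated record-level schema violations in a compound file."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(errors)} invalid record(s):\n" + "\n".join(f"  - {e}" for e in errors)
        )


def _spec_from_record(
    rec: Mapping, table: GroupContributionTable, where: str
) -> MoleculeSpec:
    unknown = set(rec) - _SPEC_KEYS
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    groups = rec.get("groups") or {}
    for label in groups:
        table.resolve(label)  # raises with the offending label named
    return MoleculeSpec(
        name=rec["name"],
        formula=rec["formula"],
        groups=groups,
        density=rec.get("density"),
        molar_volume=rec.get("molar_volume"),
        symmetry_planes=rec.get("symmetry_planes", 0),
        role=rec.get("role", "other"),
    )


def parse_compounds(
    path: str | Path, table: GroupContributionTable = VAN_KREVELEN_TABLE
) -> list[MoleculeSpec]:
    """Read and validate a JSON or CSV compound-definition file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".json", ".jsn"):
        records = json.loads(path.read_text() or "[]")
        if isinstance(records, Mapping):  # allow the registry export shape
            records = records.get("compounds", [])
        if not isinstance(records, list):
            raise CompoundFileError([f"{path}: top level must be a JSON list of objects"])
        labelled = [(f"record {i + 1} ({r.get('name', '?') if isinstance(r, Mapping) else r!r})", r)
                    for i, r in enumerate(records)]
    elif path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        meta = {"name", "formula", "density", "molar_volume", "symmetry_planes", "row", "role"}
        group_cols = [c for c in df.columns if c not in meta]
        labelled = []
        for i, row in df.iterrows():
            rec = {
                "name": row.get("name"),
                "formula": row.get("formula"),
                "groups": {
                    c: int(row[c]) for c in group_cols if pd.notna(row[c]) and int(row[c]) > 0
                },
            }
            for key in ("density", "molar_volume"):
                if key in df.columns and pd.notna(row[key]):
                    rec[key] = float(row[key])
            if "symmetry_planes" in df.columns and pd.notna(row["symmetry_planes"]):
                sp = row["symmetry_planes"]
                rec["symmetry_planes"] = sp if sp == "many" else int(sp)
            if "role" in df.columns and pd.notna(row["role"]):
                rec["role"] = str(row["role"])
            labelled.append((f"row {i + 1} ({rec['name']})", rec))
    else:
        raise ValueError(f"unsupported compound-file extension: {path.suffix!r}")

    if not labelled:
        import warnings

        warnings.warn(f"{path}: empty compound file", stacklevel=2)
        return []

    specs, errors = [], []
    for where, rec in labelled:
        try:
            if not isinstance(rec, Mapping):
                raise ValueError(f"{where}: not an object")
            specs.append(_spec_from_record(rec, table, where))
        except (ValueError, KeyError) as exc:
            errors.append(f"{where}: {exc}")
    if errors:
        raise CompoundFileError(errors)
    return specs


def write_compounds(specs: Iterable[MoleculeSpec], path: str | Path) -> None:
    """Serialize specs to the JSON compound schema (lossless round-trip)."""
    records = []
    for s in specs:
        rec = {
            "name": s.name,
            "formula": s.formula if isinstance(s.formula, str) else dict(s.formula),
            "groups": dict(s.groups),
            "symmetry_planes": s.symmetry_planes,
            "role": s.role,
        }
        if s.density is not None:
            rec["density"] = s.density
        if s.molar_volume is not None:
            rec["molar_volume"] = s.molar_volume
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1))


def write_parameters_csv(
    results: Iterable[HansenResult], path: str | Path, precision: int | None = None
) -> None:
    """Solubility-parameter table as CSV.

    Full float precision by default; ``precision`` adds display rounding
    (1 decimal mirrors the source tables).
    """
    rows = []
    for r in results:
        p = r.parameters
        rows.append(
            {
                "name": r.name,
                "v": r.molar_volume,
                "delta_d": p.delta_d,
                "delta_p": p.delta_p,
                "delta_h": p.delta_h,
                "delta_total": p.delta_total,
                "symmetry_factor": r.symmetry_factor,
                "flags": ";".join(r.flags),
            }
        )
    df = pd.DataFrame(rows)
    if precision is not None:
        if precision < 1:
            raise ValueError("display precision must be >= 1 decimal")
        for c in ("v", "delta_d", "delta_p", "delta_h", "delta_total"):
            df[c] = df[c].round(precision)
    df.to_csv(path, index=False)


def read_parameters_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parser so write-then-read is lossless to the last ulp
    return pd.read_csv(path, float_precision="round_trip")


def parse_contact_angles(path: str | Path) -> list[ContactAngleSet]:
    """Read a contact-angle CSV: surface, liquid, theta_mean_deg[, theta_sd_deg, n]."""
    df = pd.read_csv(path)
    required = {"surface", "liquid", "theta_mean_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sets = []
    for surface, grp in df.groupby("surface", sort=False):
        angles = {}
        for _, row in grp.iterrows():
            sd = float(row["theta_sd_deg"]) if "theta_sd_deg" in grp.columns and not math.isnan(
                row.get("theta_sd_deg", float("nan"))
            ) else 0.0
            n = int(row["n"]) if "n" in grp.columns and not pd.isna(row.get("n")) else 1
            angles[str(row["liquid"])] = (float(row["theta_mean_deg"]), sd, n)
        sets.append(ContactAngleSet.from_mapping(str(surface), angles))
    return sets


def write_profiles_csv(profiles, path: str | Path, precision: int | None = None) -> None:
    """Surface-energetics table mirroring the published column layout."""
    rows = []
    for p in profiles:
        row = {
            "surface": p.surface_name,
            "gamma_lw": p.gamma_lw,
            "gamma_minus": p.gamma_minus,
            "gamma_plus": p.gamma_plus,
            "gamma_ab": p.gamma_ab,
            "gamma_total": p.gamma_total,
            "polarity_pct": p.polarity,
            "delta_theta": p.delta_theta,
        }
        for liq, wa in p.work_of_adhesion.items():
            row[f"wa_{liq}"] = wa
        row["flags"] = ";".join(sorted(p.flags))
        rows.append(row)
    df = pd.DataFrame(rows)
    if precision is not None:
        num = df.select_dtypes("number").columns
        df[num] = df[num].round(precision)
    df.to_csv(path, index=False)


def load_probe_liquids(path: str | Path) -> dict[str, ProbeLiquid]:
    """Probe-liquid constants from JSON/YAML keyed by liquid name."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    out = {}
    for name, rec in data.items():
        out[name] = ProbeLiquid(
            name=name,
            gamma_total=float(rec["gamma_total"]),
            gamma_lw=float(rec["gamma_lw"]),
            gamma_plus=float(rec["gamma_plus"]),
            gamma_minus=float(rec["gamma_minus"]),
        )
    return out
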