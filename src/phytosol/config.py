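"""Run configuration: one authoritative object, file-loadable, CLI-overridable."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

log = logging.getLogger("phytosol")

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a toolkit run.

    symmetry_mode / polar_combination select the polar-component conventions
    (see :mod:`phytosol.hansen`); thresholds are the miscibility band limits
    in MJ^1/2 m^-3/2; resampling controls the parametric uncertainty draws.
    """

    symmetry_mode: str = "on_delta_p"
    polar_combination: str = "per_group_type"
    negative_root_mode: str = "square"  # or "clamp"
    miscible_below: float = 7.0
    immiscible_above: float = 10.0
    liquids_file: str | None = None  # None -> standard vOCG constants
    resampling_draws: int = 10_000
    resampling_seed: int = 20121114
    output_precision: int = 1

    def __post_init__(self):
        if not 0 < self.miscible_below < self.immiscible_above:
            raise ValueError("thresholds must satisfy 0 < miscible_below < immiscible_above")
        if self.resampling_draws < 1:
            raise ValueError("resampling draws must be >= 1")
        if self.output_precision < 1:
            raise ValueError("output precision must be >= 1 decimal")
        if self.negative_root_mode not in ("square", "clamp"):
            raise ValueError(f"unknown negative_root_mode {self.negative_root_mode!r}")

    @property
    def clamp_negative(self) -> bool:
        return self.negative_root_mode == "clamp"

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})

    def log_resolved(self) -> None:
        log.info("resolved config: %s", json.dumps(asdict(self), sort_keys=True))


def load_config(path: str | Path | None) -> RunConfig:
    """RunConfig from a JSON or YAML file; defaults when path is None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text or "{}")
    return RunConfig(**data)
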