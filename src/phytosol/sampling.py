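"""Random molecule generation for property-based testing.

Generated specs are chemically loose (no connectivity is implied) but always
satisfy the MoleculeSpec contract; formulas are synthesised from the group
inventory so the heavy-atom consistency check passes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .groups import VAN_KREVELEN_TABLE, GroupContributionTable
from .hansen import MoleculeSpec

__all__ = ["MoleculeConstraints", "random_molecule"]


@dataclass(frozen=True)
class MoleculeConstraints:
    """Sampling constraints: allowed groups, per-group counts, molar volume."""

    allowed_groups: Sequence[str] = ()  # empty -> whole canonical table
    min_groups: int = 1  # distinct group labels drawn
    max_groups: int = 5
    min_count: int = 1
    max_count: int = 30
    v_range: tuple[float, float] = (40.0, 1200.0)
    symmetry_planes: Sequence[int | str] = (0, 1, 2, "many")

    def __post_init__(self):
        if self.min_groups < 1 or self.max_groups < self.min_groups:
            raise ValueError("need 1 <= min_groups <= max_groups")
        if self.min_count < 1 or self.max_count < self.min_count:
            raise ValueError("need 1 <= min_count <= max_count")
        if not 0 < self.v_range[0] <= self.v_range[1]:
            raise ValueError("molar-volume range must be positive and ordered")


def random_molecule(
    seed: int | np.random.Generator,
    constraints: MoleculeConstraints = MoleculeConstraints(),
    table: GroupContributionTable = VAN_KREVELEN_TABLE,
) -> MoleculeSpec:
    """A reproducible random MoleculeSpec satisfying ``constraints``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [table.resolve(g) for g in constraints.allowed_groups] or list(table.labels())
    labels = sorted(set(labels))
    n_distinct = min(
        len(labels), int(rng.integers(constraints.min_groups, constraints.max_groups + 1))
    )
    if n_distinct < constraints.min_groups:
        raise ValueError(
            f"unsatisfiable constraints: only {len(labels)} allowed group(s) but "
            f"min_groups={constraints.min_groups}"
        )
    chosen = rng.choice(labels, size=n_distinct, replace=False)
    groups = {
        str(g): int(rng.integers(constraints.min_count, constraints.max_count + 1))
        for g in chosen
    }
    v = float(rng.uniform(*constraints.v_range))
    # synthesise a formula from the inventory's heavy-atom content
    counts: dict[str, int] = {}
    for g, n in groups.items():
        for elem, c in table[g].elements.items():
            counts[elem] = counts.get(elem, 0) + n * c
    formula = {e: c for e, c in counts.items() if c > 0} or {"C": 1}
    planes = constraints.symmetry_planes[int(rng.integers(len(constraints.symmetry_planes)))]
    return MoleculeSpec(
        name=f"random-{rng.integers(1 << 31)}",
        formula=formula,
        groups=groups,
        molar_volume=v,
        symmetry_planes=planes,
        role="other",
    )
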