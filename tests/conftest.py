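import math

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def table():
    from phytosol.groups import VAN_KREVELEN_TABLE

    return VAN_KREVELEN_TABLE


@pytest.fixture
def pepper_angles():
    from phytosol.wettability import ContactAngleSet

    return ContactAngleSet.from_mapping(
        "pepper",
        {"water": (83.4, 4.7, 30), "glycerol": (68.6, 9.2, 30), "diiodomethane": (60.8, 6.2, 30)},
    )


def naive_hansen(groups, v, symmetry_planes, table):
    """Independent per-instance loop oracle for the three components.

    Deliberately naive: walks every group instance one at a time, keeping a
    running linear polar sum per label, then combines.
    """
    f_d = 0.0
    e_h = 0.0
    polar_by_label: dict[str, float] = {}
    for label, count in groups.items():
        entry = table[label]
        canon = table.resolve(label)
        for _ in range(count):
            f_d += entry.f_d
            e_h += entry.e_h
            polar_by_label[canon] = polar_by_label.get(canon, 0.0) + entry.f_p
    factor = table.symmetry_factor(symmetry_planes)
    delta_d = f_d / v
    delta_p = factor * math.sqrt(sum(t * t for t in polar_by_label.values())) / v
    delta_h = math.sqrt(e_h / v)
    return delta_d, delta_p, delta_h, math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)
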