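import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytosol.wettability import (
    DEFAULT_PROBE_LIQUIDS,
    ContactAngleMeasurement,
    ContactAngleSet,
    ProbeLiquid,
    acid_base_component,
    analyze_surface,
    angles_from_components,
    cohesive_energy_density,
    delta_theta,
    lw_from_apolar_probe,
    resample_profiles,
    solve_acid_base,
    surface_polarity,
    work_of_adhesion,
)

WATER = DEFAULT_PROBE_LIQUIDS["water"]
GLYCEROL = DEFAULT_PROBE_LIQUIDS["glycerol"]
DIM = DEFAULT_PROBE_LIQUIDS["diiodomethane"]


class TestProbeLiquids:
    def test_standard_set_is_self_consistent(self):
        for liq in DEFAULT_PROBE_LIQUIDS.values():
            recomposed = liq.gamma_lw + 2 * math.sqrt(liq.gamma_plus * liq.gamma_minus)
            assert recomposed == pytest.approx(liq.gamma_total, rel=0.02)
        assert DIM.is_apolar and not WATER.is_apolar

    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError, match="2%"):
            ProbeLiquid("broken", 100.0, 10.0, 1.0, 1.0)


class TestWorkOfAdhesion:
    @pytest.mark.parametrize(
        "theta, liquid, expected",
        [
            (83.4, WATER, 81.2),  # pepper / water
            (90.0, WATER, 72.8),  # cos 90 = 0 -> gamma_L
            (90.0, GLYCEROL, 64.0),
            (142.6, WATER, 15.0),  # eucalyptus / water
        ],
    )
    def test_examples(self, theta, liquid, expected):
        assert work_of_adhesion(theta, liquid) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("theta", [0.0, -3.0, 180.0, 270.0])
    def test_degenerate_angles_rejected(self, theta):
        with pytest.raises(ValueError, match="\\(0, 180\\)"):
            work_of_adhesion(theta, WATER)

    @given(st.floats(0.01, 179.98), st.floats(0.001, 0.01))
    def test_strictly_decreasing_in_theta(self, theta, step):
        assert work_of_adhesion(theta, WATER) > work_of_adhesion(theta + step, WATER)

    def test_complete_wetting_limit(self):
        assert work_of_adhesion(1e-6, WATER) == pytest.approx(2 * WATER.gamma_total)


class TestLifshitzVanDerWaals:
    def test_pepper_and_peach(self):
        assert lw_from_apolar_probe(60.8, DIM) == pytest.approx(28.1, abs=0.05)
        # peach recomputes to 31.05, one half-unit below the tabulated 31.1
        assert lw_from_apolar_probe(55.7, DIM) == pytest.approx(31.1, abs=0.1)

    def test_perfect_wetting_limit(self):
        assert lw_from_apolar_probe(1e-6, DIM) == pytest.approx(DIM.gamma_total)

    def test_polar_probe_rejected(self):
        with pytest.raises(ValueError, match="not apolar"):
            lw_from_apolar_probe(60.0, WATER)


class TestAcidBaseSolve:
    def test_pepper(self):
        gp, gm, flags = solve_acid_base(83.4, 68.6, 28.11)
        assert gp == pytest.approx(1.4, abs=0.05)
        assert gm == pytest.approx(3.9, abs=0.05)
        assert not flags

    def test_peach_negative_roots_squared_and_flagged(self):
        gp, gm, flags = solve_acid_base(134.2, 130.9, 31.05)
        assert gm == pytest.approx(0.04, abs=0.01)
        assert flags == {"negative_root_minus", "negative_root_plus"}
        gp_c, gm_c, _ = solve_acid_base(134.2, 130.9, 31.05, clamp_negative=True)
        assert gp_c == 0.0 and gm_c == 0.0

    def test_purely_dispersive_surface_recovers_zero_without_flags(self):
        angles = angles_from_components(30.0, 0.0, 0.0)
        glw = lw_from_apolar_probe(angles["diiodomethane"], DIM)
        gp, gm, flags = solve_acid_base(angles["water"], angles["glycerol"], glw)
        assert gp == pytest.approx(0.0, abs=1e-12)
        assert gm == pytest.approx(0.0, abs=1e-12)
        assert not flags

    def test_degenerate_liquid_pair_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            solve_acid_base(80.0, 80.0, 30.0, WATER, WATER)


class TestDerivedQuantities:
    def test_acid_base_component(self):
        assert acid_base_component(1.37, 3.87) == pytest.approx(4.6, abs=0.05)
        assert acid_base_component(0.0, 12.0) == 0.0
        # eucalyptus printed pair: own-consistent value, not the printed 1.0
        assert acid_base_component(6.5, 0.2) == pytest.approx(2.28, abs=0.005)

    def test_surface_polarity(self):
        assert surface_polarity(4.6, 32.7) == pytest.approx(14.1, abs=0.05)
        assert surface_polarity(0.0, 20.0) == 0.0
        assert surface_polarity(1.2, 32.2) == pytest.approx(3.7, abs=0.05)
        with pytest.raises(ValueError):
            surface_polarity(1.0, 0.0)
        with pytest.raises(ValueError):
            surface_polarity(5.0, 4.0)

    def test_cohesive_energy_density(self):
        assert cohesive_energy_density(0.75) == pytest.approx(1.0)
        assert cohesive_energy_density(17.4) == pytest.approx(111.75, abs=0.05)
        assert cohesive_energy_density(32.7) == pytest.approx(287.9, abs=0.05)
        with pytest.raises(ValueError):
            cohesive_energy_density(0.0)

    def test_delta_theta_values_and_monotonicity(self):
        assert delta_theta(cohesive_energy_density(17.4)) == pytest.approx(10.6, abs=0.05)
        assert delta_theta(cohesive_energy_density(32.7)) == pytest.approx(17.0, abs=0.05)
        gammas = np.linspace(5.0, 60.0, 40)
        dts = [delta_theta(cohesive_energy_density(g)) for g in gammas]
        assert all(b > a for a, b in zip(dts, dts[1:]))


class TestAnalyzeSurface:
    def test_pepper_profile(self, pepper_angles):
        prof = analyze_surface(pepper_angles)
        assert round(prof.gamma_lw, 1) == 28.1
        assert round(prof.gamma_minus, 1) == 3.9
        assert round(prof.gamma_plus, 1) == 1.4
        assert round(prof.gamma_ab, 1) == 4.6
        assert round(prof.gamma_total, 1) == 32.7
        assert round(prof.polarity, 1) == 14.1
        assert round(prof.delta_theta, 1) == 17.0
        assert round(prof.work_of_adhesion["water"], 1) == 81.2
        assert round(prof.work_of_adhesion["glycerol"], 1) == 87.4
        assert round(prof.work_of_adhesion["diiodomethane"], 1) == 75.6
        assert not prof.flags

    def test_round_trip_reproduces_work_of_adhesion(self, pepper_angles):
        """Linear-system consistency: solved components give back the inputs."""
        prof = analyze_surface(pepper_angles)
        for liq_name in ("water", "glycerol"):
            liq = DEFAULT_PROBE_LIQUIDS[liq_name]
            wa = 2 * (
                math.sqrt(prof.gamma_lw * liq.gamma_lw)
                + math.sqrt(prof.gamma_plus * liq.gamma_minus)
                + math.sqrt(prof.gamma_minus * liq.gamma_plus)
            )
            assert wa == pytest.approx(prof.work_of_adhesion[liq_name], rel=1e-9)

    def test_two_liquid_set_rejected(self):
        angles = ContactAngleSet.from_mapping("partial", {"water": 80.0, "glycerol": 70.0})
        with pytest.raises(ValueError, match="one apolar and two polar"):
            analyze_surface(angles)

    def test_unknown_liquid_rejected(self, pepper_angles):
        angles = ContactAngleSet.from_mapping("odd", {"water": 80.0, "glycerol": 70.0,
                                                      "benzene": 30.0})
        with pytest.raises(KeyError, match="benzene"):
            analyze_surface(angles)

    def test_forward_inverse_round_trip(self):
        """500 random physical component triples survive generate-then-invert."""
        rng = np.random.default_rng(7)
        done = 0
        while done < 500:
            glw = rng.uniform(10.0, 45.0)
            gp = rng.uniform(0.05, 8.0)
            gm = rng.uniform(0.05, 30.0)
            try:
                angles = angles_from_components(glw, gp, gm)
            except ValueError:  # complete wetting for this triple; resample
                continue
            prof = analyze_surface(
                ContactAngleSet.from_mapping(
                    "synthetic", {k: v for k, v in angles.items()}
                )
            )
            assert prof.gamma_lw == pytest.approx(glw, abs=1e-6)
            assert prof.gamma_plus == pytest.approx(gp, abs=1e-6)
            assert prof.gamma_minus == pytest.approx(gm, abs=1e-6)
            assert not prof.flags
            done += 1


class TestResampling:
    def test_deterministic_for_fixed_seed(self, pepper_angles):
        a = resample_profiles(pepper_angles, draws=200, seed=123)
        b = resample_profiles(pepper_angles, draws=200, seed=123)
        assert a == b

    def test_spread_tracks_angle_uncertainty(self, pepper_angles):
        stats = resample_profiles(pepper_angles, draws=300, seed=5)
        mean, sd = stats["delta_theta"]
        assert mean == pytest.approx(17.0, abs=0.5)
        assert 0.0 < sd < 3.0

    def test_invalid_draws_rejected(self, pepper_angles):
        with pytest.raises(ValueError):
            resample_profiles(pepper_angles, draws=0)


class TestMeasurementValidation:
    @pytest.mark.parametrize("theta", [0.0, 180.0, -10.0])
    def test_angle_bounds(self, theta):
        with pytest.raises(ValueError):
            ContactAngleMeasurement("water", theta)

    def test_sd_and_n(self):
        with pytest.raises(ValueError):
            ContactAngleMeasurement("water", 80.0, theta_sd=-1.0)
        with pytest.raises(ValueError):
            ContactAngleMeasurement("water", 80.0, n=0)
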