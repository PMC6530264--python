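"""Water-ethanol thermodynamics: saturation pressures, composition
conversions, mixture density and activities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bottlesim import thermo

K = 273.15


class TestSaturationPressure:
    def test_water_normal_boiling_point_is_standard_pressure(self):
        # every correction term vanishes at the reference temperature
        assert thermo.saturation_pressure("water", 373.15) == pytest.approx(
            101324.6, rel=1e-9
        )

    @pytest.mark.parametrize(
        "t_c, steam_table_pa",
        [(20.0, 2338.8), (35.0, 5626.7), (50.0, 12351.0)],
    )
    def test_water_matches_steam_tables_within_1pct(self, t_c, steam_table_pa):
        p = thermo.saturation_pressure("water", K + t_c)
        assert p == pytest.approx(steam_table_pa, rel=0.01)

    def test_ethanol_normal_boiling_point(self):
        # hand evaluation of the Antoine correlation at 78.3 degC:
        # 10^(2.12490 + 8.20417 - 1642.89 / (230.3 + 78.3)) = 101.25 kPa
        p = thermo.saturation_pressure("ethanol", K + 78.3)
        assert p == pytest.approx(101.3e3, rel=0.005)

    def test_ethanol_50c_hand_value(self):
        # 10^(2.12490 + 8.20417 - 1642.89 / 280.3) = 29.37 kPa
        p = thermo.saturation_pressure("ethanol", K + 50.0)
        assert p == pytest.approx(29.37e3, rel=0.002)

    def test_monotonic_in_temperature(self):
        for species, lo, hi in [("water", 274.0, 372.0), ("ethanol", K - 50, K + 79)]:
            t = np.linspace(lo, hi, 40)
            p = [thermo.saturation_pressure(species, ti) for ti in t]
            assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize(
        "species, t_k",
        [("water", 200.0), ("water", 400.0), ("ethanol", K - 80), ("ethanol", K + 90)],
    )
    def test_out_of_range_rejected_naming_the_range(self, species, t_k):
        with pytest.raises(ValueError, match="valid"):
            thermo.saturation_pressure(species, t_k)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            thermo.saturation_pressure("methanol", 300.0)


class TestComposition:
    def test_pure_limits(self):
        assert thermo.composition_from_abv(0.0).x_e == 0.0
        assert thermo.composition_from_abv(0.0).w_e == 0.0
        assert thermo.composition_from_abv(1.0).x_e == pytest.approx(1.0)
        assert thermo.composition_from_abv(1.0).w_e == pytest.approx(1.0)

    def test_vodka_strength_hand_values(self):
        # w_e = 789.24 * 0.4 / rho(20 C, abv=0.4 ~ 948.0) = 0.333;
        # x_e = (w/46.069) / (w/46.069 + (1-w)/18.015) = 0.163
        c = thermo.composition_from_abv(0.4)
        assert c.w_e == pytest.approx(0.333, abs=0.002)
        assert c.x_e == pytest.approx(0.163, abs=0.002)

    def test_abv_from_masses_trivial(self):
        assert thermo.abv_from_masses(0.0, 1.0) == 0.0
        assert thermo.abv_from_masses(1.0, 0.0) == 1.0

    def test_mass_fraction_inverse_hand_value(self):
        # inverse of the conversion above
        abv = thermo.abv_from_masses(0.333, 0.667)
        assert abv == pytest.approx(0.400, abs=0.002)

    @pytest.mark.parametrize("abv", np.round(np.linspace(0, 1, 11), 10).tolist())
    def test_round_trip_identity(self, abv):
        c = thermo.composition_from_abv(abv)
        back = thermo.abv_from_masses(c.w_e, 1.0 - c.w_e)
        assert back == pytest.approx(abv, abs=1e-8)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=40, deadline=None)
    def test_round_trip_property(self, abv):
        c = thermo.composition_from_abv(abv)
        assert abs(thermo.abv_from_masses(c.w_e, 1.0 - c.w_e) - abv) < 1e-8
        assert abs(c.x_e + c.x_w - 1.0) < 1e-12

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_composition_domain_errors(self, bad):
        with pytest.raises(ValueError):
            thermo.composition_from_abv(bad)

    @pytest.mark.parametrize("m_e, m_w", [(-0.1, 1.0), (float("nan"), 1.0), (0.0, 0.0)])
    def test_mass_domain_errors(self, m_e, m_w):
        with pytest.raises(ValueError):
            thermo.abv_from_masses(m_e, m_w)


class TestDensity:
    def test_pure_component_anchors(self):
        assert thermo.density(20.0, 0.0) == pytest.approx(998.2, abs=0.5)
        assert thermo.density(20.0, 1.0) == pytest.approx(789.2, abs=0.5)

    def test_decreasing_in_abv_on_grid(self):
        for t in (-10.0, 0.0, 20.0, 40.0, 60.0):
            rho = [thermo.density(t, a) for a in np.linspace(0, 1, 41)]
            assert np.all(np.diff(rho) < 0), f"non-monotone at {t} degC"

    def test_interpolation_continuity_at_cell_midpoints(self):
        # bilinear table within 0.5 kg/m^3 of the polynomial everywhere
        table = thermo.DensityTable()
        t_mid = 0.5 * (table.t_grid[:-1] + table.t_grid[1:])
        a_mid = 0.5 * (table.abv_grid[:-1] + table.abv_grid[1:])
        err = max(
            abs(table(t, a) - thermo.density(t, a))
            for t in t_mid[::6]
            for a in a_mid[::5]
        )
        assert err < 0.5

    def test_table_interpolation_close_to_polynomial(self):
        table = thermo.DensityTable()
        for t, a in [(17.3, 0.37), (43.0, 0.11), (-5.0, 0.93)]:
            assert table(t, a) == pytest.approx(thermo.density(t, a), abs=0.5)

    @pytest.mark.parametrize("t_c, abv", [(-30.0, 0.5), (80.0, 0.5), (20.0, 1.2)])
    def test_out_of_grid_rejected(self, t_c, abv):
        with pytest.raises(ValueError):
            thermo.density(t_c, abv)


# printed 35 degC activity values of typical beverages (beer, wine,
# vodka, rum strengths)
ACTIVITY_VALUES = [
    (0.08, 0.977, 0.153),
    (0.15, 0.960, 0.243),
    (0.40, 0.911, 0.408),
    (0.70, 0.819, 0.541),
]


class TestActivities:
    @pytest.mark.parametrize("abv, a_w_ref, a_e_ref", ACTIVITY_VALUES)
    def test_reference_activities_35c(self, abv, a_w_ref, a_e_ref):
        a_w, a_e, _, _ = thermo.activities(35.0, abv)
        assert a_w == pytest.approx(a_w_ref, abs=0.010)
        assert a_e == pytest.approx(a_e_ref, abs=0.010)

    @pytest.mark.parametrize("t_c", [20.0, 35.0, 50.0])
    def test_raoult_limits(self, t_c):
        a_w, _, gamma_w, _ = thermo.activities(t_c, 0.0)
        assert abs(gamma_w - 1.0) <= 1e-3
        assert a_w == pytest.approx(1.0, abs=1e-3)
        _, a_e, _, gamma_e = thermo.activities(t_c, 1.0)
        assert abs(gamma_e - 1.0) <= 1e-3
        assert a_e == pytest.approx(1.0, abs=1e-3)

    def test_positive_deviation_from_ideality(self):
        for t_c in (10.0, 35.0, 70.0):
            for abv in np.linspace(0.0, 1.0, 11):
                _, _, gamma_w, gamma_e = thermo.activities(t_c, abv)
                assert gamma_w >= 1.0 - 1e-9
                assert gamma_e >= 1.0 - 1e-9

    def test_activities_bounded(self):
        for abv in np.linspace(0.0, 1.0, 11):
            a_w, a_e, _, _ = thermo.activities(35.0, abv)
            assert 0.0 <= a_w <= 1.0 + 1e-9
            assert 0.0 <= a_e <= 1.0 + 1e-9


class TestPartialPressures:
    def test_no_ethanol_no_ethanol_pressure(self):
        p_w, p_e, p_tot = thermo.partial_pressures(35.0, 0.0)
        assert p_e == 0.0
        assert p_tot == p_w

    def test_additivity(self):
        p_w, p_e, p_tot = thermo.partial_pressures(50.0, 0.7)
        assert p_tot == p_w + p_e

    def test_liquor_50c_total_pressure(self):
        _, _, p_tot = thermo.partial_pressures(50.0, 0.7)
        assert p_tot == pytest.approx(25e3, abs=1.5e3)
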