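"""Wall transport: material properties, finite-volume solver, oracles."""

import numpy as np
import pytest

from bottlesim import transport as tr
from bottlesim.geometry import WallSection, sectionize
from bottlesim.headspace import initial_inventory


def planar_section(thickness=1e-3, area=0.01):
    # radius >> thickness puts the cylindrical operator in its planar limit
    return WallSection(z_lo=0.0, z_hi=0.01, radius=1.0, thickness=thickness,
                       area=area)


class TestMaterialProps:
    def test_table_anchors(self):
        assert tr.material_props_at(35.0, 0.4).d_w == pytest.approx(1.5e-12)
        assert tr.material_props_at(50.0, 0.7).d_w == pytest.approx(2.6e-12)
        assert tr.material_props_at(50.0, 0.7).d_e == pytest.approx(
            2.4e-15, rel=0.02
        )
        p35 = tr.material_props_at(35.0, 0.15)
        assert p35.d_e == pytest.approx(5.5e-16)
        assert p35.c_w_sat == pytest.approx(0.0118)
        assert p35.c_e_sat == pytest.approx(0.0208)

    def test_ethanol_composition_interpolation_monotone(self):
        ds = [tr.material_props_at(35.0, a).d_e for a in (0.15, 0.3, 0.4, 0.55, 0.7)]
        assert np.all(np.diff(ds) > 0)
        # clamped outside the anchor range
        assert tr.material_props_at(35.0, 0.0).d_e == pytest.approx(5.5e-16)
        assert tr.material_props_at(35.0, 1.0).d_e == pytest.approx(8.9e-16)

    def test_ethanol_arrhenius_consistency(self):
        # the 50 degC anchor is derived from the 35 degC abv=0.7 value with
        # a 54 kJ/mol apparent activation energy
        d35 = tr.material_props_at(35.0, 0.7).d_e
        d50 = tr.material_props_at(50.0, 0.7).d_e
        ratio_expected = np.exp(-54e3 / 8.314 * (1 / 323.15 - 1 / 308.15))
        assert d50 / d35 == pytest.approx(ratio_expected, rel=0.01)

    def test_out_of_range_warns_and_flags(self):
        with pytest.warns(UserWarning, match="extrapolated"):
            p = tr.material_props_at(10.0, 0.4)
        assert p.extrapolated
        assert p.d_w > 0

    def test_isotherm_inverse_identity(self):
        p = tr.material_props_at(35.0, 0.4)
        for a in (0.0, 0.3, 1.0):
            assert (a * p.s_w) / p.s_w == pytest.approx(a)


class TestInitializeWalls:
    def test_dry_atmosphere_gives_dry_walls(self):
        secs = [planar_section()]
        (f,) = tr.initialize_walls(secs, 0.0, 20.0)
        assert f["C_w"][0] == 0.0

    def test_reference_humidity_at_35c(self):
        secs = [planar_section()]
        (f,) = tr.initialize_walls(secs, 55.0, 35.0)
        assert f["C_w"][0] == pytest.approx(0.55 * 0.0118 * 1335.0, rel=1e-9)

    @pytest.mark.parametrize("rh", [0.0, 55.0, 100.0])
    def test_no_initial_ethanol(self, rh):
        secs = [planar_section()]
        (f,) = tr.initialize_walls(secs, rh, 20.0)
        assert f["C_e"][0] == 0.0

    def test_invalid_humidity_rejected(self):
        with pytest.raises(ValueError):
            tr.initialize_walls([planar_section()], 120.0, 20.0)


class TestWallOracles:
    def test_steady_slab_flux(self):
        """Steady permeation through a slab matches (a_in-a_out)/(2/k + L/DS)."""
        L = 1e-3
        sec = planar_section(thickness=L)
        opt = tr.SolverOptions(n_nodes=40, h_conductance=1e-2)
        m = tr.WallModel([sec], 35.0, 0.4, opt)
        D, S = m.props.d_w, m.props.s_w
        a_in, a_out = 0.9, 0.1
        dt = L**2 / D / 400
        for _ in range(4000):
            flows = m.step(dt, {"w": a_in, "e": 0.0}, {"w": a_out, "e": 0.0})
        k = m.k_film["w"]
        flow_ref = (a_in - a_out) / (2.0 / k + L / (D * S)) * sec.area
        assert flows["w"][1] == pytest.approx(flow_ref, rel=0.005)
        assert flows["w"][0] == pytest.approx(flows["w"][1], rel=1e-6)

    def test_permeation_time_lag(self):
        """Cumulative permeated mass extrapolates to the L^2/6D intercept."""
        L = 1e-3
        sec = planar_section(thickness=L)
        opt = tr.SolverOptions(n_nodes=40, h_conductance=1e3)
        m = tr.WallModel([sec], 35.0, 0.4, opt)
        D = m.props.d_w
        dt = L**2 / D / 800
        q = t = 0.0
        for _ in range(8000):
            f = m.step(dt, {"w": 1.0, "e": 0.0}, {"w": 0.0, "e": 0.0})
            q += f["w"][1] * dt
            t += dt
        t_lag = t - q / f["w"][1]
        assert t_lag == pytest.approx(L**2 / (6 * D), rel=0.02)

    def test_sleeve_serial_resistance(self):
        """Same-material sleeve reduces the steady flux by l/(l + l_sleeve)."""
        L, Ls = 0.8e-3, 0.2e-3
        sec = planar_section(thickness=L)
        sleeved = tr.apply_sleeve([sec], (0.0, 0.01), Ls)
        opt = tr.SolverOptions(n_nodes=30, n_nodes_sleeve=10, h_conductance=1e3)
        flows = {}
        for tag, sections in [("bare", [sec]), ("sleeved", sleeved)]:
            m = tr.WallModel(sections, 35.0, 0.0, opt)
            dt = (L + Ls) ** 2 / m.props.d_w / 400
            for _ in range(6000):
                f = m.step(dt, {"w": 1.0, "e": 0.0}, {"w": 0.0, "e": 0.0})
            flows[tag] = f["w"][1]
        assert flows["sleeved"] / flows["bare"] == pytest.approx(
            L / (L + Ls), rel=0.01
        )


class TestApplySleeve:
    def test_partial_coverage_splits_area(self):
        sec = WallSection(z_lo=0.0, z_hi=0.1, radius=0.01, thickness=1e-3,
                          area=0.01)
        out = tr.apply_sleeve([sec], (0.0, 0.04), 60e-6)
        covered = sum(s.area for s in out if s.sleeve_thickness > 0)
        assert covered == pytest.approx(0.4 * 0.01, rel=1e-12)
        assert sum(s.area for s in out) == pytest.approx(0.01, rel=1e-12)

    def test_overlapping_sleeves_rejected(self):
        sec = WallSection(z_lo=0.0, z_hi=0.1, radius=0.01, thickness=1e-3,
                          area=0.01)
        once = tr.apply_sleeve([sec], (0.0, 0.1), 60e-6)
        with pytest.raises(ValueError, match="sleeve"):
            tr.apply_sleeve(once, (0.0, 0.05), 60e-6)

    def test_zero_thickness_rejected(self):
        sec = planar_section()
        with pytest.raises(ValueError):
            tr.apply_sleeve([sec], (0.0, 0.01), 0.0)


def miniature_sim(miniature, abv0, t_c, rh, days, **opt_kw):
    fill = initial_inventory(55e-6, 11e-6, 20.0, 101325.0, abv0)
    options = tr.SolverOptions(**opt_kw) if opt_kw else None
    return tr.simulate(miniature, fill, t_c, rh, days, options=options)


class TestSimulate:
    def test_impermeable_walls_nothing_happens(self, miniature):
        sealed = tr.MaterialProps(
            name="sealed", d_w_35=1e-30, d_w_50=1e-30,
            d_e_35_by_abv=((0.15, 1e-32), (0.4, 1e-32), (0.7, 1e-32)),
        )
        fill = initial_inventory(55e-6, 11e-6, 20.0, 101325.0, 0.4)
        res = tr.simulate(miniature, fill, 35.0, 20.0, 10.0, material=sealed,
                          options=tr.SolverOptions(n_sections=3, n_nodes=6))
        assert res.mass_loss_permeation[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.abv, 0.4, atol=1e-9)

    def test_species_conservation_every_step(self, miniature):
        res = miniature_sim(miniature, 0.4, 35.0, 20.0, 8.0,
                            n_sections=5, n_nodes=12)
        for m, sorbed, perm in [
            (res.m_w, res.sorbed_w, res.permeated_w),
            (res.m_e, res.sorbed_e, res.permeated_e),
        ]:
            total = m + sorbed + perm
            np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_concentrations_within_physical_bounds(self, miniature):
        res = miniature_sim(miniature, 0.7, 35.0, 20.0, 5.0,
                            n_sections=4, n_nodes=10)
        props = tr.material_props_at(35.0, 0.7)
        for snap in res.wall_snapshot:
            assert np.all(snap["C_w"] >= -1e-12)
            assert np.all(snap["C_w"] <= props.s_w * (1 + 1e-6))
            assert np.all(snap["C_e"] >= -1e-12)
            assert np.all(snap["C_e"] <= props.s_e * (1 + 1e-6))

    def test_drier_outside_means_faster_loss(self, miniature):
        losses = []
        for rh in (10.0, 40.0, 70.0):
            res = miniature_sim(miniature, 0.0, 35.0, rh, 15.0,
                                n_sections=4, n_nodes=10)
            losses.append(res.mass_loss_permeation[-1])
        assert losses[0] > losses[1] > losses[2]

    def test_quasi_steady_regime_within_days(self, miniature):
        """The mass-loss rate settles to a constant within 3-6 days."""
        res = miniature_sim(miniature, 0.7, 35.0, 20.0, 14.0)
        t, q = res.t_days, res.mass_loss_permeation

        def rate(t0, t1):
            i = (t >= t0) & (t <= t1)
            return np.polyfit(t[i], q[i], 1)[0]

        assert rate(6.0, 8.0) == pytest.approx(rate(11.0, 14.0), rel=0.05)

    def test_abv_rises_in_dry_storage_of_liquor(self, miniature):
        res = miniature_sim(miniature, 0.7, 35.0, 20.0, 10.0,
                            n_sections=4, n_nodes=10)
        assert res.abv[-1] > res.abv[0]
        # water dominates the loss; ethanol permeation is lag-limited
        assert res.permeated_w[-1] > 100 * res.permeated_e[-1]

    def test_sleeve_slows_water_loss(self, miniature):
        fill = initial_inventory(55e-6, 11e-6, 20.0, 101325.0, 0.0)
        opt = tr.SolverOptions(n_sections=5, n_nodes=10)
        bare = tr.simulate(miniature, fill, 35.0, 20.0, 20.0, options=opt)
        sleeved = tr.simulate(
            miniature, fill, 35.0, 20.0, 20.0, options=opt,
            sleeve=((8e-3, 72e-3), 60e-6),
        )
        assert sleeved.mass_loss_permeation[-1] < bare.mass_loss_permeation[-1]

    def test_ethanol_lag_times_by_temperature(self):
        """Lag L^2/6D for 0.8 mm walls: years, longer at 35 than 50 degC."""
        L = 0.8e-3
        lag35 = L**2 / (6 * tr.material_props_at(35.0, 0.7).d_e) / 86400 / 365.25
        lag50 = L**2 / (6 * tr.material_props_at(50.0, 0.7).d_e) / 86400 / 365.25
        assert lag35 == pytest.approx(3.8, rel=0.1)
        assert lag50 == pytest.approx(1.4, rel=0.1)
        assert lag35 > lag50
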