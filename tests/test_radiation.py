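"""Net-radiation corrections: geometry oracles and identity limits."""

import numpy as np
import pytest

from ebcflux import radiation as rad
from ebcflux import synthetic
from ebcflux.constants import STEFAN_BOLTZMANN
from ebcflux.core import Grid


class TestIncidenceAngle:
    def test_flat_terrain_identity(self):
        zen = np.linspace(0.0, np.pi / 2, 20)
        az = np.linspace(0.0, 2 * np.pi, 20)
        psi = rad.incidence_angle(zen, az, slope_deg=0.0, aspect_deg=123.0)
        np.testing.assert_allclose(psi, zen, atol=1e-12)

    def test_sun_normal_to_slope(self):
        # slope 30 deg facing south; sun at zenith 30 deg due south
        psi = rad.incidence_angle(np.array([np.deg2rad(30)]),
                                  np.array([np.pi]), 30.0, 180.0)
        assert psi[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_3d_dot_product(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            zen = rng.uniform(0, np.pi / 2)
            az = rng.uniform(0, 2 * np.pi)
            beta = rng.uniform(0, 60)
            aspect = rng.uniform(0, 360)
            sun = np.array([np.sin(zen) * np.sin(az), np.sin(zen) * np.cos(az),
                            np.cos(zen)])
            b, a = np.deg2rad(beta), np.deg2rad(aspect)
            normal = np.array([np.sin(b) * np.sin(a), np.sin(b) * np.cos(a),
                               np.cos(b)])
            expected = np.arccos(np.clip(sun @ normal, -1, 1))
            psi = rad.incidence_angle(np.array([zen]), np.array([az]), beta, aspect)
            assert psi[0] == pytest.approx(expected, abs=1e-10)


class TestSlopeCorrection:
    def test_identity_when_psi_equals_zenith_and_no_albedo(self):
        sw = rad.slope_correct_sw(np.array([500.0]), np.array([0.7]),
                                  np.array([0.5]), np.array([0.5]),
                                  np.array([0.0]))
        assert sw[0] == pytest.approx(500.0, rel=1e-12)

    def test_hand_value(self):
        # 500 * exp(-0.7(0.3491^2 - 0.5236^2)) * (1 - 0.2 sin^2(0.1745))
        sw = rad.slope_correct_sw(np.array([500.0]), np.array([0.7]),
                                  np.array([np.deg2rad(30)]),
                                  np.array([np.deg2rad(20)]), np.array([0.2]))
        assert sw[0] == pytest.approx(552.9, abs=0.1)

    def test_divisor_variant_switch(self):
        args = (np.array([500.0]), np.array([0.7]), np.array([np.deg2rad(30)]),
                np.array([np.deg2rad(20)]), np.array([0.2]))
        mul = rad.slope_correct_sw(*args, albedo_term="multiply")[0]
        div = rad.slope_correct_sw(*args, albedo_term="divide")[0]
        fac = 1 - 0.2 * np.sin(np.deg2rad(20) / 2) ** 2
        assert div == pytest.approx(mul / fac ** 2, rel=1e-12)

    def test_oblique_sun_reduces_exponential_factor(self):
        kt, zen = np.array([0.6]), np.array([np.deg2rad(30)])
        steeper = rad.slope_correct_sw(np.array([500.0]), kt, zen,
                                       np.array([np.deg2rad(50)]), np.array([0.0]))
        assert steeper[0] < 500.0

    def test_night_passthrough(self):
        sw = rad.slope_correct_sw(np.array([0.0]), np.array([np.nan]),
                                  np.array([np.deg2rad(100)]),
                                  np.array([np.deg2rad(100)]), np.array([0.2]))
        assert sw[0] == 0.0


class TestHorizon:
    def test_flat_dem_zero_horizon(self):
        hp = rad.horizon_from_dem(synthetic.generate_dem("flat", size=101))
        assert hp.elevations.max() == 0.0

    def test_single_peak_due_east(self):
        dem = synthetic.generate_dem("single_peak", peak_height=100.0,
                                     peak_distance=1000.0, peak_azimuth=90.0)
        hp = rad.horizon_from_dem(dem)
        expected = np.rad2deg(np.arctan(100.0 / 1000.0))
        assert hp.elevation_at(90.0) == pytest.approx(expected, abs=0.1)
        assert hp.elevation_at(270.0) == 0.0

    def test_periodicity(self):
        dem = synthetic.generate_dem("single_peak", peak_azimuth=0.0)
        hp = rad.horizon_from_dem(dem)
        assert hp.elevation_at(0.0) == hp.elevation_at(360.0)

    def test_ridge_symmetry(self):
        dem = synthetic.generate_dem("ridge", peak_azimuth=90.0,
                                     ridge_azimuth=0.0, peak_distance=1500.0)
        hp = rad.horizon_from_dem(dem)
        assert hp.elevation_at(80.0) == pytest.approx(hp.elevation_at(100.0), abs=0.05)

    def test_site_outside_grid_rejected(self):
        dem = synthetic.generate_dem("flat", size=11)
        with pytest.raises(ValueError):
            rad.horizon_from_dem(dem, site_xy=(1e6, 0.0))


class TestShadowRule:
    def _horizon(self, elev=10.0):
        return rad.HorizonProfile(np.arange(0.0, 360.0), np.full(360, elev))

    def test_sun_above_horizon_unchanged(self):
        sw = rad.shadow_correct_sw(np.array([200.0]), np.array([0.4]),
                                   np.array([np.deg2rad(20)]), np.array([np.pi]),
                                   self._horizon(10.0))
        assert sw[0] == 200.0

    def test_blocked_sun_keeps_only_diffuse(self):
        sw = rad.shadow_correct_sw(np.array([200.0]), np.array([0.4]),
                                   np.array([np.deg2rad(5)]), np.array([np.pi]),
                                   self._horizon(10.0))
        assert sw[0] == pytest.approx(80.0)

    def test_fully_diffuse_sky_unaffected(self):
        sw = rad.shadow_correct_sw(np.array([200.0]), np.array([1.0]),
                                   np.array([np.deg2rad(5)]), np.array([np.pi]),
                                   self._horizon(10.0))
        assert sw[0] == 200.0


class TestTowerSolidAngle:
    def test_vanishes_at_large_distance(self):
        g = rad.TowerGeometry(0.6, 3.0, 1e6, 170.0)
        assert rad.tower_disturbance_fraction(g) < 1e-10

    def test_against_monte_carlo_on_random_geometries(self):
        # exact rectangular solid angle vs 1e6-point area-sampling estimate
        rng = np.random.default_rng(0)
        n = 10 ** 6
        for _ in range(20):
            w = rng.uniform(0.2, 2.0)
            h = rng.uniform(0.5, 6.0)
            d = rng.uniform(1.0, 8.0)
            fov = rng.uniform(120.0, 175.0)
            exact = rad.tower_disturbance_fraction(rad.TowerGeometry(w, h, d, fov))
            u = rng.uniform(-w / 2, w / 2, n)
            v = rng.uniform(-h, 0.0, n)
            r3 = (u * u + v * v + d * d) ** 1.5
            contrib = d / r3
            omega_mc = w * h * contrib.mean()
            se = w * h * contrib.std() / np.sqrt(n)
            fov_omega = 2 * np.pi * (1 - np.cos(np.deg2rad(fov) / 2))
            mc = omega_mc / fov_omega
            assert abs(exact - mc) < max(0.01 * mc, 3 * se / fov_omega)

    def test_monotonicity_in_geometry(self):
        base = rad.TowerGeometry(0.6, 3.0, 4.0, 170.0)
        f0 = rad.tower_disturbance_fraction(base)
        assert rad.tower_disturbance_fraction(rad.TowerGeometry(1.2, 3.0, 4.0, 170.0)) > f0
        assert rad.tower_disturbance_fraction(rad.TowerGeometry(0.6, 6.0, 4.0, 170.0)) > f0
        assert rad.tower_disturbance_fraction(rad.TowerGeometry(0.6, 3.0, 8.0, 170.0)) < f0

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            rad.TowerGeometry(0.0, 3.0, 4.0, 170.0)


class TestTowerShortwave:
    def test_zero_disturbance_identity(self):
        sw, bad = rad.tower_correct_sw(np.array([75.0]), np.array([500.0]), 0.0, 0.2)
        assert sw[0] == 75.0 and not bad[0]

    def test_fixed_point_when_ground_matches_tower(self):
        sw, _ = rad.tower_correct_sw(np.array([100.0]), np.array([500.0]), 0.3, 0.2)
        assert sw[0] == pytest.approx(100.0, rel=1e-12)   # ALB_FoV = 0.2 = ALB_t

    def test_hand_inversion(self):
        sw, _ = rad.tower_correct_sw(np.array([75.0]), np.array([500.0]), 0.05, 0.2)
        alb_g = (0.15 - 0.05 * 0.2) / 0.95
        assert alb_g == pytest.approx(0.14737, abs=1e-5)
        assert sw[0] == pytest.approx(500 * alb_g, rel=1e-9)
        assert sw[0] == pytest.approx(73.68, abs=0.01)

    def test_nonphysical_inversion_flagged_passthrough(self):
        sw, bad = rad.tower_correct_sw(np.array([5.0]), np.array([500.0]), 0.2, 0.2)
        assert bad[0] and sw[0] == 5.0


class TestTowerLongwave:
    def test_zero_disturbance_identity(self):
        lw, bad = rad.tower_correct_lw(np.array([420.0]), np.array([350.0]),
                                       np.array([20.0]), 0.0, 0.3,
                                       denominator="standard")
        assert lw[0] == pytest.approx(420.0, rel=1e-12) and not bad[0]

    def test_standard_denominator_hand_value(self):
        # T_surf = 293.15 + 4 (day); eps_fov = (420-350)/(sigma T^4 - 350)
        lw, bad = rad.tower_correct_lw(np.array([420.0]), np.array([350.0]),
                                       np.array([20.0]), 0.05, 0.3,
                                       day=np.array([True]),
                                       denominator="standard")
        t4 = STEFAN_BOLTZMANN * 297.15 ** 4
        eps_fov = (420.0 - 350.0) / (t4 - 350.0)
        eps_g = (eps_fov - 0.05 * 0.3) / 0.95
        assert not bad[0]
        assert lw[0] == pytest.approx(420.0 * eps_g / eps_fov, rel=1e-10)

    def test_literal_denominator_hand_value_or_flag(self):
        # literal reading: denominator sigma T^4 - LW_OUT; for these typical
        # values the retrieved emissivity exceeds 1.5 -> flagged passthrough
        lw, bad = rad.tower_correct_lw(np.array([420.0]), np.array([350.0]),
                                       np.array([20.0]), 0.05, 0.3,
                                       day=np.array([True]),
                                       denominator="literal")
        t4 = STEFAN_BOLTZMANN * 297.15 ** 4
        eps_fov = (420.0 - 350.0) / (t4 - 420.0)
        assert eps_fov > 1.5
        assert bad[0] and lw[0] == 420.0

    def test_night_offset_is_2k(self):
        lw_day, _ = rad.tower_correct_lw(np.array([380.0]), np.array([330.0]),
                                         np.array([10.0]), 0.05, 0.3,
                                         day=np.array([True]), denominator="standard")
        lw_night, _ = rad.tower_correct_lw(np.array([380.0]), np.array([330.0]),
                                           np.array([10.0]), 0.05, 0.3,
                                           day=np.array([False]), denominator="standard")
        assert lw_day[0] != lw_night[0]

    def test_fov_emissivity_equal_tower_fixed_point(self):
        # choose LW_OUT so that eps_fov == eps_t = 0.3 (standard form)
        ta = 20.0
        t4 = STEFAN_BOLTZMANN * (ta + 273.15 + 4) ** 4
        lw_in = 330.0
        lw_out = lw_in + 0.3 * (t4 - lw_in)
        lw, _ = rad.tower_correct_lw(np.array([lw_out]), np.array([lw_in]),
                                     np.array([ta]), 0.05, 0.3,
                                     day=np.array([True]), denominator="standard")
        assert lw[0] == pytest.approx(lw_out, rel=1e-10)


class TestFovMismatch:
    def test_homogeneous_raster_unity_ratios(self):
        sr, lst, fp, disc = synthetic.generate_rasters("homogeneous")
        r_sw, r_lw = rad.fov_mismatch_ratios(rad.FovWeights(fp, disc), sr, lst)
        assert r_sw == pytest.approx(1.0) and r_lw == pytest.approx(1.0)

    def test_two_patch_disjoint_regions_ratio_two(self):
        sr, lst, fp, disc = synthetic.generate_rasters(
            "two_patch", values=(1.0, 2.0), disc_center=(900.0, 0.0),
            disc_radius=300.0, fp_center=(-900.0, 0.0), fp_sigma=250.0)
        w = rad.FovWeights(fp, disc)
        r_sw, _ = rad.fov_mismatch_ratios(w, sr, lst)
        assert r_sw == pytest.approx(2.0)
        assert rad.fov_overlap_fraction(w) < 0.6

    def test_gradient_matches_brute_force_weighted_means(self):
        sr, lst, fp, disc = synthetic.generate_rasters(
            "gradient", disc_center=(500.0, 200.0), fp_center=(-400.0, 0.0))
        w = rad.FovWeights(fp, disc)
        r_sw, r_lw = rad.fov_mismatch_ratios(w, sr, lst)
        exp_sw = ((sr.data * disc.data).sum() / disc.data.sum()) \
            / ((sr.data * fp.data).sum() / fp.data.sum())
        exp_lw = ((lst.data * disc.data).sum() / disc.data.sum()) \
            / ((lst.data * fp.data).sum() / fp.data.sum())
        assert r_sw == pytest.approx(exp_sw, rel=1e-12)
        assert r_lw == pytest.approx(exp_lw, rel=1e-12)

    def test_insufficient_valid_pixels_undefined(self):
        sr, lst, fp, disc = synthetic.generate_rasters("homogeneous")
        sr.data[:] = np.nan
        r_sw, _ = rad.fov_mismatch_ratios(rad.FovWeights(fp, disc), sr, lst)
        assert np.isnan(r_sw)


class TestAssembly:
    def test_no_corrections_netrad_only(self, two_day_table, site_meta):
        out = rad.assemble_netrad(two_day_table, site_meta, ())
        assert list(out.variants.columns) == ["NETRAD"]

    def test_identity_when_drivers_vanish(self, two_day_table, site_meta):
        # flat site: slope correction inactive; flat horizon: no shadowing
        hp = rad.HorizonProfile(np.arange(0.0, 360.0), np.zeros(360))
        out = rad.assemble_netrad(two_day_table, site_meta, ("slope", "shadow"),
                                  horizon=hp)
        np.testing.assert_allclose(out.variants["NETRAD_SLOPE"],
                                   out.variants["NETRAD"])
        np.testing.assert_allclose(out.variants["NETRAD_SHADOW"],
                                   out.variants["NETRAD"])

    def test_fov_homogeneous_identity(self, two_day_table, site_meta):
        sr, lst, fp, disc = synthetic.generate_rasters(
            "homogeneous", disc_center=(900.0, 0.0), disc_radius=300.0,
            fp_center=(-900.0, 0.0), fp_sigma=250.0)
        out = rad.assemble_netrad(two_day_table, site_meta, ("fov",),
                                  fov_weights=rad.FovWeights(fp, disc),
                                  sr=sr, lst=lst)
        np.testing.assert_allclose(out.variants["NETRAD_FOV"],
                                   out.variants["NETRAD"])

    def test_corrections_never_negative_sw(self, two_day_table, site_meta):
        meta = synthetic.default_site_meta(slope=10.0, aspect=180.0)
        out = rad.assemble_netrad(two_day_table, meta, ("slope",))
        assert (out.variants["SW_IN_SLOPE"].dropna() >= 0).all()
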