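"""Generators: analytic oracles, phantom construction, wrap, noise, cohorts."""

import numpy as np
import pytest
from scipy import stats as sps

from rhvort import (
    AnalyticFlowParams,
    CardiacWaveformParams,
    CohortSimParams,
    DiskProbe,
    GridSpec,
    add_phase_noise,
    make_analytic_field,
    make_cardiac_phantom,
    make_magnitude,
    make_smooth_blob_field,
    simulate_cohort,
    wrap_velocities,
)
from rhvort.synthetic import jet_effective_area_mm2


class TestAnalyticFields:
    def test_unknown_kind_rejected(self, small_grid):
        with pytest.raises(ValueError, match="unknown analytic flow kind"):
            AnalyticFlowParams("vortex_sheet")

    def test_tube_radius_exceeding_grid_rejected(self, small_grid):
        params = AnalyticFlowParams("poiseuille_tube", v_max_cm_s=50.0, tube_radius_mm=200.0)
        with pytest.raises(ValueError, match="exceeds grid extent"):
            make_analytic_field(params, small_grid)

    def test_uniform_field_is_constant(self, small_grid):
        f = make_analytic_field(
            AnalyticFlowParams("uniform", velocity_cm_s=(10.0, -5.0, 3.0)), small_grid
        )
        assert np.all(f.values[0] == 10.0)
        assert np.all(f.values[1] == -5.0)
        assert np.all(f.values[2] == 3.0)

    def test_solid_body_velocity_is_omega_cross_r(self, small_grid):
        om = np.array([1.0, 2.0, 3.0])
        om /= np.linalg.norm(om)
        f = make_analytic_field(
            AnalyticFlowParams("solid_body", angular_velocity_s=tuple(om * 4.0)), small_grid
        )
        X, Y, Z = small_grid.meshgrid_mm()
        c = small_grid.center_mm()
        r = np.stack([X - c[0], Y - c[1], Z - c[2]])  # mm
        expected = np.cross(om * 4.0, np.moveaxis(r, 0, -1)).transpose(3, 0, 1, 2) * 0.1
        np.testing.assert_allclose(f.values[..., 0], expected, atol=1e-12)

    def test_poiseuille_profile(self):
        grid = GridSpec((24, 24, 10), (1.0, 1.0, 2.0))
        f = make_analytic_field(
            AnalyticFlowParams("poiseuille_tube", v_max_cm_s=60.0, tube_radius_mm=8.0), grid
        )
        X, Y, _ = grid.meshgrid_mm()
        c = grid.center_mm()
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2
        vz = f.values[2, ..., 0]
        inside = r2 <= 64.0
        np.testing.assert_allclose(vz[inside], 60.0 * (1 - r2[inside] / 64.0), atol=1e-12)
        assert np.all(vz[~inside] == 0.0)
        assert np.all(f.values[:2] == 0.0)

    def test_hill_vortex_is_divergence_free_and_continuous(self):
        # numeric sanity on the closed-form field: interior/exterior match at
        # the sphere and div(v) vanishes away from the surface
        grid = GridSpec((40, 40, 40), (1.0, 1.0, 1.0))
        f = make_analytic_field(
            AnalyticFlowParams("hill_vortex", v_max_cm_s=30.0, tube_radius_mm=12.0), grid
        )
        v = f.values[..., 0]
        div = sum(np.gradient(v[i], grid.spacing_mm[i], axis=i) for i in range(3))
        X, Y, Z = grid.meshgrid_mm()
        c = grid.center_mm()
        r = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        away = np.abs(r - 12.0) > 2.0  # differencing straddles the surface otherwise
        interior = away & (r > 1.0) & (r < 18.0)
        assert np.abs(div[interior]).max() < 1.5  # cm/s per mm, vs ~30 cm/s scale


class TestLambOseen:
    def test_integrated_vorticity_magnitude_equals_circulation(self):
        """Volume-integrated |curl v| of a Lamb-Oseen tube is Gamma * L.

        Frozen oracle: brute-force integration of the analytic vorticity
        profile 2*pi*int r * Gamma/(pi rc^2) exp(-r^2/rc^2) dr -> Gamma as
        the plane extent -> inf; at 4 core radii of extent the tail is
        below 1e-7 relative.
        """
        from rhvort import compute_vorticity

        grid = GridSpec((40, 40, 16), (2.0, 2.0, 2.0))
        gamma = 0.002  # m^2/s
        f = make_analytic_field(
            AnalyticFlowParams("lamb_oseen_tube", circulation_m2_s=gamma, core_radius_mm=8.0),
            grid,
        )
        om = compute_vorticity(f, 0)
        integral_m3_s = om.magnitude().sum() * grid.voxel_volume_mm3 * 1e-9
        L = grid.shape[2] * grid.spacing_mm[2] * 1e-3
        assert integral_m3_s == pytest.approx(gamma * L, rel=0.01)

    def test_pointwise_profile_matches_analytic(self):
        from rhvort import compute_vorticity

        grid = GridSpec((64, 64, 8), (1.0, 1.0, 2.0))
        gamma, rc_mm = 0.002, 8.0  # core resolved by 8 voxels
        f = make_analytic_field(
            AnalyticFlowParams("lamb_oseen_tube", circulation_m2_s=gamma, core_radius_mm=rc_mm),
            grid,
        )
        om = compute_vorticity(f, 0)
        X, Y, _ = grid.meshgrid_mm()
        c = grid.center_mm()
        r = np.hypot(X - c[0], Y - c[1])
        peak = gamma / (np.pi * (rc_mm * 1e-3) ** 2)
        analytic = peak * np.exp(-((r / rc_mm) ** 2))
        mid = om.magnitude()[:, :, 4]
        core = r[:, :, 4] <= 2 * rc_mm
        assert np.abs(mid[core] - analytic[:, :, 4][core]).max() < 0.01 * peak


class TestWrap:
    def test_wrap_maps_into_range_examples(self, small_grid):
        f = make_analytic_field(
            AnalyticFlowParams("uniform", velocity_cm_s=(130.0, 99.0, 0.0)), small_grid
        )
        w = wrap_velocities(f, 100.0)
        assert np.all(w.values[0] == -70.0)  # 130 wraps past +venc
        assert np.all(w.values[1] == 99.0)  # inside the range, untouched

    def test_wrap_is_idempotent(self, small_grid):
        f = make_smooth_blob_field(small_grid, venc_cm_s=100.0, seed=3)
        once = wrap_velocities(f, 100.0)
        twice = wrap_velocities(once, 100.0)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_wrap_range_property(self, small_grid):
        for seed in range(5):
            f = make_smooth_blob_field(small_grid, venc_cm_s=100.0, peak_fraction=2.7, seed=seed)
            w = wrap_velocities(f, 100.0)
            assert np.all(w.values >= -100.0) and np.all(w.values < 100.0)

    def test_wrapped_offset_is_exact_float_multiple_of_two_venc(self, small_grid):
        f = make_smooth_blob_field(small_grid, venc_cm_s=100.0, peak_fraction=1.5, seed=11)
        w = wrap_velocities(f, 100.0)
        k = np.round((f.values - w.values) / 200.0)
        np.testing.assert_array_equal(w.values + 200.0 * k, f.values)


class TestPhaseNoise:
    def test_sigma_zero_is_identity_and_seed_reproducible(self, solid_body_field):
        same = add_phase_noise(solid_body_field, 0.0, seed=1)
        np.testing.assert_array_equal(same.values, solid_body_field.values)
        a = add_phase_noise(solid_body_field, 5.0, seed=42)
        b = add_phase_noise(solid_body_field, 5.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_sample_sd_matches_request(self):
        grid = GridSpec((24, 24, 24), (2.0, 2.0, 2.0), n_timesteps=2)
        f = make_analytic_field(AnalyticFlowParams("uniform", velocity_cm_s=(0, 0, 0)), grid)
        noisy = add_phase_noise(f, 5.0, seed=7)
        sd = (noisy.values - f.values).std()
        assert sd == pytest.approx(5.0, rel=0.02)


class TestMagnitude:
    def test_noise_free_image_reproduces_mask(self, solid_body_field):
        grid = solid_body_field.grid
        rng = np.random.default_rng(0)
        mask = rng.random(grid.shape) > 0.5
        mag = make_magnitude(solid_body_field, mask, 500.0, 0.0, seed=0)
        np.testing.assert_array_equal(mag.values[..., 0] > 0, mask)
        assert mag.max_intensity == 500.0

    def test_background_falls_below_three_percent_threshold(self, solid_body_field):
        grid = solid_body_field.grid
        mask = np.zeros(grid.shape, dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        mag = make_magnitude(solid_body_field, mask, 500.0, 10.0, seed=1, noise_sd=1.0)
        thr = 0.03 * mag.max_intensity
        background = ~np.repeat(mask[..., None], grid.n_timesteps, axis=-1)
        assert np.all(mag.values[background] < thr)

    def test_same_seed_identical(self, solid_body_field):
        mask = np.zeros(solid_body_field.grid.shape, dtype=bool)
        mask[2:6] = True
        a = make_magnitude(solid_body_field, mask, 500.0, 10.0, seed=9, noise_sd=3.0)
        b = make_magnitude(solid_body_field, mask, 500.0, 10.0, seed=9, noise_sd=3.0)
        np.testing.assert_array_equal(a.values, b.values)


class TestCardiacPhantom:
    def test_flowrate_argmax_at_E_for_normal_filling(self, normal_phantom):
        params, _, q, _ = normal_phantom
        dias = q.times_ms > 250.0
        t_star = q.times_ms[dias][np.argmax(q.values_ml_s[dias])]
        assert t_star == 400.0

    def test_A_dominant_waveform_has_global_A_and_local_E_peak(self, rvdd_phantom):
        params, _, q, _ = rvdd_phantom
        dias = q.times_ms > 250.0
        td, qd = q.times_ms[dias], q.values_ml_s[dias]
        assert td[np.argmax(qd)] == 800.0
        i_e = np.argmin(np.abs(td - 400.0))
        assert qd[i_e] > qd[i_e - 1] and qd[i_e] > qd[i_e + 1]  # secondary local peak

    def test_lv_dvdt_peaks_delayed_by_lv_delay(self, phantom_grid, valve_disk):
        from rhvort import dvdt

        params = CardiacWaveformParams(lv_delay_ms=50.0)
        _, _, vol = make_cardiac_phantom(params, phantom_grid, valve_disk)
        d = dvdt(vol)
        dias = d.times_ms > 300.0
        t_peak = d.times_ms[dias][np.argmax(d.values_ml_s[dias])]
        assert abs(t_peak - (params.t_E_ms + 50.0)) <= vol.uniform_dt_ms

    def test_negative_volume_rejected(self, phantom_grid, valve_disk):
        params = CardiacWaveformParams(
            peak_systolic_Q_ml_s=3000.0, lv_baseline_volume_ml=50.0
        )
        with pytest.raises(ValueError, match="negative LV volume"):
            make_cardiac_phantom(params, phantom_grid, valve_disk)

    def test_disk_outside_grid_rejected(self, phantom_grid):
        disk = DiskProbe((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), 15.0)
        with pytest.raises(ValueError, match="outside the grid"):
            make_cardiac_phantom(CardiacWaveformParams(), phantom_grid, disk)

    def test_effective_area_matches_numeric_profile_integral(self):
        # frozen quadrature oracle for the plug + cosine-taper profile
        from rhvort.synthetic import _jet_profile

        R = 15.0
        r = np.linspace(0, R, 20001)
        numeric = np.trapezoid(2 * np.pi * r * _jet_profile(r, R), r)
        assert jet_effective_area_mm2(R) == pytest.approx(numeric, rel=1e-6)


class TestCohortSimulation:
    def test_same_seed_identical_and_truncation_respected(self):
        a = simulate_cohort(CohortSimParams(seed=5))
        b = simulate_cohort(CohortSimParams(seed=5))
        va = [s.metrics[("RA", "SS", 0.04)] for s in a]
        vb = [s.metrics[("RA", "SS", 0.04)] for s in b]
        assert va == vb
        assert min(va) >= 0.0
        assert [s.group for s in a].count("control") == 14

    def test_tiny_sd_collapses_to_group_means(self):
        p = CohortSimParams(control_sd=1e-9, rvdd_sd=1e-9, seed=1)
        vals = {s.group: s.metrics[("RA", "SS", 0.04)] for s in simulate_cohort(p)}
        assert vals["control"] == pytest.approx(709.0, abs=1e-5)
        assert vals["rvdd"] == pytest.approx(408.0, abs=1e-5)

    def test_large_sample_means_match_truncated_normal_moments(self):
        """Resampling negatives makes the draws truncated normal; the sample
        means must match scipy.truncnorm moments (not the raw means)."""
        p = CohortSimParams(n_control=1000, n_rvdd=1000, seed=17)
        subj = simulate_cohort(p)
        for group, mu, sd in (("control", 709.0, 325.0), ("rvdd", 408.0, 303.0)):
            vals = np.array([s.metrics[("RA", "SS", 0.04)] for s in subj if s.group == group])
            expected = sps.truncnorm.mean(-mu / sd, np.inf, loc=mu, scale=sd)
            se = sps.truncnorm.std(-mu / sd, np.inf, loc=mu, scale=sd) / np.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 3 * se
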