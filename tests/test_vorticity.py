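"""Curl, thresholding, oriented-box integration and scaling schemes."""

import numpy as np
import pytest

from rhvort import (
    AnalyticFlowParams,
    GridSpec,
    OrientedBoxROI,
    ThresholdScheme,
    VorticityField,
    apply_scheme,
    compute_vorticity,
    integrate_vorticity,
    make_analytic_field,
    roi_from_landmarks,
    scale_threshold,
    subject_metric,
    threshold_vorticity,
)


def _axis_box(grid, center=None, half=None, label="RH"):
    center = tuple(grid.center_mm()) if center is None else center
    if half is None:
        half = tuple(0.5 * (grid.shape[a] - 1) * grid.spacing_mm[a] + 0.6 for a in range(3))
    return OrientedBoxROI(center, ((1, 0, 0), (0, 1, 0), (0, 0, 1)), half, label=label)


class TestComputeVorticity:
    def test_uniform_flow_has_zero_curl(self, small_grid):
        f = make_analytic_field(
            AnalyticFlowParams("uniform", velocity_cm_s=(25.0, -10.0, 5.0)), small_grid
        )
        om = compute_vorticity(f, 0)
        assert np.abs(om.vectors).max() < 1e-12

    def test_solid_body_curl_is_twice_omega(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        interior = om.vectors[:, 1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior[2], 10.0, rtol=1e-6)
        assert np.abs(interior[:2]).max() < 1e-9

    def test_anisotropic_spacing_is_honoured(self, aniso_grid):
        """A shear flow v_x = c * z has curl (0, c, 0) regardless of dz."""
        X, Y, Z = aniso_grid.meshgrid_mm()
        vals = np.zeros((3,) + aniso_grid.shape + (aniso_grid.n_timesteps,))
        c = 2.0  # s^-1: v_x [cm/s] = 0.1 * c * z[mm]
        vals[0] = (0.1 * c * Z)[..., None]
        from rhvort import VelocityField4D

        f = VelocityField4D(values=vals, grid=aniso_grid, venc_cm_s=200.0)
        om = compute_vorticity(f, 0)
        np.testing.assert_allclose(om.vectors[1], c, rtol=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            GridSpec((1, 8, 8), (2.0, 2.0, 2.0))


class TestThreshold:
    def _field_with_magnitudes(self, grid, mags):
        vecs = np.zeros((3,) + grid.shape)
        flat = vecs[2].ravel()
        flat[: len(mags)] = mags
        vecs[2] = flat.reshape(grid.shape)
        return VorticityField(vectors=vecs, grid=grid, timestep=0)

    def test_strict_inequality_keeps_ties(self, small_grid):
        om = self._field_with_magnitudes(small_grid, [0.01, 0.03, 0.04, 0.05])
        out = threshold_vorticity(om, 0.04)
        survived = sorted(out.vectors[2].ravel()[out.vectors[2].ravel() > 0])
        assert survived == [0.04, 0.05]

    def test_tau_zero_is_identity_and_huge_tau_zeroes_all(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        np.testing.assert_array_equal(threshold_vorticity(om, 0.0).vectors, om.vectors)
        assert np.all(threshold_vorticity(om, 1e9).vectors == 0.0)

    def test_integral_monotone_non_increasing_in_tau(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        box = _axis_box(solid_body_field.grid)
        vals = [
            integrate_vorticity(threshold_vorticity(om, tau), box).value
            for tau in (0.0, 2.0, 5.0, 8.0, 10.0, 12.0)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestScaleThreshold:
    def test_identity_and_proportionality(self):
        assert scale_threshold(0.04, 2.4, 2.4) == 0.04
        assert scale_threshold(0.04, 4.8, 2.4) == pytest.approx(0.08)
        assert scale_threshold(0.04, 2.5, 2.4) == pytest.approx(0.0416666667)

    def test_non_positive_ci_rejected(self):
        with pytest.raises(ValueError):
            scale_threshold(0.04, -1.0, 2.4)
        with pytest.raises(ValueError):
            scale_threshold(0.04, 2.4, 0.0)


class TestIntegrate:
    def test_zero_field_integrates_to_zero(self, small_grid):
        om = VorticityField(np.zeros((3,) + small_grid.shape), small_grid, 0)
        assert integrate_vorticity(om, _axis_box(small_grid)).value == 0.0

    def test_single_voxel_arithmetic(self):
        grid = GridSpec((8, 8, 8), (2.0, 2.0, 3.0))  # voxel volume 12 mm^3
        vecs = np.zeros((3,) + grid.shape)
        vecs[2, 4, 4, 4] = 2.0  # |omega| = 2 s^-1
        om = VorticityField(vecs, grid, 0)
        center = (
            grid.origin_mm[0] + 4 * 2.0,
            grid.origin_mm[1] + 4 * 2.0,
            grid.origin_mm[2] + 4 * 3.0,
        )
        box = OrientedBoxROI(center, ((1, 0, 0), (0, 1, 0), (0, 0, 1)), (1.0, 1.0, 1.4))
        assert integrate_vorticity(om, box).value == pytest.approx(24.0)

    def test_lamb_oseen_circulation_inside_box(self):
        grid = GridSpec((40, 40, 16), (2.0, 2.0, 2.0))
        gamma = 0.002
        f = make_analytic_field(
            AnalyticFlowParams("lamb_oseen_tube", circulation_m2_s=gamma, core_radius_mm=8.0),
            grid,
        )
        om = compute_vorticity(f, 0)
        value = integrate_vorticity(om, _axis_box(grid)).value * 1e-9  # mm^3/s -> m^3/s
        L = grid.shape[2] * grid.spacing_mm[2] * 1e-3
        assert value == pytest.approx(gamma * L, rel=0.01)

    def test_empty_intersection_warns_and_returns_zero(self, small_grid):
        om = VorticityField(np.ones((3,) + small_grid.shape), small_grid, 0)
        far = OrientedBoxROI((1e4, 1e4, 1e4), ((1, 0, 0), (0, 1, 0), (0, 0, 1)), (1, 1, 1))
        with pytest.warns(UserWarning, match="does not intersect"):
            out = integrate_vorticity(om, far)
        assert out.value == 0.0 and out.empty_intersection

    def test_additivity_over_disjoint_rois(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        grid = solid_body_field.grid
        c = grid.center_mm()
        axes = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        left = OrientedBoxROI((c[0] - 6.0, c[1], c[2]), axes, (6.0, 10.0, 10.0))
        right = OrientedBoxROI((c[0] + 6.0, c[1], c[2]), axes, (6.0, 10.0, 10.0))
        union = OrientedBoxROI((c[0], c[1], c[2]), axes, (12.0, 10.0, 10.0))
        v = integrate_vorticity(om, left).value + integrate_vorticity(om, right).value
        assert v == pytest.approx(integrate_vorticity(om, union).value, rel=1e-12)

    def test_face_perturbation_invariance_with_buffered_support(self):
        """Thresholding creates a vorticity-free buffer: moving any box face
        by one voxel must not change the integral at all."""
        grid = GridSpec((24, 24, 24), (2.0, 2.0, 2.0))
        vecs = np.zeros((3,) + grid.shape)
        vecs[2, 8:16, 8:16, 8:16] = 1.0  # compact supra-threshold support
        vecs[2, 4, 4, 4] = 0.01  # sub-threshold clutter near the face
        om = threshold_vorticity(VorticityField(vecs, grid, 0), 0.5)
        c = grid.center_mm()
        axes = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        base_half = (12.0, 12.0, 12.0)
        ref = integrate_vorticity(om, OrientedBoxROI(tuple(c), axes, base_half)).value
        dx = grid.spacing_mm[0]
        for axis in range(3):
            for sign in (-1.0, 1.0):
                # move one face by one voxel: shift center by dx/2, change extent by dx/2
                center = list(c)
                half = list(base_half)
                center[axis] += sign * dx / 2.0
                half[axis] += dx / 2.0
                grown = OrientedBoxROI(tuple(center), axes, tuple(half))
                assert integrate_vorticity(om, grown).value == ref
                half[axis] -= dx
                shrunk = OrientedBoxROI(tuple(center), axes, tuple(half))
                assert integrate_vorticity(om, shrunk).value == ref


class TestSchemes:
    def test_ss_divides_by_ci_and_none_is_identity(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        box = _axis_box(solid_body_field.grid)
        raw = integrate_vorticity(om, box)
        ss = apply_scheme(raw, ThresholdScheme("SS"), ci_subject=2.4)
        assert ss.value == pytest.approx(raw.value / 2.4)
        none = apply_scheme(raw, ThresholdScheme("NONE"), ci_subject=None)
        assert none.value == raw.value

    def test_ss_value_960_ci_2p4_gives_400(self, small_grid):
        from rhvort.vorticity import IntegratedVorticity

        raw = IntegratedVorticity(960.0, "RA", 0.04, ThresholdScheme("NONE"), 0)
        assert apply_scheme(raw, ThresholdScheme("SS"), 2.4).value == pytest.approx(400.0)

    def test_missing_ci_rejected(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        raw = integrate_vorticity(om, _axis_box(solid_body_field.grid))
        with pytest.raises(ValueError, match="cardiac index"):
            apply_scheme(raw, ThresholdScheme("SS"), None)

    def test_ss_ts_composes_ts_thresholding_then_ss_division(self, solid_body_field):
        om = compute_vorticity(solid_body_field, 0)
        box = _axis_box(solid_body_field.grid)
        ci = 3.0
        scheme = ThresholdScheme("SS_TS", tau_ref=5.0, ci_ref=2.4)
        combined = subject_metric(om, box, scheme, ci_subject=ci)
        # run the two steps independently
        tau = scale_threshold(5.0, ci, 2.4)
        manual = integrate_vorticity(threshold_vorticity(om, tau), box).value / ci
        assert combined.value == pytest.approx(manual, rel=1e-12)
        assert combined.threshold_used == pytest.approx(tau)

    def test_identical_ci_makes_all_schemes_rank_alike(self, solid_body_field):
        rng = np.random.default_rng(0)
        om = compute_vorticity(solid_body_field, 0)
        box = _axis_box(solid_body_field.grid)
        scales = rng.uniform(0.5, 2.0, size=5)
        ranks = {}
        for name in ("NONE", "SS", "TS"):
            scheme = ThresholdScheme(name, tau_ref=4.0, ci_ref=2.4)
            vals = []
            for s in scales:
                scaled = VorticityField(om.vectors * s, om.grid, om.timestep)
                vals.append(subject_metric(scaled, box, scheme, ci_subject=2.4).value)
            ranks[name] = list(np.argsort(vals))
        assert ranks["NONE"] == ranks["SS"] == ranks["TS"]


class TestRoiFromLandmarks:
    def test_center_split_halves_the_voxels(self, small_grid):
        c = small_grid.center_mm()
        ra, rv, rh = roi_from_landmarks(
            (0.0, 0.0, 1.0), tuple(c), (0.0, 0.0, 1.0), tuple(c), (15.0, 15.0, 15.0)
        )
        n_ra = ra.voxel_mask(small_grid).sum()
        n_rv = rv.voxel_mask(small_grid).sum()
        assert abs(int(n_ra) - int(n_rv)) <= 16 * 16  # within one voxel slab

    def test_partition_is_exact(self, solid_body_field):
        grid = solid_body_field.grid
        c = grid.center_mm()
        plane_pt = (c[0], c[1], c[2] + 3.3)  # generic, off voxel centers
        ra, rv, rh = roi_from_landmarks(
            (0.0, 0.0, 1.0), plane_pt, (0.0, 0.0, 1.0), tuple(c), (13.0, 13.0, 13.0)
        )
        m_ra, m_rv, m_rh = (r.voxel_mask(grid) for r in (ra, rv, rh))
        assert not np.any(m_ra & m_rv)
        np.testing.assert_array_equal(m_ra | m_rv, m_rh)
        om = compute_vorticity(solid_body_field, 0)
        total = integrate_vorticity(om, ra).value + integrate_vorticity(om, rv).value
        assert total == pytest.approx(integrate_vorticity(om, rh).value, rel=1e-14)

    def test_labels_and_orientation(self, small_grid):
        c = small_grid.center_mm()
        ra, rv, rh = roi_from_landmarks(
            (0.0, 0.0, 1.0), tuple(c), (0.0, 0.0, 1.0), tuple(c), (15.0, 15.0, 15.0)
        )
        assert (ra.label, rv.label, rh.label) == ("RA", "RV", "RH")
        np.testing.assert_allclose(rh.axes[0], (0.0, 0.0, 1.0))

    def test_plane_parallel_to_long_axis_rejected(self, small_grid):
        c = tuple(small_grid.center_mm())
        with pytest.raises(ValueError, match="parallel"):
            roi_from_landmarks((0.0, 0.0, 1.0), c, (1.0, 0.0, 0.0), c, (15.0, 15.0, 15.0))

    def test_plane_missing_the_box_rejected(self, small_grid):
        c = np.array(small_grid.center_mm())
        with pytest.raises(ValueError, match="intersect"):
            roi_from_landmarks(
                (0.0, 0.0, 1.0), tuple(c + [0, 0, 100.0]), (0.0, 0.0, 1.0), tuple(c),
                (15.0, 15.0, 15.0),
            )
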