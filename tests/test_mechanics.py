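"""Deformation fields, strain, mechanics curves, and peak extraction."""

from __future__ import annotations

import numpy as np
import pytest

from dyssync.errors import OutOfDomainError
from dyssync.mechanics import (
    DeformationField,
    motion_from_field,
    strain_curves,
    thickness_curves,
    time_to_peak,
    volume_curves,
)
from dyssync.phantom import dyssynchronous_params, generate_phantom, sample_field


def _uniform_field(disp_per_phase, shape=(8, 8, 8), n_phases=3, spacing=2.0):
    disp = np.zeros((n_phases, *shape, 3))
    for p in range(1, n_phases):
        disp[p] = disp_per_phase
    return DeformationField(
        disp=disp,
        origin=np.zeros(3),
        spacing=np.full(3, spacing),
        phase_times_ms=np.arange(n_phases) * 100.0,
    )


class TestMotionFromField:
    def test_ed_phase_returns_zero(self):
        f = _uniform_field([1.0, 2.0, 3.0])
        assert np.allclose(motion_from_field(f, np.array([5.0, 5.0, 5.0]), 0), 0.0)

    def test_pure_translation_everywhere(self):
        f = _uniform_field([1.5, -2.0, 0.5])
        pts = np.array([[3.3, 4.4, 5.5], [10.0, 2.0, 7.0]])
        out = motion_from_field(f, pts, 2)
        assert np.allclose(out, [1.5, -2.0, 0.5])

    def test_point_outside_grid_rejected(self):
        f = _uniform_field([1.0, 0.0, 0.0])
        with pytest.raises(OutOfDomainError):
            motion_from_field(f, np.array([100.0, 0.0, 0.0]), 1)

    def test_point_outside_mask_rejected(self):
        disp = np.zeros((2, 8, 8, 8, 3))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        f = DeformationField(disp, np.zeros(3), np.ones(3), [0.0, 100.0], mask=mask)
        with pytest.raises(OutOfDomainError):
            motion_from_field(f, np.array([6.5, 6.5, 6.5]), 1)
        assert np.allclose(motion_from_field(f, np.array([3.0, 3.0, 3.0]), 1), 0.0)

    def test_phantom_field_matches_analytic_motion(self):
        """Interpolated sampled field vs the closed-form motion model."""
        from dyssync.phantom import PhantomParams

        truth = generate_phantom(PhantomParams(n_phases=8, twist_deg=0.0))
        field = sample_field(truth, spacing=(1.5, 1.5, 1.5))
        pts = np.array([[33.0, 0.0, 70.0], [0.0, -33.0, 70.0], [32.0, 0.0, 50.0]])
        for p in [2, 4]:
            est = motion_from_field(field, pts, p, check_mask=False)
            ref = truth.displacement(pts, truth.phase_times_ms[p])
            assert np.max(np.abs(est - ref)) < 0.01


def _grid_field(fn, n=16, spacing=2.0, n_phases=2):
    """Field whose phase-1 displacement is fn(points)."""
    ax = np.arange(n) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    disp = np.zeros((n_phases, n, n, n, 3))
    for p in range(1, n_phases):
        disp[p] = fn(pts)
    mask = np.ones((n, n, n), dtype=bool)
    return DeformationField(disp, np.zeros(3), np.full(3, spacing), np.arange(n_phases) * 100.0, mask)


class TestStrain:
    def test_zero_field_gives_zero_strain(self, ed_geom):
        field = sample_field_zeroed(ed_geom)
        for direction in ("radial", "circumferential", "longitudinal", "combined"):
            curves = strain_curves(field, ed_geom, direction)
            assert np.nanmax(np.abs(curves.values)) < 1e-12

    def test_isotropic_scaling_strain_closed_form(self, ed_geom):
        """x -> 0.9 x gives Green-Lagrange strain (0.81 - 1)/2 in every direction."""
        truth = generate_phantom(dyssynchronous_params(n_phases=8))
        field = sample_field(truth, spacing=(2.0, 2.0, 2.0))
        scaled = DeformationField(
            disp=np.where(
                np.arange(field.n_phases)[:, None, None, None, None] > 0,
                -0.1 * field.grid_points()[None],
                0.0,
            ),
            origin=field.origin,
            spacing=field.spacing,
            phase_times_ms=field.phase_times_ms,
            mask=field.mask,
        )
        geom_ed = truth.geometry_per_phase[0]
        for direction in ("radial", "circumferential", "longitudinal", "combined"):
            curves = strain_curves(scaled, geom_ed, direction)
            vals = curves.values[np.isfinite(curves.values[:, 1]), 1]
            assert vals == pytest.approx(np.full(len(vals), -0.095), abs=1e-6)

    def test_rigid_rotation_gives_zero_strain(self, ed_geom):
        truth = generate_phantom(dyssynchronous_params(n_phases=8))
        field = sample_field(truth, spacing=(2.0, 2.0, 2.0))
        a = np.radians(10.0)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        pts = field.grid_points()
        rot = pts @ R.T - pts
        disp = np.zeros_like(field.disp)
        disp[1:] = rot[None]
        rigid = DeformationField(disp, field.origin, field.spacing, field.phase_times_ms, field.mask)
        curves = strain_curves(rigid, truth.geometry_per_phase[0], "radial")
        assert np.nanmax(np.abs(curves.values)) < 1e-3

    def test_radial_strain_matches_material_line_oracle(self, dys_truth):
        """Segment radial strain vs length change of advected radial fibres."""
        from dyssync.geometry import assign_aha16
        from dyssync.mechanics import local_frames

        truth = dys_truth
        field = sample_field(truth, spacing=(1.5, 1.5, 1.5))
        geom_ed = truth.geometry_per_phase[0]
        curves = strain_curves(field, geom_ed, "radial")
        p = 3
        t = truth.phase_times_ms[p]
        # mid-wall sample points with their radial directions
        pts = field.grid_points()[field.mask]
        rng = np.random.default_rng(0)
        pts = pts[rng.choice(len(pts), 4000, replace=False)]
        frames = local_frames(pts, geom_ed)
        h = 0.25
        ends_a = pts - h * frames[:, 0]
        ends_b = pts + h * frames[:, 0]
        la = truth.motion.map_points(ends_b, t) - truth.motion.map_points(ends_a, t)
        stretch2 = np.einsum("ij,ij->i", la, la) / (2 * h) ** 2
        oracle_voxel = 0.5 * (stretch2 - 1.0)
        labels = assign_aha16(pts, geom_ed)
        for s in range(1, 17):
            sel = labels == s
            if sel.sum() < 50 or not np.isfinite(curves.values[s - 1, p]):
                continue
            assert curves.values[s - 1, p] == pytest.approx(oracle_voxel[sel].mean(), abs=0.02)


def sample_field_zeroed(geom):
    n = 12
    disp = np.zeros((3, n, n, n, 3))
    mask = np.ones((n, n, n), dtype=bool)
    return DeformationField(
        disp, geom.apex - 10.0, np.full(3, 8.0), np.arange(3) * 100.0, mask
    )


class TestCurves:
    def test_static_geometry_gives_flat_thickness_curves(self, sync_truth):
        geoms = [sync_truth.geometry_per_phase[0]] * 3
        geoms = [g for g in geoms]
        curves = thickness_curves(geoms, cycle_length_ms=1000.0)
        assert np.allclose(curves.values, curves.values[:, :1])

    def test_contracting_phantom_thickens_every_segment(self, dys_truth):
        curves = thickness_curves(dys_truth.geometry_per_phase, cycle_length_ms=1000.0)
        thickening = curves.values.max(axis=1) - curves.values[:, 0]
        assert np.all(thickening > 0)

    def test_earliest_segment_thickens_first(self, dys_truth):
        curves = thickness_curves(dys_truth.geometry_per_phase, cycle_length_ms=1000.0)
        delays = np.asarray(dys_truth.params.segment_delays_ms)
        peaks = np.array(
            [time_to_peak(v, curves.times_ms, "thickness") for v in curves.values]
        )
        assert peaks[delays == 0.0].mean() < peaks[delays > 0.0].mean()

    def test_synchronous_volume_minima_coincide(self, sync_truth):
        curves = volume_curves(sync_truth.geometry_per_phase, cycle_length_ms=1000.0)
        argmins = np.argmin(curves.values, axis=1)
        assert np.all(argmins == argmins[0])

    def test_wedge_sum_equals_global_volume_curve(self, dys_truth):
        from dyssync.geometry import cavity_volume

        curves = volume_curves(dys_truth.geometry_per_phase, cycle_length_ms=1000.0)
        totals = np.array([cavity_volume(g) for g in dys_truth.geometry_per_phase])
        assert np.allclose(curves.values.sum(axis=0), totals, rtol=1e-9)

    def test_volume_minima_match_phantom_truth_within_half_frame(self, dys_truth):
        curves = volume_curves(dys_truth.geometry_per_phase, cycle_length_ms=1000.0)
        frame = curves.times_ms[1] - curves.times_ms[0]
        peaks = np.array(
            [time_to_peak(v, curves.times_ms, "volume") for v in curves.values]
        )
        assert np.max(np.abs(peaks - dys_truth.true_segment_peak_times_ms)) < frame / 2.0


class TestTimeToPeak:
    def test_strictly_decreasing_volume_peaks_at_final_phase(self):
        t = np.arange(10) * 50.0
        v = 100.0 - 3.0 * np.arange(10)
        assert time_to_peak(v, t, "volume", interpolate=False) == t[-1]

    def test_half_cosine_minimum_recovered_subframe(self):
        T = 1000.0
        t_star = 0.37 * T
        t = np.arange(30) * T / 30.0
        v = np.cos(np.pi * (t - t_star) / T)  # maximum at t_star
        est = time_to_peak(v, t, "thickness")
        assert abs(est - t_star) < T / 60.0

    def test_tied_minima_return_earliest(self):
        t = np.arange(7) * 100.0
        v = np.array([5.0, 1.0, 5.0, 5.0, 1.0, 5.0, 5.0])
        assert time_to_peak(v, t, "volume", interpolate=False) == 100.0

    def test_flat_curve_has_no_peak(self):
        t = np.arange(8) * 100.0
        v = np.full(8, 42.0)
        assert np.isnan(time_to_peak(v, t, "volume"))

    def test_peak_time_scales_with_time_axis(self):
        t = np.arange(30) * 33.0
        v = np.cos((t - 400.0) / 150.0)
        a = time_to_peak(v, t, "thickness")
        b = time_to_peak(v, 3.0 * t, "thickness")
        assert b == pytest.approx(3.0 * a, rel=1e-6)
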