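"""Regional mechanics: curves of volume, thickening and strain, and peaks.

All motion is Lagrangian and referenced to end-diastole (ED, phase 0):
the deformation field ``v(x, p)`` gives the displacement in mm of the
material point that sits at ``x`` at ED, at cardiac phase ``p``.  Strain
is the Green-Lagrange tensor ``E = (F^T F - I) / 2`` with
``F = I + grad v``, projected onto a local radial / circumferential /
longitudinal frame evaluated at ED and held fixed.  The Green-Lagrange
measure is exactly invariant under rigid rotation, which makes the
rigid-motion sanity checks sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from dyssync.errors import InvalidGeometryError, OutOfDomainError
from dyssync.geometry import (
    N_SEGMENTS,
    LVGeometry,
    assign_aha16,
    regional_cavity_volumes,
    wall_thickness,
)

__all__ = [
    "DeformationField",
    "SegmentCurves",
    "local_frames",
    "motion_from_field",
    "strain_curves",
    "thickness_curves",
    "volume_curves",
    "time_to_peak",
    "PEAK_CONVENTIONS",
]

#: Peak convention per mechanics measure: "min" (volume reaches its
#: minimum, shortening strains their most negative value), "max"
#: (thickness, radial strain), or "absmax" (combined strain: the largest
#: absolute excursion from zero).
PEAK_CONVENTIONS = {
    "volume": "min",
    "thickness": "max",
    "radial": "max",
    "circumferential": "min",
    "longitudinal": "min",
    "combined": "absmax",
}


@dataclass
class DeformationField:
    """ED-referenced displacement field sampled on a regular grid.

    ``disp`` has shape ``(n_phases, nx, ny, nz, 3)`` with displacements
    in mm; ``origin``/``spacing`` place the grid in world mm.  ``mask``
    marks the ED myocardial voxels on which the field is trusted.
    """

    disp: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    phase_times_ms: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.phase_times_ms = np.asarray(self.phase_times_ms, dtype=float)
        if self.disp.ndim != 5 or self.disp.shape[-1] != 3:
            raise ValueError("disp must have shape (n_phases, nx, ny, nz, 3)")
        if len(self.phase_times_ms) != self.disp.shape[0]:
            raise ValueError("phase_times_ms length must match the number of phases")
        if not np.allclose(self.disp[0], 0.0, atol=1e-9):
            raise ValueError("phase 0 is the ED reference; its displacement must be zero")

    @property
    def n_phases(self) -> int:
        return self.disp.shape[0]

    @property
    def cycle_length_ms(self) -> float:
        # Phase times sample one cycle uniformly; the cycle closes one
        # frame interval after the last stored phase.
        dt = self.phase_times_ms[1] - self.phase_times_ms[0] if self.n_phases > 1 else 0.0
        return float(self.phase_times_ms[-1] + dt)

    def grid_points(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.disp.shape[1:4]
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.origin + idx * self.spacing


def motion_from_field(field: DeformationField, x: np.ndarray, p: int, *, check_mask: bool = True) -> np.ndarray:
    """Displacement v(x, p) of ED points ``x``, trilinearly interpolated.

    ``check_mask=False`` skips the myocardial-mask membership check
    (used when evaluating the field on surface points that straddle the
    voxelized mask).

    Raises
    ------
    OutOfDomainError
        If a point falls outside the ED myocardial mask (when the field
        carries one and ``check_mask`` is on) or outside the grid.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    coords = ((pts - field.origin) / field.spacing).T
    shape = np.array(field.disp.shape[1:4])
    if np.any(coords.min(axis=1) < -0.5) or np.any(coords.max(axis=1) > shape - 0.5):
        raise OutOfDomainError("point outside the deformation-field grid")
    if field.mask is not None and check_mask:
        nearest = np.clip(np.round(coords).astype(int).T, 0, shape - 1)
        inside = field.mask[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
        if not np.all(inside):
            raise OutOfDomainError("point outside the ED myocardial mask")
    out = np.stack(
        [map_coordinates(field.disp[p, ..., d], coords, order=1, mode="nearest") for d in range(3)],
        axis=-1,
    )
    return out[0] if np.asarray(x).ndim == 1 else out


@dataclass
class SegmentCurves:
    """A 16 x n_phases matrix of one mechanics measure with its time axis."""

    measure: str
    values: np.ndarray
    times_ms: np.ndarray
    cycle_length_ms: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape[1] != len(self.times_ms):
            raise ValueError("values second dimension must match the time axis")


def local_frames(points: np.ndarray, geom: LVGeometry) -> np.ndarray:
    """Right-handed (radial, circumferential, longitudinal) triads at ED.

    The radial direction is the outward wall normal, taken from the
    closest epicardial face; circumferential is ``long_axis x radial``;
    longitudinal completes the triad.  Returns shape ``(n, 3, 3)`` with
    rows radial / circumferential / longitudinal.
    """
    from dyssync._proximity import closest_on_mesh

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _, tri_id = closest_on_mesh(geom.epi, pts)
    radial = geom.epi.face_normals[tri_id].copy()
    # Ensure outward orientation: positive component away from the axis.
    rel = pts - geom.apex
    axial = np.outer(rel @ geom.long_axis, geom.long_axis)
    outward = rel - axial
    flip = np.einsum("ij,ij->i", radial, outward) < 0
    radial[flip] *= -1.0

    circ = np.cross(geom.long_axis, radial)
    norms = np.linalg.norm(circ, axis=1, keepdims=True)
    degenerate = norms[:, 0] < 1e-8
    if np.any(degenerate):
        # Near the apex the normal is parallel to the long axis; fall
        # back to the RV-insertion direction for the circumferential.
        circ[degenerate] = np.cross(geom.long_axis, geom.rv_insertion_dir)
        norms = np.linalg.norm(circ, axis=1, keepdims=True)
    circ /= norms
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    longitudinal = np.cross(radial, circ)
    return np.stack([radial, circ, longitudinal], axis=1)


def _deformation_gradient(disp_phase: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """F = I + grad v on the grid, central differences (one-sided at edges)."""
    grads = np.gradient(disp_phase, *spacing, axis=(0, 1, 2))
    F = np.stack(grads, axis=-1)  # (..., comp, d/dx_j)
    F = F + np.eye(3)
    return F


def green_lagrange(disp_phase: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain tensor E = (F^T F - I)/2 per voxel."""
    F = _deformation_gradient(disp_phase, spacing)
    C = np.einsum("...ki,...kj->...ij", F, F)
    return 0.5 * (C - np.eye(3))


def strain_curves(
    field: DeformationField,
    geom_ed: LVGeometry,
    direction: str,
    labels: np.ndarray | None = None,
    min_voxels: int = 10,
) -> SegmentCurves:
    """Per-segment directional Green-Lagrange strain over the cycle.

    ``direction`` is one of ``radial``, ``circumferential``,
    ``longitudinal`` or ``combined`` (the per-voxel mean of the three
    directional strains).  Segment values are means over the segment's
    masked myocardial voxels; segments with fewer than ``min_voxels``
    voxels are flagged missing (NaN).
    """
    if direction not in ("radial", "circumferential", "longitudinal", "combined"):
        raise ValueError(f"unknown strain direction {direction!r}")
    if field.mask is None:
        raise ValueError("strain computation requires the ED myocardial mask")
    mask = field.mask
    pts = field.grid_points()[mask]
    if labels is None:
        labels = assign_aha16(pts, geom_ed)
    frames = local_frames(pts, geom_ed)

    n_phases = field.n_phases
    values = np.full((N_SEGMENTS, n_phases), np.nan)
    seg_masks = [(labels == s, np.count_nonzero(labels == s)) for s in range(1, N_SEGMENTS + 1)]
    for p in range(n_phases):
        E = green_lagrange(field.disp[p], field.spacing)[mask]
        if direction == "combined":
            per_voxel = np.mean(
                [np.einsum("nij,ni,nj->n", E, frames[:, d], frames[:, d]) for d in range(3)],
                axis=0,
            )
        else:
            d = {"radial": 0, "circumferential": 1, "longitudinal": 2}[direction]
            per_voxel = np.einsum("nij,ni,nj->n", E, frames[:, d], frames[:, d])
        for s, (sel, count) in enumerate(seg_masks):
            if count >= min_voxels:
                values[s, p] = per_voxel[sel].mean()
    return SegmentCurves(
        measure=direction,
        values=values,
        times_ms=field.phase_times_ms,
        cycle_length_ms=field.cycle_length_ms,
    )


def volume_curves(geoms: list[LVGeometry], cycle_length_ms: float | None = None) -> SegmentCurves:
    """Regional cavity-volume curves, partitioned in the ED frame at all phases."""
    if len(geoms) < 2:
        raise InvalidGeometryError("need at least two phases for curves")
    frame = geoms[0]
    values = np.stack([regional_cavity_volumes(g, frame=frame) for g in geoms], axis=1)
    times = np.array([g.phase_time_ms for g in geoms])
    if cycle_length_ms is None:
        cycle_length_ms = float(times[-1] + (times[1] - times[0]))
    return SegmentCurves("volume", values, times, cycle_length_ms)


def thickness_curves(geoms: list[LVGeometry], cycle_length_ms: float | None = None) -> SegmentCurves:
    """Per-segment wall-thickness curves (endo-to-epi surface distance)."""
    if len(geoms) < 2:
        raise InvalidGeometryError("need at least two phases for curves")
    frame = geoms[0]
    values = np.stack([wall_thickness(g, frame=frame) for g in geoms], axis=1)
    times = np.array([g.phase_time_ms for g in geoms])
    if cycle_length_ms is None:
        cycle_length_ms = float(times[-1] + (times[1] - times[0]))
    return SegmentCurves("thickness", values, times, cycle_length_ms)


def time_to_peak(
    values: np.ndarray,
    times_ms: np.ndarray,
    measure: str,
    *,
    interpolate: bool = True,
    flat_tol_frac: float = 0.005,
) -> float:
    """Time (ms) at which one segment's curve reaches its peak.

    The peak convention follows the measure's physiologic direction
    (see :data:`PEAK_CONVENTIONS`).  With ``interpolate=True`` (the
    default) the discrete extremum is refined below the frame interval
    by locating the extremum of a cubic-spline interpolant within two
    frames of the discrete peak; a local parabola would be biased by
    several ms at typical frame rates because the underlying curves are
    cosine-like, not parabolic, near their extrema.  Ties go to the
    earliest extremum.  A flat curve - range below ``flat_tol_frac`` of
    the ED value's magnitude - has no peak and returns NaN.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 phases to locate a peak")
    convention = PEAK_CONVENTIONS.get(measure, measure)
    if convention == "min":
        signal = -v
    elif convention == "max":
        signal = v
    elif convention == "absmax":
        signal = np.abs(v)
    else:
        raise ValueError(f"unknown peak convention {convention!r}")

    scale = abs(v[0]) if abs(v[0]) > 0 else 1e-12
    if np.ptp(v) < flat_tol_frac * scale:
        return float("nan")

    i = int(np.argmax(signal))
    t_peak = t[i]
    if interpolate and 0 < i < len(t) - 1:
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(t, signal)
        lo = max(t[0], t[i] - 2.0 * (t[i] - t[i - 1]))
        hi = min(t[-1], t[i] + 2.0 * (t[i + 1] - t[i]))
        dense = np.linspace(lo, hi, 401)
        t_peak = dense[int(np.argmax(spline(dense)))]
    return float(t_peak)
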