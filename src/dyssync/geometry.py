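"""LV shell geometry, the AHA 16-segment model, and regional measures.

The left ventricle is represented as a pair of triangulated surfaces
(endocardium and epicardium) together with an anatomical frame: the long
axis (apex to mitral valve plane), the valve plane itself, and the
direction of the anterior right-ventricular insertion point, which fixes
the origin of the circumferential sectors.

The standard AHA partition divides the ventricle into three longitudinal
thirds (basal / mid / apical, by equal division of the apex-to-valve
distance) and splits the basal and mid rings into six 60-degree sectors
and the apical ring into four 90-degree sectors.  Segments are numbered
1-16 (6 basal, 6 mid, 4 apical); the apical cap (segment 17) is not
used.  Angles are measured from the RV-insertion direction,
counterclockwise when viewed from the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from dyssync.errors import InvalidGeometryError

__all__ = [
    "LVGeometry",
    "assign_aha16",
    "regional_cavity_volumes",
    "wall_thickness",
    "cavity_volume",
    "N_SEGMENTS",
]

N_SEGMENTS = 16

# Apical quadrant -> AHA segment number.  The quadrant containing the
# RV-insertion direction (angle 0) maps to the apical septal segment 14;
# subsequent quadrants counterclockwise are 15 (inferior), 16 (lateral),
# 13 (anterior).
_APICAL_SEGMENTS = np.array([14, 15, 16, 13])


@dataclass
class LVGeometry:
    """LV shell pair with its anatomical frame at one cardiac phase.

    Surfaces are in mm, world coordinates.  ``endo`` must be a closed
    (capped at the valve plane) mesh when cavity volumes are requested;
    ``epi`` is the outer surface.
    """

    endo: trimesh.Trimesh
    epi: trimesh.Trimesh
    apex: np.ndarray
    valve_point: np.ndarray
    long_axis: np.ndarray
    rv_insertion_dir: np.ndarray
    phase_time_ms: float = 0.0
    valve_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        self.valve_point = np.asarray(self.valve_point, dtype=float)
        self.long_axis = _unit(self.long_axis)
        self.rv_insertion_dir = np.asarray(self.rv_insertion_dir, dtype=float)
        if self.valve_normal is None:
            self.valve_normal = self.long_axis.copy()
        # Orthogonalize the insertion direction against the long axis.
        proj = self.rv_insertion_dir - np.dot(self.rv_insertion_dir, self.long_axis) * self.long_axis
        norm = np.linalg.norm(proj)
        if norm < 1e-9:
            raise InvalidGeometryError("rv_insertion_dir is parallel to the long axis")
        self.rv_insertion_dir = proj / norm
        if self.axis_length <= 0:
            raise InvalidGeometryError("valve plane is not above the apex along the long axis")

    @property
    def axis_length(self) -> float:
        """Apex-to-valve-plane distance along the long axis, mm."""
        return float(np.dot(self.valve_point - self.apex, self.long_axis))

    @property
    def circumferential_ref(self) -> np.ndarray:
        """In-plane direction 90 degrees counterclockwise from the RV insertion."""
        return np.cross(self.long_axis, self.rv_insertion_dir)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidGeometryError("degenerate (zero-length) axis vector")
    return v / n


def assign_aha16(points: np.ndarray, geom: LVGeometry) -> np.ndarray:
    """Label points with AHA segment numbers 1-16 (0 = above the valve plane).

    Longitudinal thirds divide the apex-to-valve distance equally; the
    basal and mid rings use six 60-degree sectors and the apical ring
    four 90-degree sectors, with angle 0 at the RV-insertion direction
    and angles increasing counterclockwise viewed from the base.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - geom.apex
    h = rel @ geom.long_axis
    total = geom.axis_length
    frac = np.clip(h / total, 0.0, None)

    u = rel @ geom.rv_insertion_dir
    v = rel @ geom.circumferential_ref
    angle = np.degrees(np.arctan2(v, u)) % 360.0

    labels = np.zeros(len(pts), dtype=int)
    excluded = frac > 1.0 + 1e-9
    apical = (~excluded) & (frac < 1.0 / 3.0)
    mid = (~excluded) & (frac >= 1.0 / 3.0) & (frac < 2.0 / 3.0)
    basal = (~excluded) & (frac >= 2.0 / 3.0)

    sector6 = np.minimum((angle // 60.0).astype(int), 5)
    quad4 = np.minimum((angle // 90.0).astype(int), 3)
    labels[basal] = 1 + sector6[basal]
    labels[mid] = 7 + sector6[mid]
    labels[apical] = _APICAL_SEGMENTS[quad4[apical]]
    return labels


def _soft_wedge_weights(
    points: np.ndarray,
    geom: LVGeometry,
    angle_soft_deg: float = 3.0,
    frac_soft: float = 0.04,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Antialiased AHA-wedge membership weights for a point set.

    Returns flat arrays ``(point_idx, segment_label, weight)`` where each
    point's weights sum to one.  Sector and third boundaries are linear
    ramps of half-width ``angle_soft_deg`` (degrees) and ``frac_soft``
    (fraction of the long axis) instead of hard cuts: as material
    crosses a wedge boundary its volume transfers gradually, which keeps
    regional volume curves continuous in time.  Points above the valve
    plane fold into the basal ring.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - geom.apex
    frac = np.clip((rel @ geom.long_axis) / geom.axis_length, 0.0, 1.0)
    u = rel @ geom.rv_insertion_dir
    v = rel @ geom.circumferential_ref
    angle = np.degrees(np.arctan2(v, u)) % 360.0

    w1 = np.clip((frac - (1.0 / 3.0 - frac_soft)) / (2.0 * frac_soft), 0.0, 1.0)
    w2 = np.clip((frac - (2.0 / 3.0 - frac_soft)) / (2.0 * frac_soft), 0.0, 1.0)
    ring_w = {
        "apical": 1.0 - w1,
        "mid": w1 * (1.0 - w2),
        "basal": w1 * w2,
    }
    ring_sectors = {
        "apical": _APICAL_SEGMENTS,
        "mid": np.arange(7, 13),
        "basal": np.arange(1, 7),
    }

    idx_out, lab_out, w_out = [], [], []
    n = len(pts)
    all_idx = np.arange(n)
    for ring, segments in ring_sectors.items():
        rw = ring_w[ring]
        active = rw > 0
        if not np.any(active):
            continue
        nsec = len(segments)
        width = 360.0 / nsec
        h = angle_soft_deg / width  # ramp half-width in sector units
        s = angle[active] / width
        k = np.floor(s).astype(int) % nsec
        frac_u = s - np.floor(s)
        to_lower = 1.0 - np.clip(frac_u / (2.0 * h) + 0.5, 0.0, 1.0)
        to_upper = np.clip((frac_u - 1.0) / (2.0 * h) + 0.5, 0.0, 1.0)
        self_w = 1.0 - to_lower - to_upper
        base = rw[active]
        ai = all_idx[active]
        for offset, w in ((-1, to_lower), (0, self_w), (1, to_upper)):
            nz = w > 0
            if np.any(nz):
                idx_out.append(ai[nz])
                lab_out.append(segments[(k[nz] + offset) % nsec])
                w_out.append(base[nz] * w[nz])
    return np.concatenate(idx_out), np.concatenate(lab_out), np.concatenate(w_out)


def wedge_volumes_from_faces(
    triangles: np.ndarray,
    frame: LVGeometry,
    angle_soft_deg: float = 3.0,
    frac_soft: float = 0.04,
) -> np.ndarray:
    """16-wedge volumes (mm^3) of a closed surface given as triangles.

    Each face contributes the signed volume of its tetrahedron with a
    fixed reference point at mid-height of the frame's long axis, split
    across segments by the antialiased wedge weights of its centroid.
    The weights of every face sum to one, so the 16 wedges sum to the
    total enclosed volume exactly.
    """
    ref_point = frame.apex + 0.5 * frame.axis_length * frame.long_axis
    tri = triangles - ref_point
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    if signed.sum() < 0:
        signed = -signed
    centroids = tri.mean(axis=1) + ref_point
    idx, labels, weights = _soft_wedge_weights(centroids, frame, angle_soft_deg, frac_soft)
    volumes = np.zeros(N_SEGMENTS)
    np.add.at(volumes, labels - 1, signed[idx] * weights)
    return volumes


def cavity_volume(geom: LVGeometry) -> float:
    """Total cavity volume (ml) of the closed endocardial surface."""
    endo = geom.endo
    if not endo.is_watertight:
        raise InvalidGeometryError("endocardial surface is not closed (cap it at the valve plane)")
    return float(abs(endo.volume)) / 1000.0


def regional_cavity_volumes(
    geom: LVGeometry,
    frame: LVGeometry | None = None,
    angle_soft_deg: float = 3.0,
    frac_soft: float = 0.04,
) -> np.ndarray:
    """Partition the cavity into 16 wedges and return their volumes in ml.

    Each triangle of the closed endocardial surface contributes the
    signed volume of the tetrahedron it spans with a fixed reference
    point on the long axis, split across segments by the antialiased
    wedge weights of its centroid (hard sector cuts would make regional
    volumes jump discontinuously in time as mesh faces cross wedge
    boundaries).  Because every face's weights sum to one against the
    same reference point, the 16 wedge volumes sum to the total cavity
    volume by construction.

    ``frame`` optionally supplies the anatomical frame used for the
    partition (e.g. the end-diastolic frame applied to all phases); the
    deforming geometry itself provides the surface.
    """
    endo = geom.endo
    if not endo.is_watertight:
        raise InvalidGeometryError("endocardial surface is not closed (cap it at the valve plane)")
    ref_geom = geom if frame is None else frame
    return wedge_volumes_from_faces(endo.triangles, ref_geom, angle_soft_deg, frac_soft) / 1000.0


def wall_thickness(
    geom: LVGeometry,
    labels: np.ndarray | None = None,
    frame: LVGeometry | None = None,
) -> np.ndarray:
    """Per-segment wall thickness (mm): endo-to-epi nearest-surface distance.

    For every endocardial face centroid below the valve plane the
    distance to the closest point on the epicardial surface is computed;
    the segment value is the area-weighted mean over the segment's
    endocardial faces.  The measure is directional (endo toward epi);
    coincident surfaces legitimately give zero thickness.
    """
    ref_geom = geom if frame is None else frame
    centroids = geom.endo.triangles_center
    areas = geom.endo.area_faces
    if labels is None:
        labels = assign_aha16(centroids, ref_geom)
    labels = np.asarray(labels)
    keep = labels > 0
    centroids, areas, labels = centroids[keep], areas[keep], labels[keep]

    from dyssync._proximity import closest_on_mesh

    dists, _ = closest_on_mesh(geom.epi, centroids)

    thickness = np.full(N_SEGMENTS, np.nan)
    for s in range(1, N_SEGMENTS + 1):
        sel = labels == s
        if np.any(sel):
            thickness[s - 1] = float(np.average(dists[sel], weights=areas[sel]))
    return thickness
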