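"""From raw geometry to a corresponding landmark grid.

Input per subject: a triangulated lumen surface, an ordered center lumen
line (CLL), and the marker at the lowest renal artery orifice.  Output: a
grid of 10 levels x 360 azimuthal landmarks with anatomical point-to-point
correspondence across subjects, rigidly aligned at the renal baseline.

Correspondence convention (fixed across the whole package):

- level i sits at arc length i/(L-1) of the way from the renal baseline to
  the distal neck end (the first centerline location where the lumen's
  area-equivalent diameter reaches 110% of the renal-baseline diameter);
- azimuth j is j * (360/n_angles) degrees from the anterior reference
  direction (the projection of the patient's +y axis onto the cutting
  plane), counterclockwise when viewed from cranial.

Axes: x = left, y = anterior, z = cranial; all lengths in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from neckssm.errors import (
    DegenerateSegmentError,
    GeometryError,
    InvalidParameterError,
    NoDistalEndError,
    OpenContourError,
)

logger = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])


@dataclass
class CenterLumenLine:
    """Ordered polyline through the lumen center, with arc length.

    Arc length is cumulative along the polyline, 0 at the first (most
    proximal) point.
    """

    points: np.ndarray
    arclength: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise InvalidParameterError("centerline needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if (seg <= 0).any():
            raise InvalidParameterError("centerline has duplicate consecutive points")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the polyline at arc length(s) s."""
        s = np.clip(s, 0.0, self.total_length)
        out = np.stack(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)], axis=-1
        )
        return out

    def tangent_at(self, s: float, h: float = 0.5) -> np.ndarray:
        """Unit tangent by central differences of the interpolated curve."""
        lo = max(s - h, 0.0)
        hi = min(s + h, self.total_length)
        d = self.point_at(hi) - self.point_at(lo)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GeometryError("degenerate tangent on centerline")
        return d / n

    def project(self, point: np.ndarray) -> float:
        """Arc length of the polyline point closest to ``point``."""
        p = np.asarray(point, dtype=float)
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p[None, :] - a, ab) / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", closest - p, closest - p)
        i = int(np.argmin(d2))
        return float(self.arclength[i] + t[i] * np.sqrt(denom[i]))


@dataclass
class LumenSurface:
    """Triangulated lumen surface (vertices in mm, faces as index triples)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise InvalidParameterError("face index out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "LumenSurface":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))


@dataclass
class CenterlineLevels:
    """The resampled neck levels: points, unit tangents, arc lengths."""

    points: np.ndarray  # (L, 3)
    tangents: np.ndarray  # (L, 3)
    arclengths: np.ndarray  # (L,), along the CLL


@dataclass
class ParametrizedNeck:
    """Corresponding landmark grid of one subject.

    ``landmarks[i, j]`` is the surface point at level i, azimuth
    j * (360 / n_angles) degrees from the anterior reference.
    """

    landmarks: np.ndarray  # (L, A, 3)
    level_arclengths: np.ndarray  # (L,)
    reference_azimuth: float = 0.0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 3 or self.landmarks.shape[2] != 3:
            raise InvalidParameterError("landmarks must have shape (levels, angles, 3)")
        if np.isnan(self.landmarks).any():
            raise InvalidParameterError("landmarks contain NaNs")

    @property
    def n_levels(self) -> int:
        return self.landmarks.shape[0]

    @property
    def n_angles(self) -> int:
        return self.landmarks.shape[1]

    def flattened(self) -> np.ndarray:
        return self.landmarks.reshape(-1)


# ---------------------------------------------------------------------------
# plane/contour machinery
# ---------------------------------------------------------------------------


def plane_contour(
    mesh: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray
) -> np.ndarray:
    """Closed intersection polygon of a plane with the mesh, as (M, 3).

    If the plane cuts the mesh in several closed polylines the one whose
    centroid is nearest ``origin`` is returned (robust to side-branch
    slivers).  Open polylines are ignored; if none is closed an
    :class:`OpenContourError` is raised.
    """
    section = mesh.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        raise OpenContourError("cutting plane does not intersect the mesh")
    best = None
    best_d = np.inf
    for poly in section.discrete:
        closed = np.linalg.norm(poly[0] - poly[-1]) < 1e-8
        if not closed:
            continue
        ring = poly[:-1]
        if len(ring) < 3:
            continue
        d = np.linalg.norm(ring.mean(axis=0) - origin)
        if d < best_d:
            best, best_d = ring, d
    if best is None:
        raise OpenContourError("no closed intersection polyline at this level")
    return np.asarray(best, dtype=float)


def plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal basis (e1 anterior-ish, e2) of a cutting plane.

    e1 is the unit projection of the anterior axis (+y) onto the plane; if
    that projection is degenerate (tangent parallel to +y) the projection
    of +x is used instead and a warning logged.  e2 completes the basis so
    that azimuth measured from e1 toward e2 runs counterclockwise when
    viewed from cranial.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    proj = _Y - (_Y @ t) * t
    if np.linalg.norm(proj) < 1e-6:
        logger.warning("anterior reference degenerate at this level; falling back to +x")
        proj = _X - (_X @ t) * t
        if np.linalg.norm(proj) < 1e-6:
            raise GeometryError("no usable in-plane reference direction")
    e1 = proj / np.linalg.norm(proj)
    m = t if t @ _Z > 0 else -t
    e2 = np.cross(m, e1)
    return e1, e2


def contour_to_plane(
    polygon: np.ndarray, origin: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> np.ndarray:
    """Project a 3D polygon into (xi, eta) plane coordinates about origin."""
    rel = polygon - np.asarray(origin)[None, :]
    return np.stack([rel @ e1, rel @ e2], axis=1)


def contour_area(poly2d: np.ndarray) -> float:
    """Shoelace area of a closed 2D polygon (vertices not repeated)."""
    x, y = poly2d[:, 0], poly2d[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def equivalent_diameter(poly2d: np.ndarray) -> float:
    """Area-equivalent diameter 2*sqrt(A/pi) of a cross-section polygon."""
    return 2.0 * np.sqrt(contour_area(poly2d) / np.pi)


def _ray_radii(poly2d: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from the origin to the polygon along each ray direction.

    Nearest crossing if a ray cuts the polygon more than once.  Rays with
    no crossing (numerically grazing cases) fall back to the azimuthally
    nearest vertex radius.
    """
    a = poly2d
    b = np.roll(poly2d, -1, axis=0)
    d = b - a  # (M, 2) segment directions
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (A, 2)

    # r * dir = a + u * d ; solve per (ray, segment) with 2D cross products
    denom = dirs[:, 0][:, None] * d[:, 1][None, :] - dirs[:, 1][:, None] * d[:, 0][None, :]
    cross_ad = a[:, 0] * d[:, 1] - a[:, 1] * d[:, 0]  # (M,)
    cross_a_dir = a[None, :, 0] * dirs[:, 1][:, None] - a[None, :, 1] * dirs[:, 0][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross_ad[None, :] / denom
        u = cross_a_dir / denom
    valid = (np.abs(denom) > 1e-14) & (u >= -1e-12) & (u < 1.0) & (r > 1e-9)
    r = np.where(valid, r, np.inf)
    radii = r.min(axis=1)

    missing = ~np.isfinite(radii)
    if missing.any():
        vert_ang = np.arctan2(poly2d[:, 1], poly2d[:, 0])
        vert_rad = np.linalg.norm(poly2d, axis=1)
        for k in np.flatnonzero(missing):
            diff = np.angle(np.exp(1j * (vert_ang - angles[k])))
            radii[k] = vert_rad[int(np.argmin(np.abs(diff)))]
    return radii


# ---------------------------------------------------------------------------
# the four pipeline operations
# ---------------------------------------------------------------------------


def locate_distal_neck_end(
    surface: LumenSurface,
    cll: CenterLumenLine,
    renal_marker: np.ndarray,
    step: float = 0.5,
    diameter_ratio: float = 1.10,
) -> tuple[np.ndarray, float]:
    """Find the distal neck end by the +10% diameter rule.

    Walks distally from the renal baseline in ``step`` mm arc-length
    increments, computing the area-equivalent diameter of the cross-section
    perpendicular to the centerline, and returns the most proximal location
    where it reaches ``diameter_ratio`` times the renal-baseline diameter,
    refined by linear interpolation between the bracketing steps.

    Returns ``(point, arc_length)``; raises :class:`NoDistalEndError` if the
    rule is never met before the centerline ends.
    """
    mesh = surface.to_trimesh()
    s0 = cll.project(renal_marker)

    def diam(s: float) -> float:
        poly = plane_contour(mesh, cll.point_at(s), cll.tangent_at(s))
        e1, e2 = plane_basis(cll.tangent_at(s))
        return equivalent_diameter(contour_to_plane(poly, cll.point_at(s), e1, e2))

    d0 = diam(s0)
    target = diameter_ratio * d0
    s_prev, d_prev = s0, d0
    s = s0 + step
    # stay a hair away from the very end where the cap apex degenerates the cut
    s_max = cll.total_length - max(step / 10.0, 1e-3)
    while s <= s_max:
        d = diam(s)
        if d >= target:
            if d == d_prev:
                s_hit = s
            else:
                s_hit = s_prev + (target - d_prev) / (d - d_prev) * (s - s_prev)
            return cll.point_at(s_hit), float(s_hit)
        s_prev, d_prev = s, d
        s += step
    raise NoDistalEndError(
        f"diameter never reached {diameter_ratio:.2f} x baseline ({target:.2f} mm) "
        f"before the centerline end"
    )


def resample_centerline(
    cll: CenterLumenLine,
    renal: np.ndarray,
    distal: np.ndarray,
    n_levels: int = 10,
    min_spacing: float = 0.1,
) -> CenterlineLevels:
    """Equally spaced (in arc length) levels from renal to distal marker."""
    s_r = cll.project(renal)
    s_d = cll.project(distal)
    if s_d <= s_r:
        raise DegenerateSegmentError("distal marker is not distal to the renal marker")
    if (s_d - s_r) < n_levels * min_spacing:
        raise DegenerateSegmentError(
            f"neck segment of {s_d - s_r:.3f} mm too short for {n_levels} levels"
        )
    s_levels = np.linspace(s_r, s_d, n_levels)
    points = cll.point_at(s_levels)
    h = min(0.5, (s_levels[1] - s_levels[0]) / 2.0)
    tangents = np.array([cll.tangent_at(s, h=h) for s in s_levels])
    return CenterlineLevels(points=points, tangents=tangents, arclengths=s_levels - s_r)


def extract_contours(
    surface: LumenSurface,
    levels: CenterlineLevels,
    n_angles: int = 360,
    subject_id: str = "",
) -> ParametrizedNeck:
    """Sample each level's cross-section contour at equal azimuth steps.

    For every level the closed plane-mesh intersection polyline nearest the
    centerline point is resampled along ``n_angles`` rays from the level
    point, starting at the anterior reference direction and running
    counterclockwise viewed from cranial.
    """
    mesh = surface.to_trimesh()
    n_levels = len(levels.points)
    angles = 2 * np.pi * np.arange(n_angles) / n_angles
    grid = np.empty((n_levels, n_angles, 3))
    for i in range(n_levels):
        origin = levels.points[i]
        tangent = levels.tangents[i]
        poly = plane_contour(mesh, origin, tangent)
        e1, e2 = plane_basis(tangent)
        poly2d = contour_to_plane(poly, origin, e1, e2)
        radii = _ray_radii(poly2d, angles)
        grid[i] = (
            origin[None, :]
            + (radii * np.cos(angles))[:, None] * e1[None, :]
            + (radii * np.sin(angles))[:, None] * e2[None, :]
        )
    return ParametrizedNeck(
        landmarks=grid,
        level_arclengths=levels.arclengths,
        subject_id=subject_id,
    )


def _level0_frame(neck: ParametrizedNeck) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centroid, distal tangent, anterior reference) of the renal baseline."""
    ring = neck.landmarks[0]
    c0 = ring.mean(axis=0)
    rel = ring - c0
    # plane normal = least-varying direction of the (coplanar) contour
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[2]
    c1 = neck.landmarks[1].mean(axis=0)
    if normal @ (c1 - c0) < 0:
        normal = -normal
    a = rel[0]
    a = a - (a @ normal) * normal
    n = np.linalg.norm(a)
    if n < 1e-9:
        raise GeometryError("anterior reference landmark coincides with the centroid")
    return c0, normal, a / n


def alignment_transform(neck: ParametrizedNeck) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping the neck into the canonical frame.

    Canonical frame: renal-baseline centroid at the origin, the distal
    (flow) tangent along +z, the subject's anterior reference along +y.
    Applied as ``x_aligned = (x - c0) @ R.T``.  No scaling: size
    differences are shape signal.
    """
    c0, tangent, anterior = _level0_frame(neck)
    x = np.cross(anterior, tangent)
    R = np.stack([x, anterior, tangent])
    return R, c0


def align_necks(necks: list[ParametrizedNeck]) -> list[ParametrizedNeck]:
    """Rigidly align all necks at the renal baseline (no scaling)."""
    shapes = {(n.n_levels, n.n_angles) for n in necks}
    if len(shapes) > 1:
        raise InvalidParameterError(f"landmark grid dimensions differ across subjects: {shapes}")
    out = []
    for neck in necks:
        R, c0 = alignment_transform(neck)
        aligned = (neck.landmarks - c0) @ R.T
        out.append(
            ParametrizedNeck(
                landmarks=aligned,
                level_arclengths=neck.level_arclengths.copy(),
                reference_azimuth=neck.reference_azimuth,
                subject_id=neck.subject_id,
                group=neck.group,
            )
        )
    return out


def parametrize_subject(
    surface: LumenSurface,
    cll: CenterLumenLine,
    renal_marker: np.ndarray,
    n_levels: int = 10,
    n_angles: int = 360,
    step: float = 0.5,
    subject_id: str = "",
) -> ParametrizedNeck:
    """Full parametrization of one subject: distal-end detection, level
    resampling and contour extraction (alignment is a cohort operation)."""
    distal, _ = locate_distal_neck_end(surface, cll, renal_marker, step=step)
    levels = resample_centerline(cll, renal_marker, distal, n_levels=n_levels)
    return extract_contours(surface, levels, n_angles=n_angles, subject_id=subject_id)
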