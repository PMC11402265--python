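"""Conventional aortic-neck measurements from the same geometric inputs.

These are the workstation-style characteristics used to gauge neck
hostility: neck length (arc length between the renal and distal markers),
neck diameter at the renal baseline, suprarenal and infrarenal angulation,
and 3-level calcification/thrombus categories.

Definitions the literature leaves open are fixed here and documented in
``docs/methods.md``:

- "diameter" is the area-equivalent diameter 2*sqrt(A/pi) of the lumen
  cross-section (rotation-invariant, standard on workstations);
- angulation is the angle between least-squares line directions fitted to
  three low-curvature stretches of the centerline: the proximal end of the
  available centerline (suprarenal axis), the central portion of the neck
  (neck axis), and the distal end of the centerline (aneurysm axis).
  Windows adjacent to the markers are avoided because the bend transitions
  concentrate there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neckssm.errors import InsufficientCenterlineError, InvalidParameterError
from neckssm.parametrization import (
    CenterLumenLine,
    LumenSurface,
    contour_to_plane,
    equivalent_diameter,
    plane_basis,
    plane_contour,
)

__all__ = [
    "ConventionalMeasures",
    "neck_length",
    "neck_diameter",
    "angulations",
    "categorize_circumferential",
    "ring_equivalent_diameter",
    "measure_subject",
]


@dataclass
class ConventionalMeasures:
    neck_length: float  # mm
    neck_diameter: float  # mm
    suprarenal_angle: float  # degrees
    infrarenal_angle: float  # degrees
    calcification_cat: int  # 0 absent, 1 mild, 2 moderate
    thrombus_cat: int

    def __post_init__(self) -> None:
        if self.neck_length <= 0 or self.neck_diameter <= 0:
            raise InvalidParameterError("length and diameter must be positive")
        for a in (self.suprarenal_angle, self.infrarenal_angle):
            if not (0 <= a < 180):
                raise InvalidParameterError("angles must be in [0, 180) degrees")


def neck_length(cll: CenterLumenLine, renal: np.ndarray, distal: np.ndarray) -> float:
    """Arc length along the centerline between the two markers, mm."""
    s_r = cll.project(renal)
    s_d = cll.project(distal)
    if s_d <= s_r:
        raise InvalidParameterError("markers out of order: distal is not distal to renal")
    return s_d - s_r


def neck_diameter(surface: LumenSurface, cll: CenterLumenLine, renal: np.ndarray) -> float:
    """Area-equivalent diameter of the renal-baseline cross-section, mm."""
    mesh = surface.to_trimesh()
    s = cll.project(renal)
    origin = cll.point_at(s)
    tangent = cll.tangent_at(s)
    poly = plane_contour(mesh, origin, tangent)
    e1, e2 = plane_basis(tangent)
    return equivalent_diameter(contour_to_plane(poly, origin, e1, e2))


def _fit_direction(cll: CenterLumenLine, s_lo: float, s_hi: float, spacing: float = 0.25) -> np.ndarray:
    """Unit direction of the least-squares line through a centerline window,
    oriented along increasing arc length."""
    n = max(int(np.ceil((s_hi - s_lo) / spacing)) + 1, 3)
    pts = cll.point_at(np.linspace(s_lo, s_hi, n))
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if d @ (pts[-1] - pts[0]) < 0:
        d = -d
    return d


def angulations(
    cll: CenterLumenLine,
    renal: np.ndarray,
    distal: np.ndarray,
    fit_length: float = 15.0,
    neck_trim_fraction: float = 0.2,
) -> tuple[float, float]:
    """Suprarenal and infrarenal angulation, degrees.

    Suprarenal = angle between the suprarenal axis (fitted over the
    ``fit_length`` mm at the proximal end of the centerline) and the neck
    axis (fitted over the central portion of the neck, trimming
    ``neck_trim_fraction`` of the segment at each end).  Infrarenal = angle
    between the neck axis and the aneurysm axis (fitted over the
    ``fit_length`` mm at the distal end of the centerline).

    Requires the centerline to extend at least ``fit_length`` proximal to
    the renal marker and distal to the distal marker.
    """
    s_r = cll.project(renal)
    s_d = cll.project(distal)
    if s_d <= s_r:
        raise InvalidParameterError("markers out of order")
    if s_r < fit_length - 1e-9:
        raise InsufficientCenterlineError(
            f"only {s_r:.1f} mm of centerline proximal to the renal marker "
            f"(need {fit_length:.1f})",
            available_mm=s_r,
        )
    tail = cll.total_length - s_d
    if tail < fit_length - 1e-9:
        raise InsufficientCenterlineError(
            f"only {tail:.1f} mm of centerline distal to the neck end "
            f"(need {fit_length:.1f})",
            available_mm=tail,
        )
    supra_dir = _fit_direction(cll, 0.0, fit_length)
    trim = neck_trim_fraction * (s_d - s_r)
    neck_dir = _fit_direction(cll, s_r + trim, s_d - trim)
    distal_dir = _fit_direction(cll, cll.total_length - fit_length, cll.total_length)

    def angle(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))

    return angle(supra_dir, neck_dir), angle(neck_dir, distal_dir)


def ring_equivalent_diameter(ring: np.ndarray) -> float:
    """Area-equivalent diameter of a closed 3D contour (e.g. one landmark
    level): the ring is projected onto its own best-fit plane and the
    shoelace area converted to 2*sqrt(A/pi)."""
    ring = np.asarray(ring, dtype=float)
    c = ring.mean(axis=0)
    rel = ring - c
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    poly2d = np.stack([rel @ vt[0], rel @ vt[1]], axis=1)
    return equivalent_diameter(poly2d)


def categorize_circumferential(fraction: float) -> int:
    """3-level circumferential burden: <25% absent (0), 25%-50% mild (1),
    >50% moderate (2).  Both boundaries belong to the mild class."""
    if not (0.0 <= fraction <= 1.0):
        raise InvalidParameterError(f"fraction must be in [0, 1], got {fraction}")
    if fraction < 0.25:
        return 0
    if fraction <= 0.50:
        return 1
    return 2


def measure_subject(
    surface: LumenSurface,
    cll: CenterLumenLine,
    renal: np.ndarray,
    distal: np.ndarray,
    calcification_cat: int = 0,
    thrombus_cat: int = 0,
    fit_length: float = 15.0,
) -> ConventionalMeasures:
    """All conventional measures of one subject from its geometry.

    Calcification/thrombus categories are pass-through covariates: they
    come from image assessment, not from the lumen geometry.
    """
    supra, infra = angulations(cll, renal, distal, fit_length=fit_length)
    return ConventionalMeasures(
        neck_length=neck_length(cll, renal, distal),
        neck_diameter=neck_diameter(surface, cll, renal),
        suprarenal_angle=supra,
        infrarenal_angle=infra,
        calcification_cat=calcification_cat,
        thrombus_cat=thrombus_cat,
    )
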