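"""Synthetic infrarenal aortic neck cohorts.

Clinical CTA-derived geometry for the original case-control study is not
publicly deposited, so this module generates stand-in subjects: a
triangulated lumen surface, a center lumen line (CLL), the two anatomical
markers (lowest renal artery orifice and distal neck end), 3-level
calcification/thrombus categories, and a case/control label.

Each neck is a swept tube: a straight suprarenal segment, a circular-arc
transition bending the tangent by the suprarenal angle, a straight tapering
neck, a second arc bending by the infrarenal angle, and a flaring sac-entry
segment.  Both bends lie in a single plane selected by an azimuth.  The
distal neck end is, by construction, the point where the lumen diameter
reaches 110% of the renal-baseline diameter, which is the rule the
parametrization stage has to rediscover from the mesh.

Group parameter distributions are calibrated so that sample medians and
quartiles of neck length, diameter and angulation approximate the published
case (late type Ia endoleak) and control summaries; see ``docs/methods.md``
for the calibration.

Patient-like axes are used throughout: x = left, y = anterior, z = cranial,
all lengths in mm.  Flow runs caudally, i.e. along -z for a straight neck.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats as sps

from neckssm.errors import GeometryError, InvalidParameterError
from neckssm.parametrization import CenterLumenLine, LumenSurface

__all__ = [
    "NeckParams",
    "GroupSpec",
    "SyntheticSubject",
    "generate_neck_geometry",
    "analytic_landmarks",
    "sample_cohort",
    "default_case_spec",
    "default_control_spec",
    "write_subject",
]

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])

#: arc radius of a bend transition, as a multiple of the local tube radius.
#: Below 1 the swept surface folds into itself on the inner curve.
TRANSITION_RADIUS_FACTOR = 1.5


@dataclass(frozen=True)
class NeckParams:
    """Ground-truth geometric parameters of one synthetic neck.

    ``taper_fraction`` is (distal diameter / proximal diameter) - 1 over the
    neck segment.  With the default 0.10 the diameter reaches the +10%
    detection rule exactly at the built-in distal marker.
    """

    neck_length: float
    proximal_diameter: float
    suprarenal_angle: float = 0.0
    infrarenal_angle: float = 0.0
    taper_fraction: float = 0.10
    bend_plane_azimuth: float = 0.0
    calcification_cat: int = 0
    thrombus_cat: int = 0
    surface_noise_sd: float = 0.0
    suprarenal_length: float = 35.0
    sac_length: float = 35.0
    sac_flare_fraction: float = 0.6
    supra_transition: float | None = None  # None -> adaptive arc length
    infra_transition: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.neck_length) and self.neck_length > 0):
            raise InvalidParameterError(f"neck_length must be positive, got {self.neck_length}")
        if not (np.isfinite(self.proximal_diameter) and self.proximal_diameter > 0):
            raise InvalidParameterError(
                f"proximal_diameter must be positive, got {self.proximal_diameter}"
            )
        if self.taper_fraction < 0:
            raise InvalidParameterError("taper_fraction must be >= 0")
        for name in ("suprarenal_angle", "infrarenal_angle"):
            a = getattr(self, name)
            if not (0 <= a < 90):
                raise InvalidParameterError(f"{name} must be in [0, 90) degrees, got {a}")
        if not (0 <= self.bend_plane_azimuth < 360):
            raise InvalidParameterError("bend_plane_azimuth must be in [0, 360)")
        if self.surface_noise_sd < 0:
            raise InvalidParameterError("surface_noise_sd must be >= 0")
        if self.suprarenal_length <= 0 or self.sac_length <= 0:
            raise InvalidParameterError("suprarenal_length and sac_length must be positive")
        if self.sac_flare_fraction < 0:
            raise InvalidParameterError("sac_flare_fraction must be >= 0")
        for name in ("calcification_cat", "thrombus_cat"):
            if getattr(self, name) not in (0, 1, 2):
                raise InvalidParameterError(f"{name} must be one of 0, 1, 2")


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution of :class:`NeckParams` for one study group.

    Lengths and diameters are log-normal (``*_median`` in mm, ``*_sigma``
    the SD of the log).  Angles are normal truncated to [0, 89) degrees,
    with the location solved so the *truncated* median equals
    ``*_median_deg``.  Category probabilities are 3-vectors over
    absent/mild/moderate circumferential burden.
    """

    n_subjects: int
    length_median: float
    length_sigma: float
    diameter_median: float
    diameter_sigma: float
    supra_median_deg: float
    supra_scale_deg: float
    infra_median_deg: float
    infra_scale_deg: float
    calcification_probs: tuple[float, float, float]
    thrombus_probs: tuple[float, float, float]
    taper_fraction: float = 0.10
    surface_noise_sd: float = 0.2
    angle_upper_deg: float = 89.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2 (PCA undefined below)")
        if self.taper_fraction < 0.10:
            raise InvalidParameterError(
                "taper_fraction must be >= 0.10 so the +10% distal-end rule has a solution"
            )
        for name in ("calcification_probs", "thrombus_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise InvalidParameterError(f"{name} must be a 3-vector of probabilities summing to 1")

    def sample_params(self, rng: np.random.Generator) -> list[NeckParams]:
        """Draw ``n_subjects`` ground-truth parameter sets."""
        n = self.n_subjects
        lengths = np.exp(rng.normal(np.log(self.length_median), self.length_sigma, n))
        diams = np.exp(rng.normal(np.log(self.diameter_median), self.diameter_sigma, n))
        supra = _sample_truncated_angle(
            self.supra_median_deg, self.supra_scale_deg, self.angle_upper_deg, n, rng
        )
        infra = _sample_truncated_angle(
            self.infra_median_deg, self.infra_scale_deg, self.angle_upper_deg, n, rng
        )
        azimuth = rng.uniform(0.0, 360.0, n)
        calc = rng.choice(3, size=n, p=np.asarray(self.calcification_probs, dtype=float))
        thromb = rng.choice(3, size=n, p=np.asarray(self.thrombus_probs, dtype=float))
        return [
            NeckParams(
                neck_length=float(lengths[i]),
                proximal_diameter=float(diams[i]),
                suprarenal_angle=float(supra[i]),
                infrarenal_angle=float(infra[i]),
                taper_fraction=self.taper_fraction,
                bend_plane_azimuth=float(azimuth[i]),
                calcification_cat=int(calc[i]),
                thrombus_cat=int(thromb[i]),
                surface_noise_sd=self.surface_noise_sd,
            )
            for i in range(n)
        ]


def _sample_truncated_angle(
    median: float, scale: float, upper: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal angles on [0, upper) whose median equals ``median``."""
    loc = _truncnorm_loc_for_median(median, scale, upper)
    a, b = (0.0 - loc) / scale, (upper - loc) / scale
    return sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _truncnorm_loc_for_median(median: float, scale: float, upper: float) -> float:
    def gap(loc: float) -> float:
        a, b = (0.0 - loc) / scale, (upper - loc) / scale
        return sps.truncnorm.ppf(0.5, a, b, loc=loc, scale=scale) - median

    return optimize.brentq(gap, -4 * scale, upper)


@dataclass
class SyntheticSubject:
    """One generated subject: geometry, markers, label, ground truth."""

    subject_id: str
    group: Literal["case", "control", ""]
    surface: LumenSurface | None
    centerline: CenterLumenLine
    renal_marker: np.ndarray
    distal_marker: np.ndarray
    true_params: NeckParams


# ---------------------------------------------------------------------------
# analytic tube geometry
# ---------------------------------------------------------------------------


class _TubeGeometry:
    """Closed-form centerline/radius field of one neck.

    The centerline is parametrized by arc length s.  Segment layout::

        [0, L_supra)                straight, suprarenal direction
        [L_supra, s_renal)          arc, bends by suprarenal_angle
        [s_renal, s_distal)         straight neck (renal marker at s_renal)
        [s_distal, s_distal + T_i)  arc, bends by infrarenal_angle
        [...,  s_end]               straight sac-entry segment

    All bend directions are combinations of the caudal axis d0 = -z and the
    in-plane horizontal unit vector u(azimuth); arcs are exact circle
    segments, so tangents, positions and the radius field are closed form.
    """

    def __init__(self, p: NeckParams):
        self.params = p
        theta_s = np.deg2rad(p.suprarenal_angle)
        theta_i = np.deg2rad(p.infrarenal_angle)
        r_prox = p.proximal_diameter / 2.0
        r_distal = r_prox * (1.0 + p.taper_fraction)

        t_supra = p.supra_transition
        if t_supra is None:
            t_supra = theta_s * TRANSITION_RADIUS_FACTOR * r_prox
        t_infra = p.infra_transition
        if t_infra is None:
            t_infra = theta_i * TRANSITION_RADIUS_FACTOR * r_distal
        for theta, t_len, r_loc, which in (
            (theta_s, t_supra, r_prox, "suprarenal"),
            (theta_i, t_infra, r_distal, "infrarenal"),
        ):
            if theta > 1e-9 and t_len / theta < r_loc:
                raise GeometryError(
                    f"{which} transition arc radius {t_len / theta:.2f} mm is smaller than "
                    f"the tube radius {r_loc:.2f} mm: the swept surface would fold"
                )
        self.t_supra = t_supra if theta_s > 1e-12 else 0.0
        self.t_infra = t_infra if theta_i > 1e-12 else 0.0

        az = np.deg2rad(p.bend_plane_azimuth)
        self.u = np.array([np.cos(az), np.sin(az), 0.0])  # bend-plane horizontal
        self.d0 = -_Z

        # cumulative bend angle phi at segment boundaries
        self.s_renal = p.suprarenal_length + self.t_supra
        self.s_distal = self.s_renal + p.neck_length
        self.s_end = self.s_distal + self.t_infra + p.sac_length
        self._bounds = np.array(
            [0.0, p.suprarenal_length, self.s_renal, self.s_distal, self.s_distal + self.t_infra, self.s_end]
        )
        self._phis = np.array([0.0, 0.0, theta_s, theta_s, theta_s + theta_i, theta_s + theta_i])
        self.r_prox = r_prox
        self.r_distal = r_distal
        self.r_sac = r_prox * (1.0 + p.taper_fraction + p.sac_flare_fraction)

        # integrate segment start positions once (each segment is closed form)
        self._starts = [np.zeros(3)]
        for i in range(5):
            self._starts.append(self._advance(self._starts[-1], i, self._bounds[i + 1] - self._bounds[i]))

    def _phi(self, seg: int, ds: float) -> float:
        s0, s1 = self._bounds[seg], self._bounds[seg + 1]
        p0, p1 = self._phis[seg], self._phis[seg + 1]
        if s1 - s0 < 1e-12:
            return p1
        return p0 + (p1 - p0) * ds / (s1 - s0)

    def _dir(self, phi: float) -> np.ndarray:
        return np.cos(phi) * self.d0 + np.sin(phi) * self.u

    def _advance(self, start: np.ndarray, seg: int, ds: float) -> np.ndarray:
        p0, p1 = self._phis[seg], self._phis[seg + 1]
        s0, s1 = self._bounds[seg], self._bounds[seg + 1]
        if abs(p1 - p0) < 1e-12:  # straight
            return start + ds * self._dir(p0)
        R = (s1 - s0) / (p1 - p0)
        phi = self._phi(seg, ds)
        return (
            start
            + R * (np.sin(phi) - np.sin(p0)) * self.d0
            + R * (np.cos(p0) - np.cos(phi)) * self.u
        )

    def _segment(self, s: float) -> int:
        return int(np.clip(np.searchsorted(self._bounds, s, side="right") - 1, 0, 4))

    def position(self, s: float) -> np.ndarray:
        seg = self._segment(s)
        return self._advance(self._starts[seg], seg, s - self._bounds[seg])

    def tangent(self, s: float) -> np.ndarray:
        seg = self._segment(s)
        return self._dir(self._phi(seg, s - self._bounds[seg]))

    def radius(self, s: float) -> float:
        if s <= self.s_renal:
            return self.r_prox
        if s <= self.s_distal:
            f = (s - self.s_renal) / (self.s_distal - self.s_renal)
            return self.r_prox + f * (self.r_distal - self.r_prox)
        f = (s - self.s_distal) / max(self.s_end - self.s_distal, 1e-12)
        return self.r_distal + f * (self.r_sac - self.r_distal)

    def stations(self, spacing: float) -> np.ndarray:
        """Arc-length sample stations including all segment boundaries."""
        pieces = []
        for i in range(5):
            s0, s1 = self._bounds[i], self._bounds[i + 1]
            if s1 - s0 < 1e-9:
                continue
            n = max(int(np.ceil((s1 - s0) / spacing)), 1)
            pieces.append(np.linspace(s0, s1, n + 1)[:-1])
        pieces.append(np.array([self.s_end]))
        return np.concatenate(pieces)

    def frames(self, s_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Parallel-transported in-plane frame (e1, e2) at each station."""
        tangents = np.array([self.tangent(s) for s in s_values])
        e1 = np.empty_like(tangents)
        e2 = np.empty_like(tangents)
        t0 = tangents[0]
        v = _X if abs(t0 @ _X) < 0.9 else _Y
        e1[0] = _normalize(v - (v @ t0) * t0)
        e2[0] = np.cross(t0, e1[0])
        for i in range(1, len(s_values)):
            e1[i] = _transport(e1[i - 1], tangents[i - 1], tangents[i])
            e2[i] = np.cross(tangents[i], e1[i])
        return e1, e2


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize near-zero vector")
    return v / n


def _transport(e: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Rotate frame vector e by the minimal rotation taking t_from to t_to."""
    axis = np.cross(t_from, t_to)
    s = np.linalg.norm(axis)
    c = float(np.clip(t_from @ t_to, -1.0, 1.0))
    if s < 1e-14:
        return e
    axis = axis / s
    angle = np.arctan2(s, c)
    return (
        e * np.cos(angle)
        + np.cross(axis, e) * np.sin(angle)
        + axis * (axis @ e) * (1 - np.cos(angle))
    )


# ---------------------------------------------------------------------------
# mesh + centerline emission
# ---------------------------------------------------------------------------


def generate_neck_geometry(
    params: NeckParams,
    n_angular: int = 96,
    axial_spacing: float = 1.0,
    centerline_spacing: float = 0.5,
    seed: int | np.random.Generator = 0,
    with_mesh: bool = True,
) -> SyntheticSubject:
    """Build one synthetic subject (surface mesh, centerline, markers).

    Parameters
    ----------
    params
        Ground-truth neck parameters.
    n_angular
        Vertices per mesh ring (>= 64 recommended for <0.1 mm chord error).
    axial_spacing
        Approximate arc-length spacing of mesh rings, mm.
    centerline_spacing
        Sample spacing of the emitted center lumen line, mm.
    seed
        Seed (or Generator) for the radial surface noise.
    with_mesh
        If False, only the centerline and markers are emitted (fast path).
    """
    if n_angular < 8:
        raise InvalidParameterError("n_angular must be >= 8")
    geo = _TubeGeometry(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cl_s = geo.stations(centerline_spacing)
    cl_s = np.unique(np.concatenate([cl_s, [geo.s_renal, geo.s_distal]]))
    cl_points = np.array([geo.position(s) for s in cl_s])
    centerline = CenterLumenLine(cl_points)

    renal = geo.position(geo.s_renal)
    distal = geo.position(geo.s_distal)

    surface = None
    if with_mesh:
        ring_s = geo.stations(axial_spacing)
        ring_s = np.unique(np.concatenate([ring_s, [geo.s_renal, geo.s_distal]]))
        e1, e2 = geo.frames(ring_s)
        psi = 2 * np.pi * np.arange(n_angular) / n_angular
        cos_p, sin_p = np.cos(psi), np.sin(psi)
        n_rings = len(ring_s)
        verts = np.empty((n_rings, n_angular, 3))
        for i, s in enumerate(ring_s):
            r = geo.radius(s)
            radii = r + (
                rng.normal(0.0, params.surface_noise_sd, n_angular)
                if params.surface_noise_sd > 0
                else 0.0
            )
            ring = (
                geo.position(s)[None, :]
                + (radii * cos_p)[:, None] * e1[i][None, :]
                + (radii * sin_p)[:, None] * e2[i][None, :]
            )
            verts[i] = ring
        vertices = verts.reshape(-1, 3)

        faces = []
        for i in range(n_rings - 1):
            base, nxt = i * n_angular, (i + 1) * n_angular
            for k in range(n_angular):
                k1 = (k + 1) % n_angular
                faces.append((base + k, base + k1, nxt + k1))
                faces.append((base + k, nxt + k1, nxt + k))
        # cap fans (apex at the centerline ends) keep the tube watertight
        top_apex = len(vertices)
        bot_apex = top_apex + 1
        vertices = np.vstack([vertices, geo.position(cl_s[0]), geo.position(cl_s[-1])])
        last = (n_rings - 1) * n_angular
        for k in range(n_angular):
            k1 = (k + 1) % n_angular
            faces.append((top_apex, k1, k))
            faces.append((bot_apex, last + k, last + k1))
        surface = LumenSurface(vertices=vertices, faces=np.asarray(faces, dtype=np.int64))

    return SyntheticSubject(
        subject_id="",
        group="",
        surface=surface,
        centerline=centerline,
        renal_marker=renal,
        distal_marker=distal,
        true_params=params,
    )


def analytic_landmarks(
    params: NeckParams,
    n_levels: int = 10,
    n_angles: int = 360,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Landmark grid straight from the closed-form tube geometry.

    Produces the same (n_levels, n_angles, 3) grid as mesh contour
    extraction would — levels equally spaced in arc length from the renal
    baseline to the distal neck end, azimuth 0 at the projection of the
    anterior axis onto each cutting plane, counterclockwise viewed from
    cranial — but without building or sectioning a mesh.  Radial Gaussian
    noise of sd ``surface_noise_sd`` emulates segmentation roughness.
    """
    geo = _TubeGeometry(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_levels = np.linspace(geo.s_renal, geo.s_distal, n_levels)
    phi = 2 * np.pi * np.arange(n_angles) / n_angles
    grid = np.empty((n_levels, n_angles, 3))
    for i, s in enumerate(s_levels):
        t = geo.tangent(s)
        proj = _Y - (_Y @ t) * t
        e1 = _normalize(proj) if np.linalg.norm(proj) >= 1e-6 else _normalize(_X - (_X @ t) * t)
        m = t if t @ _Z > 0 else -t  # cranial-pointing plane normal
        e2 = np.cross(m, e1)
        radii = geo.radius(s) + (
            rng.normal(0.0, params.surface_noise_sd, n_angles)
            if params.surface_noise_sd > 0
            else 0.0
        )
        grid[i] = (
            geo.position(s)[None, :]
            + (radii * np.cos(phi))[:, None] * e1[None, :]
            + (radii * np.sin(phi))[:, None] * e2[None, :]
        )
    return grid


# ---------------------------------------------------------------------------
# cohort sampling and calibrated group defaults
# ---------------------------------------------------------------------------


def default_case_spec(n_subjects: int = 63) -> GroupSpec:
    """Group spec calibrated to the published late-endoleak (case) summaries."""
    return GroupSpec(
        n_subjects=n_subjects,
        length_median=13.0,
        length_sigma=1.046,  # ln(24.6/6.0) / (2 * 0.67449)
        diameter_median=26.1,
        diameter_sigma=0.1318,  # ln(27.6/23.1) / 1.349
        supra_median_deg=36.0,
        supra_scale_deg=25.6,  # (59.0 - 24.5) / 1.349
        infra_median_deg=52.0,
        infra_scale_deg=21.9,  # (69.5 - 40.0) / 1.349
        calcification_probs=(0.78, 0.12, 0.10),
        thrombus_probs=(0.50, 0.25, 0.25),
    )


def default_control_spec(n_subjects: int = 63) -> GroupSpec:
    """Group spec calibrated to the published control-group summaries."""
    return GroupSpec(
        n_subjects=n_subjects,
        length_median=26.0,
        length_sigma=0.621,  # ln(37.0/16.0) / 1.349
        diameter_median=24.3,
        diameter_sigma=0.0837,  # ln(25.3/22.6) / 1.349
        supra_median_deg=30.0,
        supra_scale_deg=17.05,  # (42.0 - 19.0) / 1.349
        infra_median_deg=47.0,
        infra_scale_deg=18.2,  # (61.0 - 36.5) / 1.349
        calcification_probs=(0.48, 0.28, 0.24),
        thrombus_probs=(0.49, 0.25, 0.26),
    )


def sample_cohort(
    case_spec: GroupSpec | None = None,
    control_spec: GroupSpec | None = None,
    seed: int = 0,
    geometry: Literal["mesh", "centerline", "params"] = "mesh",
    n_angular: int = 96,
    axial_spacing: float = 1.0,
) -> list[SyntheticSubject]:
    """Draw a full case/control cohort, deterministically for a given seed.

    ``geometry`` selects how much of each subject is materialized:
    ``"mesh"`` builds the full surface, ``"centerline"`` skips the mesh
    (landmarks can still be produced by :func:`analytic_landmarks`), and
    ``"params"`` skips geometry entirely (for distribution-level checks).
    """
    case_spec = case_spec if case_spec is not None else default_case_spec()
    control_spec = control_spec if control_spec is not None else default_control_spec()
    root = np.random.SeedSequence(seed)
    param_seq, *subject_seqs = root.spawn(1 + case_spec.n_subjects + control_spec.n_subjects)
    param_rng = np.random.default_rng(param_seq)

    all_params = [(p, "case") for p in case_spec.sample_params(param_rng)]
    all_params += [(p, "control") for p in control_spec.sample_params(param_rng)]

    subjects = []
    for idx, ((params, group), seq) in enumerate(zip(all_params, subject_seqs)):
        rng = np.random.default_rng(seq)
        if geometry == "params":
            subj = SyntheticSubject(
                subject_id="", group=group, surface=None,
                centerline=CenterLumenLine(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0]])),
                renal_marker=np.zeros(3), distal_marker=np.zeros(3), true_params=params,
            )
        else:
            subj = generate_neck_geometry(
                params,
                n_angular=n_angular,
                axial_spacing=axial_spacing,
                seed=rng,
                with_mesh=(geometry == "mesh"),
            )
            subj.group = group
        subj.subject_id = f"{group}_{idx:03d}"
        subj.group = group
        subjects.append(subj)
    return subjects


# ---------------------------------------------------------------------------
# on-disk form: PLY surface + JSON sidecar + cohort table row
# ---------------------------------------------------------------------------


def write_subject(subject: SyntheticSubject, out_dir: str | Path, binary_ply: bool = False) -> dict:
    """Write one subject (PLY mesh + JSON sidecar); returns its table row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if subject.surface is not None:
        subject.surface.to_trimesh().export(
            out_dir / f"{subject.subject_id}.ply", encoding="binary" if binary_ply else "ascii"
        )
    sidecar = {
        "centerline": np.asarray(subject.centerline.points).tolist(),
        "renal": np.asarray(subject.renal_marker).tolist(),
        "distal": np.asarray(subject.distal_marker).tolist(),
    }
    (out_dir / f"{subject.subject_id}.json").write_text(json.dumps(sidecar))
    p = subject.true_params
    return {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "neck_length_mm": p.neck_length,
        "proximal_diameter_mm": p.proximal_diameter,
        "taper_fraction": p.taper_fraction,
        "suprarenal_angle_deg": p.suprarenal_angle,
        "infrarenal_angle_deg": p.infrarenal_angle,
        "bend_plane_azimuth_deg": p.bend_plane_azimuth,
        "calcification_cat": p.calcification_cat,
        "thrombus_cat": p.thrombus_cat,
        "surface_noise_sd_mm": p.surface_noise_sd,
    }
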