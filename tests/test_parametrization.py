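"""Distal-end detection, level resampling, contour extraction, alignment."""

import numpy as np
import pytest
import trimesh

import neckssm as ns
from neckssm.errors import DegenerateSegmentError, NoDistalEndError
from neckssm.parametrization import (
    CenterLumenLine,
    LumenSurface,
    ParametrizedNeck,
    align_necks,
    extract_contours,
    resample_centerline,
    CenterlineLevels,
)


def _cylinder_surface(radius=12.0, height=80.0, sections=128):
    mesh = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    return LumenSurface.from_trimesh(mesh)


class TestLocateDistalNeckEnd:
    def test_detected_end_near_generator_marker(self, straight_subject):
        point, s = ns.locate_distal_neck_end(
            straight_subject.surface, straight_subject.centerline, straight_subject.renal_marker
        )
        assert np.linalg.norm(point - straight_subject.distal_marker) < 1.0

    def test_pure_cylinder_never_satisfies_rule(self):
        p = ns.NeckParams(neck_length=25.0, proximal_diameter=24.0,
                          taper_fraction=0.0, sac_flare_fraction=0.0,
                          surface_noise_sd=0.0)
        s = ns.generate_neck_geometry(p, seed=0)
        with pytest.raises(NoDistalEndError):
            ns.locate_distal_neck_end(s.surface, s.centerline, s.renal_marker)

    def test_linear_taper_crosses_threshold_at_closed_form_location(self):
        # diameter grows linearly to +20% over 30 mm -> +10% at 15 mm
        p = ns.NeckParams(neck_length=30.0, proximal_diameter=24.0,
                          taper_fraction=0.20, surface_noise_sd=0.0)
        s = ns.generate_neck_geometry(p, seed=0)
        _, s_hit = ns.locate_distal_neck_end(s.surface, s.centerline, s.renal_marker, step=0.5)
        s_renal = s.centerline.project(s.renal_marker)
        assert s_hit - s_renal == pytest.approx(15.0, abs=0.5)


class TestResampleCenterline:
    def test_equal_spacing_on_straight_segment(self):
        z = np.linspace(0, -40, 161)
        cll = CenterLumenLine(np.c_[np.zeros_like(z), np.zeros_like(z), z])
        renal = np.array([0.0, 0.0, -5.0])
        distal = np.array([0.0, 0.0, -32.0])  # 27 mm apart -> 3 mm spacing
        levels = resample_centerline(cll, renal, distal, n_levels=10)
        spacing = np.diff(levels.arclengths)
        assert np.allclose(spacing, 3.0, atol=1e-9)

    def test_coincident_markers_rejected(self):
        z = np.linspace(0, -40, 81)
        cll = CenterLumenLine(np.c_[np.zeros_like(z), np.zeros_like(z), z])
        m = np.array([0.0, 0.0, -10.0])
        with pytest.raises(DegenerateSegmentError):
            resample_centerline(cll, m, m)

    def test_semicircle_tangents_perpendicular_to_radius(self):
        R = 25.0
        theta = np.linspace(0, np.pi, 400)
        pts = np.c_[R * np.cos(theta), np.zeros_like(theta), -R * np.sin(theta)]
        cll = CenterLumenLine(pts)
        levels = resample_centerline(cll, pts[20], pts[-20], n_levels=10)
        center = np.zeros(3)
        for p, t in zip(levels.points, levels.tangents):
            radial = p - center
            assert abs(np.linalg.norm(t) - 1.0) < 1e-9
            assert abs(t @ radial) / np.linalg.norm(radial) < 5e-3


class TestExtractContours:
    def test_cylinder_levels_are_circles(self):
        surf = _cylinder_surface(radius=12.0, sections=256)
        pts = np.array([[0, 0, -20.0], [0, 0, 0.0], [0, 0, 20.0]])
        tangents = np.tile([0.0, 0.0, 1.0], (3, 1))
        levels = CenterlineLevels(points=pts, tangents=tangents, arclengths=np.array([0, 20, 40.0]))
        neck = extract_contours(surf, levels, n_angles=360)
        for i in range(3):
            radii = np.linalg.norm(neck.landmarks[i] - pts[i], axis=1)
            assert np.abs(radii - 12.0).max() < 12.0 * (1 - np.cos(np.pi / 256)) + 1e-6

    def test_tilted_plane_gives_ellipse(self):
        """A plane tilted by theta cuts a cylinder in an ellipse with semi-axes
        r and r/cos(theta); sampled radii must match the closed-form
        ray-cylinder intersection."""
        r = 10.0
        theta = np.deg2rad(30.0)
        surf = _cylinder_surface(radius=r, height=120.0, sections=256)
        normal = np.array([0.0, np.sin(theta), np.cos(theta)])
        levels = CenterlineLevels(
            points=np.array([[0.0, 0.0, 0.0]]),
            tangents=normal[None, :],
            arclengths=np.array([0.0]),
        )
        neck = extract_contours(surf, levels, n_angles=180)
        lm = neck.landmarks[0]
        radii = np.linalg.norm(lm, axis=1)
        # independent oracle: ray from origin in the cutting plane hits the
        # infinite cylinder x^2 + y^2 = r^2 at t = r / ||(d_x, d_y)||
        from neckssm.parametrization import plane_basis

        e1, e2 = plane_basis(normal)
        phi = 2 * np.pi * np.arange(180) / 180
        d = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        expected = r / np.linalg.norm(d[:, :2], axis=1)
        assert np.abs(radii - expected).max() < 0.05
        assert expected.max() == pytest.approx(r / np.cos(theta), rel=1e-6)

    def test_mesh_refinement_converges(self, bent_params):
        coarse = ns.generate_neck_geometry(bent_params, n_angular=48, axial_spacing=2.0, seed=0)
        fine = ns.generate_neck_geometry(bent_params, n_angular=192, axial_spacing=0.5, seed=0)
        kw = dict(n_levels=6, n_angles=48)
        lm_c = ns.parametrize_subject(coarse.surface, coarse.centerline, coarse.renal_marker, **kw)
        lm_f = ns.parametrize_subject(fine.surface, fine.centerline, fine.renal_marker, **kw)
        coarse_edge = max(2 * np.pi * 14.0 / 48, 2.0)
        assert np.linalg.norm(lm_c.landmarks - lm_f.landmarks, axis=2).max() < coarse_edge

    def test_contour_closure_spacing_bounded(self, bent_subject):
        neck = ns.parametrize_subject(
            bent_subject.surface, bent_subject.centerline, bent_subject.renal_marker,
            n_levels=5, n_angles=90,
        )
        for i in range(5):
            ring = neck.landmarks[i]
            c = ring.mean(axis=0)
            r_max = np.linalg.norm(ring - c, axis=1).max()
            gaps = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
            assert gaps.max() <= 2 * np.pi * r_max / 90 * 1.5

    def test_degenerate_anterior_reference_falls_back(self):
        """Tangent parallel to the anterior axis: the +x projection takes over."""
        mesh = trimesh.creation.cylinder(radius=8.0, height=60.0, sections=64)
        mesh.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0]))
        surf = LumenSurface.from_trimesh(mesh)  # axis now along y
        levels = CenterlineLevels(
            points=np.zeros((1, 3)),
            tangents=np.array([[0.0, 1.0, 0.0]]),
            arclengths=np.array([0.0]),
        )
        neck = extract_contours(surf, levels, n_angles=36)
        radii = np.linalg.norm(neck.landmarks[0], axis=1)
        assert np.abs(radii - 8.0).max() < 0.1


class TestAlignment:
    def test_translation_invariance_exact(self, bent_subject):
        neck = ns.parametrize_subject(
            bent_subject.surface, bent_subject.centerline, bent_subject.renal_marker,
            n_levels=6, n_angles=60,
        )
        shifted = ParametrizedNeck(
            landmarks=neck.landmarks + np.array([13.0, -7.0, 42.0]),
            level_arclengths=neck.level_arclengths,
        )
        a, b = align_necks([neck, shifted])
        assert np.abs(a.landmarks - b.landmarks).max() < 1e-9

    def test_rotation_about_z_invariance_on_straight_tube(self, straight_params):
        """Rotating all of a subject's inputs by 90 deg about the cranial axis
        leaves the aligned grid unchanged (sampling pattern maps onto itself
        because the ring count divides the rotation)."""
        s = ns.generate_neck_geometry(straight_params, n_angular=96, seed=0)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rot_surface = LumenSurface(vertices=s.surface.vertices @ Rz.T, faces=s.surface.faces)
        rot_cll = CenterLumenLine(s.centerline.points @ Rz.T)
        kw = dict(n_levels=6, n_angles=48)
        neck = ns.parametrize_subject(s.surface, s.centerline, s.renal_marker, **kw)
        rot_neck = ns.parametrize_subject(rot_surface, rot_cll, Rz @ s.renal_marker, **kw)
        a, b = align_necks([neck, rot_neck])
        assert np.abs(a.landmarks - b.landmarks).max() < 1e-9

    def test_alignment_idempotent(self, small_cohort):
        necks, _ = small_cohort
        twice = align_necks(necks)
        for n1, n2 in zip(necks, twice):
            assert np.abs(n1.landmarks - n2.landmarks).max() < 1e-12

    def test_canonical_frame_postconditions(self, small_cohort):
        necks, _ = small_cohort
        for n in necks:
            ring0 = n.landmarks[0]
            assert np.linalg.norm(ring0.mean(axis=0)) < 1e-9  # centroid at origin
            assert np.abs(ring0[:, 2]).max() < 1e-6  # renal baseline in z=0 plane
            a = ring0[0] / np.linalg.norm(ring0[0])
            assert a[1] == pytest.approx(1.0, abs=1e-6)  # azimuth 0 maps to +y

    def test_mismatched_grids_rejected(self, small_cohort):
        necks, _ = small_cohort
        bad = ParametrizedNeck(
            landmarks=np.zeros((4, 12, 3)) + np.random.default_rng(0).normal(size=(4, 12, 3)),
            level_arclengths=np.zeros(4),
        )
        with pytest.raises(ns.NeckSSMError):
            align_necks([necks[0], bad])
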