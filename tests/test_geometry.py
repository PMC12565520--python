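"""Geometry engine: slicing, wedge volumes, closure, non-overlap metrics.

Prism-phantom oracles are derived independently of the mesh pipeline: the
conventional wedge is a triangular prism (½·W²·tanθ·D); oblique/hybrid
wedge cross-sections are triangles between two coronal lines through the
hinge, integrated exactly with the trapezoid rule on a linear integrand.
"""

import math

import numpy as np
import pytest
import shapely
import trimesh

import cwhto
from cwhto import (
    GeometryError,
    Plane,
    Technique,
    build_frame,
    closure_transform,
    compute_nonoverlap,
    execute_plan,
    plan_osteotomy,
    simulate_knee,
)
from cwhto.geometry import CutFace

THETAS = (12.0, 15.0, 18.0)
W, D, H = 60.0, 45.0, 100.0


def prism_oblique_wedge_oracle(fraction: float, theta_deg: float) -> float:
    """Numerical-integration oracle for the prism wedge lateral of a hinge
    at `fraction` of the 15/35 mm oblique chord.

    In the coronal (x, z) plane the proximal cut is the line through
    (-30, -15) and (30, -35); the distal cut is that line rotated by theta
    about the hinge.  The wedge section is the area between them, clipped
    to the prism wall x <= 30, integrated by the trapezoid rule (exact for
    the piecewise-linear integrand).
    """
    theta = math.radians(theta_deg)
    med = np.array([-30.0, -15.0])
    lat = np.array([30.0, -35.0])
    slope0 = (lat[1] - med[1]) / (lat[0] - med[0])
    hinge = med + fraction * (lat - med)
    phi = math.atan(-slope0)
    slope1 = math.tan(-(phi + theta))
    x = np.linspace(hinge[0], 30.0, 20001)
    z0 = med[1] + slope0 * (x - med[0])
    z1 = hinge[1] + slope1 * (x - hinge[0])
    return float(np.trapezoid(np.maximum(z0 - z1, 0.0), x)) * D


class TestSliceMesh:
    def test_unit_cube_bisection(self):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        pos, neg, face = cwhto.slice_mesh(cube, Plane([0, 0, 0], [0, 0, 1]))
        assert pos.volume == pytest.approx(0.5, rel=1e-12)
        assert neg.volume == pytest.approx(0.5, rel=1e-12)
        assert face.area == pytest.approx(1.0, rel=1e-12)
        assert pos.is_watertight and neg.is_watertight

    def test_oblique_prism_face_is_tilted_rectangle(self, prism):
        """Slicing through (-30, z1) and (30, z2) gives a rectangle of
        width D and length sqrt(W^2 + (z2 - z1)^2)."""
        mesh, _ = prism
        z1, z2 = -15.0, -35.0
        normal = np.cross([W, 0.0, z2 - z1], [0.0, 1.0, 0.0])
        pos, neg, face = cwhto.slice_mesh(mesh, Plane([-30, 0, z1], normal))
        expected = D * math.sqrt(W**2 + (z2 - z1) ** 2)
        assert face.area == pytest.approx(expected, rel=1e-9)
        assert pos.volume + neg.volume == pytest.approx(mesh.volume, rel=1e-12)

    def test_plane_missing_mesh_raises(self, prism):
        mesh, _ = prism
        with pytest.raises(GeometryError):
            cwhto.slice_mesh(mesh, Plane([0, 0, 50.0], [0, 0, 1]))

    def test_non_watertight_input_rejected(self):
        open_mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(cwhto.ValidationError):
            cwhto.slice_mesh(open_mesh, Plane([0, 0, 0], [0, 0, 1]))


class TestMeshVolume:
    def test_known_volumes(self, prism):
        mesh, _ = prism
        assert cwhto.mesh_volume(mesh) == pytest.approx(W * D * H, rel=1e-12)
        cube = trimesh.creation.box(extents=[1, 1, 1])
        assert cwhto.mesh_volume(cube) == pytest.approx(1.0, rel=1e-12)

    def test_inverted_orientation_rejected(self):
        cube = trimesh.creation.box(extents=[1, 1, 1])
        cube.invert()
        with pytest.raises(cwhto.ValidationError):
            cwhto.mesh_volume(cube)


class TestWedgeVolumes:
    @pytest.mark.parametrize("theta", THETAS)
    def test_conventional_prism_closed_form(self, prism, theta):
        mesh, lm = prism
        plan = plan_osteotomy(mesh, build_frame(lm), Technique.CONVENTIONAL, theta)
        execution = execute_plan(mesh, plan)
        expected = 0.5 * W**2 * math.tan(math.radians(theta)) * D
        assert execution.wedge.volume == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("technique,fraction", [
        (Technique.OBLIQUE, 0.0),
        (Technique.HYBRID_3_1, 0.25),
        (Technique.HYBRID_2_1, 1.0 / 3.0),
    ])
    @pytest.mark.parametrize("theta", THETAS)
    def test_oblique_family_prism_oracle(self, prism, technique, fraction, theta):
        mesh, lm = prism
        plan = plan_osteotomy(mesh, build_frame(lm), technique, theta)
        execution = execute_plan(mesh, plan)
        expected = prism_oblique_wedge_oracle(fraction, theta)
        assert execution.wedge.volume == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("technique", list(Technique))
    def test_volume_conservation(self, tibia, technique):
        mesh, lm = tibia
        frame = build_frame(lm)
        for theta in THETAS:
            e = execute_plan(mesh, plan_osteotomy(mesh, frame, technique, theta))
            total = (e.proximal_fragment.volume + e.distal_fragment.volume
                     + e.wedge.volume)
            assert total == pytest.approx(mesh.volume, rel=1e-6)

    def test_wedge_monotone_in_theta(self, tibia):
        mesh, lm = tibia
        frame = build_frame(lm)
        for technique in Technique:
            vols = [execute_plan(mesh, plan_osteotomy(mesh, frame, technique, th)
                                 ).wedge.volume for th in THETAS]
            assert vols[0] < vols[1] < vols[2]

    def test_hinge_arm_subset_ordering(self, tibia):
        """Same proximal plane, shorter lateral arm => smaller wedge."""
        mesh, lm = tibia
        frame = build_frame(lm)
        vols = {t: execute_plan(mesh, plan_osteotomy(mesh, frame, t, 15.0)
                                ).wedge.volume
                for t in (Technique.OBLIQUE, Technique.HYBRID_3_1,
                          Technique.HYBRID_2_1)}
        assert vols[Technique.HYBRID_2_1] < vols[Technique.HYBRID_3_1] \
            < vols[Technique.OBLIQUE]

    def test_tiny_theta_gives_tiny_wedge(self, prism):
        mesh, lm = prism
        plan = plan_osteotomy(mesh, build_frame(lm), Technique.CONVENTIONAL, 1e-4)
        e = execute_plan(mesh, plan)
        assert e.wedge.volume < 1.0  # -> 0 as theta -> 0

    def test_kerf_removes_extra_bone(self, prism):
        mesh, lm = prism
        plan = plan_osteotomy(mesh, build_frame(lm), Technique.CONVENTIONAL, 12.0)
        e0 = execute_plan(mesh, plan, kerf=0.0)
        e1 = execute_plan(mesh, plan, kerf=1.0)
        parts1 = (e1.proximal_fragment.volume + e1.distal_fragment.volume
                  + e1.wedge.volume)
        assert parts1 < mesh.volume  # kerf slabs are gone
        assert e1.proximal_fragment.volume < e0.proximal_fragment.volume


class TestClosure:
    @pytest.mark.parametrize("technique", list(Technique))
    def test_closure_maps_distal_onto_proximal_plane(self, tibia, technique):
        mesh, lm = tibia
        frame = build_frame(lm)
        plan = plan_osteotomy(mesh, frame, technique, 15.0)
        T = closure_transform(plan)
        R = T[:3, :3]
        # isometry
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
        # distal plane -> proximal plane
        assert np.allclose(R @ plan.distal_plane.normal,
                           plan.proximal_plane.normal, atol=1e-9)
        # every point of the distal cut lands on the proximal plane
        e = execute_plan(mesh, plan)
        from cwhto._mesh import section_loops
        pts = np.vstack(section_loops(mesh, plan.distal_plane.point,
                                      plan.distal_plane.normal))
        closed = pts @ R.T + T[:3, 3]
        dist = np.abs(plan.proximal_plane.signed_distance(closed))
        assert dist.max() < 1e-6
        # area preserved by the isometry
        assert e.distal_face.area > 0

    def test_inverse_composition_is_identity(self, prism):
        mesh, lm = prism
        plan = plan_osteotomy(mesh, build_frame(lm), Technique.OBLIQUE, 15.0)
        T = closure_transform(plan)
        angle, axis, point = trimesh.transformations.rotation_from_matrix(T)
        assert abs(abs(angle) - math.radians(15.0)) < 1e-12
        Tinv = trimesh.transformations.rotation_matrix(-angle, axis, point)
        assert np.allclose(T @ Tinv, np.eye(4), atol=1e-12)


def _rect_face(u0, u1, v0, v1, plan):
    poly = shapely.MultiPolygon([shapely.box(u0, v0, u1, v1)])
    return CutFace(plane=plan.proximal_plane, boundary=poly,
                   chart_origin=plan.hinge_point,
                   u_axis=plan.chord_direction, v_axis=plan.hinge_axis)


@pytest.fixture(scope="module")
def prism_plan(prism):
    mesh, lm = prism
    return plan_osteotomy(mesh, build_frame(lm), Technique.CONVENTIONAL, 12.0)


class TestNonOverlap:
    def test_identical_faces_fully_overlap(self, prism_plan):
        face = _rect_face(0, 60, -22.5, 22.5, prism_plan)
        m = compute_nonoverlap(face, face, prism_plan)
        assert m.overlap_area == pytest.approx(60 * 45, rel=1e-9)
        assert m.nonoverlap_total_difference == 0
        assert m.nonoverlap_lateral == 0
        assert m.nonoverlap_medial == 0
        assert m.nonoverlap_signed == 0

    def test_medial_shift_creates_lateral_strip(self, prism_plan):
        """Distal face shifted 5 mm medially uncovers a 5 x 45 lateral strip."""
        prox = _rect_face(0, 60, -22.5, 22.5, prism_plan)
        dist = _rect_face(-5, 55, -22.5, 22.5, prism_plan)
        m = compute_nonoverlap(prox, dist, prism_plan)
        assert m.nonoverlap_lateral == pytest.approx(225.0, rel=1e-9)
        assert m.nonoverlap_medial == 0
        assert m.distal_overhang_medial == pytest.approx(225.0, rel=1e-9)
        assert m.nonoverlap_signed == pytest.approx(225.0, rel=1e-9)

    def test_prism_conventional_distal_face_protrudes(self, prism):
        """On a uniform prism the closed distal face is longer than the
        proximal one by W(1/cosθ − 1), so the overhang belongs to the
        distal fragment."""
        mesh, lm = prism
        r = simulate_knee(mesh, lm, Technique.CONVENTIONAL, 12.0)
        expected = W * (1 / math.cos(math.radians(12.0)) - 1) * D
        assert r.nonoverlap_lateral == pytest.approx(0.0, abs=1e-9)
        assert r.distal_overhang_lateral == pytest.approx(expected, rel=1e-6)
        assert r.lateral_overhang_fragment == "distal"

    def test_empty_face_raises(self, prism_plan):
        face = _rect_face(0, 60, -22.5, 22.5, prism_plan)
        empty = CutFace(plane=prism_plan.proximal_plane,
                        boundary=shapely.MultiPolygon([]),
                        chart_origin=prism_plan.hinge_point,
                        u_axis=prism_plan.chord_direction,
                        v_axis=prism_plan.hinge_axis)
        with pytest.raises(GeometryError):
            compute_nonoverlap(face, empty, prism_plan)


class TestSimulateKnee:
    @pytest.mark.parametrize("technique,fraction", [
        (Technique.HYBRID_3_1, 0.25),
        (Technique.HYBRID_2_1, 1.0 / 3.0),
    ])
    def test_medial_gap_ratio_uniform_sections(self, prism, technique, fraction):
        """On a uniform prism the medial gap is exactly (f/(1-f))^2 of the
        lateral wedge: 1/9 for the 3:1 hinge, 1/4 for 2:1."""
        mesh, lm = prism
        r = simulate_knee(mesh, lm, technique, 15.0)
        expected = (fraction / (1 - fraction)) ** 2
        assert r.medial_gap_volume / r.wedge_volume == pytest.approx(
            expected, rel=1e-6)

    def test_no_medial_gap_for_cortical_hinges(self, prism):
        mesh, lm = prism
        for technique in (Technique.CONVENTIONAL, Technique.OBLIQUE):
            r = simulate_knee(mesh, lm, technique, 15.0)
            assert r.medial_gap_volume == 0.0

    def test_signed_nonoverlap_convention(self, tibia):
        """Hybrids open medially (negative), conventional/oblique overhang
        laterally (positive)."""
        mesh, lm = tibia
        for technique in Technique:
            r = simulate_knee(mesh, lm, technique, 15.0)
            if technique.is_hybrid:
                assert r.nonoverlap_signed < 0
                assert r.nonoverlap_signed == -r.nonoverlap_medial
            else:
                assert r.nonoverlap_signed > 0
                assert r.nonoverlap_signed == r.nonoverlap_lateral

    def test_overlap_bounded_by_face_areas(self, tibia):
        mesh, lm = tibia
        for technique in Technique:
            r = simulate_knee(mesh, lm, technique, 12.0)
            assert r.overlap_area <= min(r.proximal_area, r.distal_area) + 1e-6

    def test_scalar_metrics_equivariant_under_rigid_motion(self, prism):
        mesh, lm = prism
        T = trimesh.transformations.rotation_matrix(
            0.7, [0.36, 0.48, 0.8], [5.0, -3.0, 11.0])
        T[:3, 3] += [12.0, -7.0, 30.0]
        moved = mesh.copy()
        moved.apply_transform(T)
        a = simulate_knee(mesh, lm, Technique.HYBRID_2_1, 15.0)
        b = simulate_knee(moved, lm.transformed(T), Technique.HYBRID_2_1, 15.0)
        for attr in ("proximal_area", "distal_area", "wedge_volume",
                     "medial_gap_volume", "overlap_area", "nonoverlap_signed"):
            va, vb = getattr(a, attr), getattr(b, attr)
            assert vb == pytest.approx(va, rel=1e-6, abs=1e-4), attr
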