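"""Execution of an osteotomy plan on a mesh and measurement of the
resulting surfaces, volumes, and post-closure non-overlap.

Cut topology.  With the proximal cut plane P0 and the distal cut plane P1
(P0 rotated by θ about the AP hinge axis), the bone decomposes into

* the proximal fragment (above P0),
* the resected wedge (below P0 and above P1 — this dihedral region lies
  lateral of the hinge because the planes cross along the hinge axis),
* the distal fragment (the remainder).

Closure rotates the distal fragment by θ about the hinge axis, mapping P1
exactly onto P0.  All post-closure area bookkeeping happens in a 2D chart
of the proximal plane with the hinge at the origin, +u along the
medial→lateral cut chord and +v along the AP axis.

For the hybrid techniques the hinge sits inside the bone, so closing the
lateral gap opens a small medial one.  Its volume is measured as the
region of the intact bone above P0 and below the medial extension of P1 —
the mirror dihedral of the resected wedge, i.e. the opening as seen from
the distal fragment.  On a uniform cross-section this makes the
medial-gap : lateral-wedge volume ratio exactly (f/(1−f))² for a hinge at
chord fraction f, which is the closed-form the hinge-ratio semantics are
anchored to (1/9 for the 3:1 hinge).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import shapely
import trimesh

from . import _mesh
from ._mesh import mesh_volume, section_polygon, slice_capped, validate_mesh
from .errors import GeometryError
from .phantoms import LandmarkSet
from .planning import (
    OsteotomyPlan,
    Plane,
    Technique,
    build_frame,
    plan_osteotomy,
)

__all__ = [
    "CutFace",
    "SimulationResult",
    "ExecutionResult",
    "slice_mesh",
    "execute_plan",
    "mesh_volume",
    "closure_transform",
    "compute_nonoverlap",
    "simulate_knee",
]

DEFAULT_SCANLINE_STEP = 0.25  # mm, AP sampling step of the overhang scanline


@dataclass(frozen=True)
class CutFace:
    """A planar cut face: its plane, 2D chart, and boundary polygons.

    ``boundary`` is a shapely MultiPolygon in the orthonormal chart
    ``(chart_origin, u_axis, v_axis)``; for plan-derived faces the origin is
    the hinge point and +u runs along the medial→lateral cut chord.
    """

    plane: Plane
    boundary: shapely.MultiPolygon
    chart_origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    @property
    def area(self) -> float:
        return float(self.boundary.area)


@dataclass
class ExecutionResult:
    """Fragments and cut faces produced by executing a plan."""

    proximal_fragment: trimesh.Trimesh
    distal_fragment: trimesh.Trimesh
    wedge: trimesh.Trimesh
    proximal_face: CutFace
    distal_face: CutFace  # lateral-of-hinge portion, in closed position


@dataclass
class SimulationResult:
    """All scalar metrics of one knee × technique × angle simulation.

    Areas in mm², volumes in mm³.  ``nonoverlap_lateral`` /
    ``nonoverlap_medial`` are the scanline-integrated strips of the
    proximal cut face left uncovered by the closed distal face on each
    side; ``distal_overhang_lateral`` / ``..._medial`` are the mirror
    quantities for the distal face protruding beyond the proximal one.
    ``nonoverlap_signed`` is positive for a lateral overhang
    (conventional / oblique) and negative for a medial opening (hybrids).
    """

    knee_id: str
    technique: str
    theta: float
    proximal_area: float
    distal_area: float
    wedge_volume: float
    medial_gap_volume: float
    overlap_area: float
    nonoverlap_lateral: float
    nonoverlap_medial: float
    nonoverlap_signed: float
    nonoverlap_total_difference: float
    distal_overhang_lateral: float
    distal_overhang_medial: float
    lateral_overhang_fragment: str

    def to_dict(self) -> dict:
        return asdict(self)


def slice_mesh(
    mesh: trimesh.Trimesh, plane: Plane
) -> tuple[trimesh.Trimesh, trimesh.Trimesh, CutFace]:
    """Cut a watertight mesh with a plane into two watertight, capped parts.

    Returns ``(positive_part, negative_part, face)`` where the positive part
    lies on the side the plane normal points toward and ``face`` is the
    capped cross-section in a default chart of the plane.
    """
    validate_mesh(mesh)
    pos = slice_capped(mesh, plane.point, plane.normal, keep_positive=True)
    neg = slice_capped(mesh, plane.point, plane.normal, keep_positive=False)
    u, v = _mesh.plane_chart(plane.normal)
    boundary = section_polygon(mesh, plane.point, plane.normal,
                               plane.point, u, v)
    face = CutFace(plane=plane, boundary=boundary,
                   chart_origin=plane.point, u_axis=u, v_axis=v)
    return pos, neg, face


def closure_transform(plan: OsteotomyPlan) -> np.ndarray:
    """4x4 rigid rotation about the hinge axis mapping the distal plane onto
    the proximal plane (gap closure)."""
    for sign in (1.0, -1.0):
        R = trimesh.transformations.rotation_matrix(
            sign * plan.theta_rad, plan.hinge_axis, plan.hinge_point
        )
        n = R[:3, :3] @ plan.distal_plane.normal
        if np.linalg.norm(n - plan.proximal_plane.normal) < 1e-9:
            return R
    raise GeometryError("closure rotation does not map distal onto proximal plane")


def _plan_chart(plan: OsteotomyPlan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(origin, u, v): hinge-centred chart of the proximal plane."""
    u = plan.chord_direction
    v = plan.hinge_axis
    return plan.hinge_point, u, v


def execute_plan(
    mesh: trimesh.Trimesh, plan: OsteotomyPlan, kerf: float = 0.0
) -> ExecutionResult:
    """Cut the bone: proximal fragment, resected wedge, distal fragment.

    The distal cut face is reported in its closed position (rotated onto
    the proximal plane) and covers only the physical cut lateral of the
    hinge.  With the default zero saw kerf the volumes of the three pieces
    sum to the original mesh volume; a positive ``kerf`` removes an extra
    slab of that thickness, split symmetrically about each cutting plane.
    """
    validate_mesh(mesh)
    if kerf < 0:
        raise GeometryError("kerf must be non-negative")
    p0, p1 = plan.proximal_plane, plan.distal_plane
    h0 = 0.5 * kerf * p0.normal
    h1 = 0.5 * kerf * p1.normal
    proximal = slice_capped(mesh, p0.point + h0, p0.normal, keep_positive=True)
    below = slice_capped(mesh, p0.point - h0, p0.normal, keep_positive=False)
    wedge = slice_capped(below, p1.point + h1, p1.normal, keep_positive=True)
    distal = slice_capped(below, p1.point - h1, p1.normal, keep_positive=False)

    origin, u, v = _plan_chart(plan)
    proximal_face = CutFace(
        plane=p0,
        boundary=section_polygon(mesh, p0.point + h0, p0.normal, origin, u, v),
        chart_origin=origin, u_axis=u, v_axis=v,
    )
    # the section of the sub-proximal bone by P1 is exactly the physical
    # distal cut (medial of the hinge P1 runs above P0, outside that bone)
    closure = closure_transform(plan)
    loops = _mesh.section_loops(below, p1.point - h1, p1.normal)
    Rm, t = closure[:3, :3], closure[:3, 3]
    polys = []
    for loop in loops:
        closed = loop @ Rm.T + t
        rel = closed - origin
        poly = shapely.Polygon(np.column_stack((rel @ u, rel @ v)))
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        if poly.area > 0:
            polys.append(poly)
    if not polys:
        raise GeometryError("distal cut face is empty")
    merged = shapely.union_all(polys)
    if isinstance(merged, shapely.Polygon):
        merged = shapely.MultiPolygon([merged])
    distal_face = CutFace(plane=p1, boundary=merged,
                          chart_origin=origin, u_axis=u, v_axis=v)
    return ExecutionResult(
        proximal_fragment=proximal,
        distal_fragment=distal,
        wedge=wedge,
        proximal_face=proximal_face,
        distal_face=distal_face,
    )


@dataclass
class NonOverlapMetrics:
    overlap_area: float
    nonoverlap_total_difference: float
    nonoverlap_lateral: float
    nonoverlap_medial: float
    distal_overhang_lateral: float
    distal_overhang_medial: float
    nonoverlap_signed: float
    lateral_overhang_fragment: str


def compute_nonoverlap(
    proximal_face: CutFace,
    distal_face: CutFace,
    plan: OsteotomyPlan,
    step: float = DEFAULT_SCANLINE_STEP,
) -> NonOverlapMetrics:
    """Post-closure overlap and overhang metrics of the two cut faces.

    Both faces must share the hinge-centred chart of the proximal plane
    (``execute_plan`` reports them that way).  Besides the boolean overlap
    and difference areas, a scanline decomposition samples AP stations
    every ``step`` mm and integrates, on each side, the ML distance by
    which one face extends past the other; AP stations where one face is
    absent entirely (anterior/posterior rim slivers) contribute to the
    boolean difference but not to the lateral/medial strips.
    """
    P = proximal_face.boundary
    D = distal_face.boundary
    if P.is_empty or D.is_empty:
        raise GeometryError("empty cut face")
    overlap = float(P.intersection(D).area)
    total_diff = float(P.difference(D).area)

    vmin = min(P.bounds[1], D.bounds[1])
    vmax = max(P.bounds[3], D.bounds[3])
    umin = min(P.bounds[0], D.bounds[0]) - 1.0
    umax = max(P.bounds[2], D.bounds[2]) + 1.0
    vs = np.arange(vmin + step / 2.0, vmax, step)
    coords = np.empty((len(vs), 2, 2))
    coords[:, 0, 0] = umin
    coords[:, 1, 0] = umax
    coords[:, :, 1] = vs[:, None]
    lines = shapely.linestrings(coords)
    pb = shapely.bounds(shapely.intersection(lines, P))  # (n, 4), NaN if empty
    db = shapely.bounds(shapely.intersection(lines, D))
    both = ~(np.isnan(pb[:, 0]) | np.isnan(db[:, 0]))
    pmin, pmax = pb[both, 0], pb[both, 2]
    dmin, dmax = db[both, 0], db[both, 2]
    lat_prox = step * float(np.clip(pmax - np.maximum(pmin, dmax), 0, None).sum())
    med_prox = step * float(np.clip(np.minimum(pmax, dmin) - pmin, 0, None).sum())
    lat_dist = step * float(np.clip(dmax - np.maximum(dmin, pmax), 0, None).sum())
    med_dist = step * float(np.clip(np.minimum(dmax, pmin) - dmin, 0, None).sum())
    technique = Technique(plan.technique)
    signed = -med_prox if technique.is_hybrid else lat_prox
    return NonOverlapMetrics(
        overlap_area=overlap,
        nonoverlap_total_difference=total_diff,
        nonoverlap_lateral=lat_prox,
        nonoverlap_medial=med_prox,
        distal_overhang_lateral=lat_dist,
        distal_overhang_medial=med_dist,
        nonoverlap_signed=signed,
        lateral_overhang_fragment="proximal" if lat_prox >= lat_dist else "distal",
    )


def medial_gap_volume(mesh: trimesh.Trimesh, plan: OsteotomyPlan) -> float:
    """Volume of the medial opening created by a hybrid closure.

    The region of the intact bone above the proximal plane and below the
    medial extension of the distal plane (empty unless the hinge lies
    inside the bone).
    """
    p0, p1 = plan.proximal_plane, plan.distal_plane
    try:
        above = slice_capped(mesh, p0.point, p0.normal, keep_positive=True)
        gap = slice_capped(above, p1.point, p1.normal, keep_positive=False)
    except GeometryError:
        return 0.0
    return float(gap.volume)


def simulate_knee(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    technique: Technique | str,
    theta: float,
    knee_id: str = "knee",
    scanline_step: float = DEFAULT_SCANLINE_STEP,
    kerf: float = 0.0,
) -> SimulationResult:
    """Full single-knee pipeline: frame → plan → cut → closure → metrics."""
    technique = Technique(technique)
    frame = build_frame(landmarks)
    plan = plan_osteotomy(mesh, frame, technique, theta)
    execution = execute_plan(mesh, plan, kerf=kerf)
    metrics = compute_nonoverlap(
        execution.proximal_face, execution.distal_face, plan, step=scanline_step
    )
    gap = medial_gap_volume(mesh, plan) if technique.is_hybrid else 0.0
    return SimulationResult(
        knee_id=knee_id,
        technique=technique.value,
        theta=float(theta),
        proximal_area=execution.proximal_face.area,
        distal_area=execution.distal_face.area,
        wedge_volume=float(execution.wedge.volume),
        medial_gap_volume=gap,
        overlap_area=metrics.overlap_area,
        nonoverlap_lateral=metrics.nonoverlap_lateral,
        nonoverlap_medial=metrics.nonoverlap_medial,
        nonoverlap_signed=metrics.nonoverlap_signed,
        nonoverlap_total_difference=metrics.nonoverlap_total_difference,
        distal_overhang_lateral=metrics.distal_overhang_lateral,
        distal_overhang_medial=metrics.distal_overhang_medial,
        lateral_overhang_fragment=metrics.lateral_overhang_fragment,
    )
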