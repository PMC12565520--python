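"""Anatomical frame construction and osteotomy plane planning.

Four lateral closed-wedge techniques are supported, differing in the
proximal cut orientation and the hinge position along it:

``conventional``
    Proximal cut parallel to the joint line, 10 mm below the joint
    surface; hinge at the medial end of that cut (on the medial cortex).
``oblique``
    Proximal cut through the medial cortex 15 mm below the joint line and
    the lateral cortex 35 mm below it; hinge at the medial cortex.
``hybrid_3_1`` / ``hybrid_2_1``
    Same oblique proximal cut, hinge moved inside the bone to the point
    dividing the cut chord lateral:medial = 3:1 (resp. 2:1) from the
    medial end, i.e. at fraction 1/4 (resp. 1/3) of the chord.

The distal cut is the proximal plane rotated by the correction angle θ
about the antero-posterior axis through the hinge, diving distally on the
lateral side.  Both planes contain the AP direction, so the correction is
purely coronal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import trimesh

from ._mesh import section_loops
from .errors import FrameError, GeometryError, ParameterError
from .phantoms import LandmarkSet

__all__ = [
    "Plane",
    "Technique",
    "HINGE_FRACTIONS",
    "TibialFrame",
    "OsteotomyPlan",
    "build_frame",
    "locate_cortex_point",
    "plan_osteotomy",
]


@dataclass(frozen=True)
class Plane:
    """A plane as point + unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ParameterError("plane normal is the zero vector")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def transformed(self, matrix: np.ndarray) -> "Plane":
        R, t = matrix[:3, :3], matrix[:3, 3]
        return Plane(R @ self.point + t, R @ self.normal)


class Technique(str, Enum):
    CONVENTIONAL = "conventional"
    OBLIQUE = "oblique"
    HYBRID_3_1 = "hybrid_3_1"
    HYBRID_2_1 = "hybrid_2_1"

    @property
    def is_hybrid(self) -> bool:
        return self in (Technique.HYBRID_3_1, Technique.HYBRID_2_1)


#: hinge position as a fraction of the proximal cut chord from its medial end
HINGE_FRACTIONS = {
    Technique.CONVENTIONAL: 0.0,
    Technique.OBLIQUE: 0.0,
    Technique.HYBRID_3_1: 1.0 / 4.0,  # lateral:medial = 3:1
    Technique.HYBRID_2_1: 1.0 / 3.0,  # lateral:medial = 2:1
}

#: offsets of the cut anchor points below the joint line, mm
CONVENTIONAL_OFFSET = 10.0
OBLIQUE_MEDIAL_OFFSET = 15.0
OBLIQUE_LATERAL_OFFSET = 35.0


@dataclass(frozen=True)
class TibialFrame:
    """Orthonormal anatomical frame: origin at the joint center, ml/ap/si axes."""

    origin: np.ndarray
    ml_axis: np.ndarray
    ap_axis: np.ndarray
    si_axis: np.ndarray
    joint_plane: Plane

    def validate(self) -> "TibialFrame":
        M = np.column_stack((self.ml_axis, self.ap_axis, self.si_axis))
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        if float(self.si_axis @ self.joint_plane.normal) <= 0:
            raise FrameError("joint plane normal opposes the SI axis")
        return self

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """(ml, ap, si) coordinates of world points."""
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack((rel @ self.ml_axis, rel @ self.ap_axis,
                                rel @ self.si_axis))


def build_frame(landmarks: LandmarkSet) -> TibialFrame:
    """Build the anatomical frame from plateau landmarks.

    Orthonormalization order: the SI axis is the joint-plane normal (from
    the ML chord and the anterior direction), the AP axis is the anterior
    direction orthogonalized against SI, and ML completes the right-handed
    triad.
    """
    landmarks.validate()
    chord = landmarks.lateral_plateau_edge - landmarks.medial_plateau_edge
    norm = np.linalg.norm(chord)
    if norm < 1e-9:
        raise FrameError("plateau edge landmarks are degenerate")
    chord = chord / norm
    si = np.cross(chord, landmarks.anterior_direction)
    si_norm = np.linalg.norm(si)
    if si_norm < 1e-9:
        raise FrameError("anterior direction collinear with the plateau chord")
    si = si / si_norm
    ap = landmarks.anterior_direction - (landmarks.anterior_direction @ si) * si
    ap = ap / np.linalg.norm(ap)
    ml = np.cross(ap, si)
    return TibialFrame(
        origin=np.asarray(landmarks.joint_center, float),
        ml_axis=ml,
        ap_axis=ap,
        si_axis=si,
        joint_plane=Plane(landmarks.joint_center, si),
    ).validate()


def locate_cortex_point(
    mesh: trimesh.Trimesh,
    frame: TibialFrame,
    side: str,
    si_offset: float,
    ap_halfwidth: float | None = None,
) -> np.ndarray:
    """Extreme medial/lateral cortex point of the cross-section ``si_offset``
    mm below the joint line (measured perpendicular to the joint plane).

    The section is restricted to the coronal mid-slab ``|ap| <=
    ap_halfwidth`` when given; the returned point is projected onto the
    coronal mid-plane (ap = 0) so that all plane constructions are purely
    coronal.
    """
    if side not in ("medial", "lateral"):
        raise ParameterError(f"side must be 'medial' or 'lateral', got {side!r}")
    if si_offset <= 0:
        raise ParameterError("si_offset must be positive")
    origin = frame.origin - si_offset * frame.si_axis
    try:
        loops = section_loops(mesh, origin, frame.si_axis)
    except GeometryError as exc:
        raise GeometryError(
            f"no cross-section {si_offset} mm below the joint line"
        ) from exc
    pts = np.vstack(loops)
    local = frame.to_local(pts)
    if ap_halfwidth is not None:
        keep = np.abs(local[:, 1]) <= ap_halfwidth
        if not keep.any():
            raise GeometryError("coronal mid-slab is empty at this offset")
        local = local[keep]
    u = local[:, 0]
    extreme = float(u.min() if side == "medial" else u.max())
    return frame.origin + extreme * frame.ml_axis - si_offset * frame.si_axis


@dataclass(frozen=True)
class OsteotomyPlan:
    """The two cutting planes plus hinge geometry for one technique/angle."""

    technique: Technique
    theta: float  # correction angle, degrees
    proximal_plane: Plane
    distal_plane: Plane
    hinge_point: np.ndarray
    hinge_axis: np.ndarray  # unit AP direction
    hinge_fraction: float
    chord_medial: np.ndarray  # medial end of the proximal cut chord
    chord_lateral: np.ndarray  # lateral end of the proximal cut chord

    @property
    def chord_direction(self) -> np.ndarray:
        d = self.chord_lateral - self.chord_medial
        return d / np.linalg.norm(d)

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    def validate(self) -> "OsteotomyPlan":
        if abs(float(self.proximal_plane.signed_distance(self.hinge_point)[0])) > 1e-6:
            raise GeometryError("hinge point is off the proximal plane")
        dihedral = math.acos(
            float(np.clip(self.proximal_plane.normal @ self.distal_plane.normal, -1, 1))
        )
        if abs(dihedral - self.theta_rad) > 1e-9:
            raise GeometryError(
                f"dihedral angle {math.degrees(dihedral):.9f} != theta {self.theta}"
            )
        return self

    def to_json(self) -> str:
        def vec(v):
            return [float(x) for x in v]

        return json.dumps(
            {
                "technique": self.technique.value,
                "theta_deg": self.theta,
                "proximal_plane": {"point": vec(self.proximal_plane.point),
                                   "normal": vec(self.proximal_plane.normal)},
                "distal_plane": {"point": vec(self.distal_plane.point),
                                 "normal": vec(self.distal_plane.normal)},
                "hinge_point": vec(self.hinge_point),
                "hinge_axis": vec(self.hinge_axis),
                "hinge_fraction": self.hinge_fraction,
                "chord_medial": vec(self.chord_medial),
                "chord_lateral": vec(self.chord_lateral),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "OsteotomyPlan":
        d = json.loads(text)
        return OsteotomyPlan(
            technique=Technique(d["technique"]),
            theta=float(d["theta_deg"]),
            proximal_plane=Plane(d["proximal_plane"]["point"],
                                 d["proximal_plane"]["normal"]),
            distal_plane=Plane(d["distal_plane"]["point"],
                               d["distal_plane"]["normal"]),
            hinge_point=np.asarray(d["hinge_point"], float),
            hinge_axis=np.asarray(d["hinge_axis"], float),
            hinge_fraction=float(d["hinge_fraction"]),
            chord_medial=np.asarray(d["chord_medial"], float),
            chord_lateral=np.asarray(d["chord_lateral"], float),
        ).validate()


def _rotated_distal_plane(
    proximal: Plane, hinge: np.ndarray, ap: np.ndarray, chord_dir: np.ndarray,
    theta_rad: float,
) -> Plane:
    """Rotate the proximal plane about the AP hinge axis so the distal plane
    dives distally on the lateral side (positive theta closes laterally)."""
    for sign in (-1.0, 1.0):
        R = trimesh.transformations.rotation_matrix(sign * theta_rad, ap, hinge)
        n1 = R[:3, :3] @ proximal.normal
        # lateral side of the distal plane must lie below it: moving from the
        # hinge toward the lateral chord end must go to the positive side
        if float(chord_dir @ n1) > 0:
            return Plane(hinge, n1)
    raise GeometryError("could not orient the distal plane")  # pragma: no cover


def plan_osteotomy(
    mesh: trimesh.Trimesh,
    frame: TibialFrame,
    technique: Technique | str,
    theta: float,
    ap_halfwidth: float | None = None,
) -> OsteotomyPlan:
    """Construct the osteotomy plan for one technique at correction angle
    ``theta`` (degrees)."""
    technique = Technique(technique)
    if not (0.0 < theta < 45.0):
        raise ParameterError(f"theta must be in (0, 45) degrees, got {theta}")
    if technique is Technique.CONVENTIONAL:
        medial = locate_cortex_point(mesh, frame, "medial",
                                     CONVENTIONAL_OFFSET, ap_halfwidth)
        lateral = locate_cortex_point(mesh, frame, "lateral",
                                      CONVENTIONAL_OFFSET, ap_halfwidth)
        proximal = Plane(medial, frame.si_axis)
    else:
        medial = locate_cortex_point(mesh, frame, "medial",
                                     OBLIQUE_MEDIAL_OFFSET, ap_halfwidth)
        lateral = locate_cortex_point(mesh, frame, "lateral",
                                      OBLIQUE_LATERAL_OFFSET, ap_halfwidth)
        normal = np.cross(lateral - medial, frame.ap_axis)
        if float(normal @ frame.si_axis) < 0:
            normal = -normal
        proximal = Plane(medial, normal)
    fraction = HINGE_FRACTIONS[technique]
    hinge = medial + fraction * (lateral - medial)
    chord_dir = (lateral - medial) / np.linalg.norm(lateral - medial)
    distal = _rotated_distal_plane(proximal, hinge, frame.ap_axis, chord_dir,
                                   math.radians(theta))
    return OsteotomyPlan(
        technique=technique,
        theta=float(theta),
        proximal_plane=proximal,
        distal_plane=distal,
        hinge_point=hinge,
        hinge_axis=frame.ap_axis,
        hinge_fraction=fraction,
        chord_medial=medial,
        chord_lateral=lateral,
    ).validate()
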