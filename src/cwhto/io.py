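"""File IO: STL meshes, landmark JSON, cohort record JSON.

Landmark schema (JSON object)::

    {
      "medial_plateau_edge":  [x, y, z],   # mm
      "lateral_plateau_edge": [x, y, z],
      "joint_center":         [x, y, z],
      "anterior_direction":   [x, y, z]    # unit vector
    }

Cohort records are a JSON list of objects with the ``KneeRecord`` fields.
Meshes are written as ASCII STL; watertightness is verified on read and a
:class:`~cwhto.errors.ValidationError` names the defect.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh

from ._mesh import validate_mesh
from .errors import SchemaError
from .phantoms import KneeRecord, LandmarkSet

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_records",
    "write_records",
    "write_cohort",
    "read_cohort",
]

_LANDMARK_KEYS = (
    "medial_plateau_edge",
    "lateral_plateau_edge",
    "joint_center",
    "anterior_direction",
)


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        trimesh.exchange.stl.export_stl_ascii(mesh), encoding="ascii"
    )
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path), process=True)
    if isinstance(mesh, trimesh.Scene):  # pragma: no cover - multi-body STL
        mesh = mesh.to_mesh()
    return validate_mesh(mesh, name=str(path))


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {k: [float(x) for x in getattr(landmarks, k)] for k in _LANDMARK_KEYS}
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    missing = [k for k in _LANDMARK_KEYS if k not in data]
    if missing:
        raise SchemaError(f"landmark file {path} missing keys: {missing}")
    bad = [k for k in _LANDMARK_KEYS
           if not (isinstance(data[k], list) and len(data[k]) == 3)]
    if bad:
        raise SchemaError(f"landmark file {path}: keys {bad} are not length-3 arrays")
    return LandmarkSet(**{k: np.asarray(data[k], float) for k in _LANDMARK_KEYS})


_RECORD_FIELDS = [f.name for f in dataclasses.fields(KneeRecord)]


def write_records(records: list[KneeRecord], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([dataclasses.asdict(r) for r in records], indent=2))
    return path


def read_records(path: str | Path) -> list[KneeRecord]:
    data = json.loads(Path(path).read_text())
    records = []
    for i, item in enumerate(data):
        missing = [k for k in _RECORD_FIELDS if k not in item]
        if missing:
            raise SchemaError(f"record {i} in {path} missing keys: {missing}")
        records.append(KneeRecord(**{k: item[k] for k in _RECORD_FIELDS}).validate())
    return records


def write_cohort(
    cohort: list[tuple[KneeRecord, trimesh.Trimesh, LandmarkSet]],
    directory: str | Path,
) -> Path:
    """Write records.json plus per-knee STL and landmark files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_records([r for r, _, _ in cohort], directory / "records.json")
    for record, mesh, landmarks in cohort:
        write_mesh(mesh, directory / f"{record.knee_id}.stl")
        write_landmarks(landmarks, directory / f"{record.knee_id}.landmarks.json")
    return directory


def read_cohort(
    directory: str | Path,
) -> list[tuple[KneeRecord, trimesh.Trimesh, LandmarkSet]]:
    directory = Path(directory)
    records = read_records(directory / "records.json")
    cohort = []
    for record in records:
        mesh = read_mesh(directory / f"{record.knee_id}.stl")
        landmarks = read_landmarks(directory / f"{record.knee_id}.landmarks.json")
        cohort.append((record, mesh, landmarks))
    return cohort
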