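"""Low-level watertight mesh operations: plane slicing with cross-section
capping, boundary-loop extraction, ear-clipping triangulation, section
polygons, and validated signed volumes.

trimesh performs the uncapped half-space cut; the cap itself is rebuilt
here so that both halves of every cut are watertight without relying on an
external triangulation engine.  The cap triangles reuse the boundary-loop
vertex indices, which guarantees edge pairing with the cut side walls and
therefore topological watertightness by construction.
"""

from __future__ import annotations

import numpy as np
import shapely
import trimesh

from .errors import GeometryError, ValidationError

# vertices closer than this to a cutting plane are snapped onto it before
# classification (symbolic perturbation toward the kept side)
PLANE_EPS = 1e-9


def validate_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> trimesh.Trimesh:
    """Raise :class:`ValidationError` naming the first structural defect."""
    if not mesh.is_watertight:
        raise ValidationError(f"{name} is not watertight (open or non-manifold edges)")
    if not mesh.is_winding_consistent:
        raise ValidationError(f"{name} has inconsistent triangle winding")
    if mesh.volume <= 0:
        raise ValidationError(
            f"{name} has non-positive enclosed volume ({mesh.volume:.6g} mm^3); "
            "orientation is inward"
        )
    return mesh


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Signed divergence-theorem volume of a watertight, outward-oriented mesh."""
    validate_mesh(mesh)
    return float(mesh.volume)


def boundary_loops(mesh: trimesh.Trimesh) -> list[list[int]]:
    """Ordered vertex-index loops of the open boundary of ``mesh``.

    Directed edges that lack an opposing partner are chained head-to-tail.
    Raises :class:`GeometryError` on a non-manifold boundary (a vertex with
    more than one outgoing boundary edge).
    """
    edges = mesh.edges
    lo = edges.min(axis=1).astype(np.int64)
    hi = edges.max(axis=1).astype(np.int64)
    key = lo * len(mesh.vertices) + hi
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    nxt: dict[int, int] = {}
    for a, b in edges[counts[inverse] == 1].tolist():
        if a in nxt:
            raise GeometryError("non-manifold cut boundary (pinched vertex)")
        nxt[a] = b
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop, cur = [], start
        while True:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
            if cur is None:
                raise GeometryError("open boundary chain does not close")
            if cur == start:
                break
        loops.append(loop)
    return loops


def ear_clip(points: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple 2D polygon by ear clipping.

    Returns index triples in the same cyclic orientation as the input ring.
    Collinear (zero-area) ears are clipped as a fallback so that polygons
    with collinear runs of vertices — routine on sliced faceted meshes —
    still triangulate with complete boundary-edge coverage.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise GeometryError("cannot triangulate a ring with < 3 vertices")
    nxt_i = np.r_[1:n, 0]
    signed2 = np.sum(pts[:, 0] * pts[nxt_i, 1] - pts[nxt_i, 0] * pts[:, 1])
    orient = 1.0 if signed2 >= 0 else -1.0
    scale2 = max(abs(signed2), 1e-30)

    # convex fast path: fan triangulation
    prv = np.r_[n - 1, 0:n - 1]
    e_prev = pts - pts[prv]
    e_next = pts[nxt_i] - pts
    turns = orient * (e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0])
    if np.all(turns >= -1e-12 * scale2):
        return [(0, i, i + 1) for i in range(1, n - 1)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def any_inside(others: np.ndarray, a, b, c) -> bool:
        if len(others) == 0:
            return False
        q = pts[others]
        d1 = (b[0] - a[0]) * (q[:, 1] - a[1]) - (b[1] - a[1]) * (q[:, 0] - a[0])
        d2 = (c[0] - b[0]) * (q[:, 1] - b[1]) - (c[1] - b[1]) * (q[:, 0] - b[0])
        d3 = (a[0] - c[0]) * (q[:, 1] - c[1]) - (a[1] - c[1]) * (q[:, 0] - c[0])
        has_neg = (d1 < 0) | (d2 < 0) | (d3 < 0)
        has_pos = (d1 > 0) | (d2 > 0) | (d3 > 0)
        return bool(np.any(~(has_neg & has_pos)))

    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    while len(idx) > 3:
        m = len(idx)
        arr = np.asarray(idx)
        clipped = False
        degenerate: int | None = None
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            c = orient * cross(pts[i0], pts[i1], pts[i2])
            if c <= 1e-12 * scale2:
                if degenerate is None and abs(c) <= 1e-12 * scale2:
                    degenerate = k
                continue
            others = arr[(arr != i0) & (arr != i1) & (arr != i2)]
            if any_inside(others, pts[i0], pts[i1], pts[i2]):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # only reflex/collinear candidates remain; clip the flattest one
            k = degenerate if degenerate is not None else 1
            m = len(idx)
            tris.append((idx[k - 1], idx[k], idx[(k + 1) % m]))
            idx.pop(k)
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def plane_chart(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal in-plane basis (u, v) for a plane normal."""
    n = np.asarray(normal, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def slice_capped(
    mesh: trimesh.Trimesh,
    plane_origin: np.ndarray,
    plane_normal: np.ndarray,
    keep_positive: bool = True,
) -> trimesh.Trimesh:
    """Cut a watertight mesh with a plane and return the requested half, capped.

    ``keep_positive`` keeps the half on the side the normal points toward.
    Vertices within :data:`PLANE_EPS` of the plane are snapped onto it, so
    on-plane vertices are classified consistently on both halves.
    Raises :class:`GeometryError` if the kept half is empty.
    """
    origin = np.asarray(plane_origin, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    if not keep_positive:
        n = -n
    half = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=n, plane_origin=origin, cap=False
    )
    if half is None or len(half.faces) == 0:
        raise GeometryError("cutting plane leaves nothing on the requested side")
    half = trimesh.Trimesh(vertices=half.vertices, faces=half.faces, process=False)
    half.merge_vertices()
    loops = boundary_loops(half)
    if not loops:
        # plane does not intersect the mesh interior on this side
        return half
    u, v = plane_chart(n)
    verts = half.vertices.view(np.ndarray)
    faces = [list(f) for f in half.faces]
    for loop in loops:
        pts2 = np.column_stack((verts[loop] @ u, verts[loop] @ v))
        for i, j, k in ear_clip(pts2):
            # reversed relative to the wall boundary direction -> paired edges
            faces.append([loop[k], loop[j], loop[i]])
    out = trimesh.Trimesh(vertices=verts.copy(), faces=np.asarray(faces), process=False)
    if not out.is_watertight:
        raise GeometryError("capped slice failed to close (degenerate cut?)")
    return out


def section_loops(
    mesh: trimesh.Trimesh, plane_origin: np.ndarray, plane_normal: np.ndarray
) -> list[np.ndarray]:
    """Closed 3D polyline loops of the cross-section of ``mesh`` by a plane."""
    path = mesh.section(plane_origin=np.asarray(plane_origin, float),
                        plane_normal=np.asarray(plane_normal, float))
    if path is None:
        raise GeometryError("plane does not intersect the mesh")
    return [np.asarray(d) for d in path.discrete]


def section_polygon(
    mesh: trimesh.Trimesh,
    plane_origin: np.ndarray,
    plane_normal: np.ndarray,
    chart_origin: np.ndarray,
    u_axis: np.ndarray,
    v_axis: np.ndarray,
) -> shapely.MultiPolygon:
    """Cross-section of ``mesh`` as 2D polygons in the given in-plane chart."""
    loops = section_loops(mesh, plane_origin, plane_normal)
    polys = []
    for loop in loops:
        rel = loop - chart_origin
        ring = np.column_stack((rel @ u_axis, rel @ v_axis))
        poly = shapely.Polygon(ring)
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        if poly.area > 0:
            polys.append(poly)
    if not polys:
        raise GeometryError("empty cross-section")
    merged = shapely.union_all(polys)
    if isinstance(merged, shapely.Polygon):
        merged = shapely.MultiPolygon([merged])
    return merged
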