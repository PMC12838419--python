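"""Core geometric primitives shared by every pipeline stage.

Planar lumen contours, 3D centerlines with rotation-minimizing transport
frames, cutting planes and triangle meshes.  Contours are always stored
counter-clockwise in a right-handed basis; centerline frames are built by
double-reflection parallel transport so that a straight vessel carries no
artificial twist (a Frenet frame is undefined there and would corrupt the
downstream twist correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .errors import InvalidCenterlineError, InvalidContourError, ParameterError

#: Meshes are plain triangle soups; trimesh is the in-memory container.
SurfaceMesh = trimesh.Trimesh

_MERGE_TOL = 1e-6  # mm; duplicate consecutive points are merged at this tolerance


def make_mesh(vertices, faces) -> SurfaceMesh:
    """Build a cleaned :class:`SurfaceMesh`, dropping degenerate faces."""
    m = trimesh.Trimesh(vertices=np.asarray(vertices, float),
                        faces=np.asarray(faces, int), process=False)
    m.update_faces(m.nondegenerate_faces())
    return m


def _dedupe_closed(points: np.ndarray, tol: float = _MERGE_TOL) -> np.ndarray:
    pts = np.asarray(points, float)
    if pts.ndim != 2:
        raise InvalidContourError("contour points must be a 2D array")
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    pts = pts[keep]
    # drop an explicitly repeated closing point
    if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= tol:
        pts = pts[:-1]
    return pts


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class Contour2D:
    """Closed planar lumen contour in mm, stored counter-clockwise.

    The closing edge from the last back to the first point is implicit.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = _dedupe_closed(self.points)
        if pts.shape[0] < 3 or pts.shape[1] != 2:
            raise InvalidContourError(
                f"a closed contour needs >=3 distinct (x, y) points, got {pts.shape}")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def is_closed(self) -> bool:
        return True

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return polygon_area(self)

    @property
    def perimeter(self) -> float:
        return polygon_perimeter(self)

    def centroid(self) -> np.ndarray:
        c = self.polygon().centroid
        return np.array([c.x, c.y])

    def rotated(self, angle_deg: float) -> "Contour2D":
        """Rotate about the frame origin (catheter axis), CCW positive."""
        a = math.radians(angle_deg)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return Contour2D(self.points @ R.T)

    def translated(self, offset) -> "Contour2D":
        return Contour2D(self.points + np.asarray(offset, float))


@dataclass
class Contour3D:
    """A planar contour positioned in 3D, tied to one centerline point."""

    points: np.ndarray
    centerline_index: int
    normal: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        n = np.asarray(self.normal, float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise InvalidContourError("contour normal must be nonzero")
        self.normal = n / nn
        if self.points.shape[0] < 3 or self.points.shape[1] != 3:
            raise InvalidContourError("Contour3D needs >=3 (x, y, z) points")
        d = (self.points - self.points[0]) @ self.normal
        if np.max(np.abs(d)) > 1e-6 + 1e-9 * np.max(np.abs(self.points)):
            raise InvalidContourError("Contour3D points are not coplanar")

    @property
    def area(self) -> float:
        return polygon_area(self.to_plane_coords())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_plane_coords(self, origin=None) -> Contour2D:
        """Express the contour in the deterministic in-plane basis."""
        o = self.points[0] if origin is None else np.asarray(origin, float)
        e1, e2 = plane_basis(self.normal)
        rel = self.points - o
        return Contour2D(np.column_stack([rel @ e1, rel @ e2]))


@dataclass
class Plane:
    """Cutting plane defined by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        n = np.asarray(self.normal, float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ParameterError("plane normal must be nonzero")
        self.normal = n / nn


def plane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis (e1, e2) for a unit normal.

    e1 is the normalized projection of the global x-axis onto the plane,
    falling back to the y-axis when the normal is (anti)parallel to x.
    """
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(n @ ref)) > 0.999:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass
class Centerline:
    """Ordered 3D polyline with arc length and optional transport frames.

    ``frames`` is an (n, 3, 3) array of row-stacked (tangent, normal,
    binormal) triples, populated by :func:`transport_frames`.
    """

    points: np.ndarray
    frames: np.ndarray | None = None
    cumulative_arclength: np.ndarray = field(init=False)

    def __post_init__(self):
        pts = _dedupe_open(np.asarray(self.points, float))
        if pts.shape[0] < 2 or pts.shape[1] != 3:
            raise InvalidCenterlineError(
                f"centerline needs >=2 distinct (x, y, z) points, got {pts.shape}")
        self.points = pts
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.cumulative_arclength[-1])

    @property
    def n_points(self) -> int:
        return len(self.points)

    def tangents(self) -> np.ndarray:
        if self.frames is None:
            return _chord_tangents(self.points)
        return self.frames[:, 0]


def _dedupe_open(pts: np.ndarray, tol: float = _MERGE_TOL) -> np.ndarray:
    if pts.ndim != 2 or len(pts) == 0:
        raise InvalidCenterlineError("centerline points must be a nonempty 2D array")
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    return pts[keep]


# ---------------------------------------------------------------------------
# planar measures

def polygon_area(contour: Contour2D) -> float:
    """Enclosed area in mm² (shoelace, always positive for a valid contour)."""
    if not isinstance(contour, Contour2D):
        contour = Contour2D(np.asarray(contour, float))
    return abs(_signed_area(contour.points))


def polygon_perimeter(contour: Contour2D) -> float:
    """Boundary length in mm including the closing edge."""
    if not isinstance(contour, Contour2D):
        contour = Contour2D(np.asarray(contour, float))
    pts = contour.points
    return float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())


def theoretical_radius(area: float) -> float:
    """Radius of the circle of equal area, sqrt(A / pi).

    The standard single-number size summary for irregular calcification
    cross-sections.
    """
    if area < 0:
        raise ParameterError(f"area must be non-negative, got {area}")
    return math.sqrt(area / math.pi)


def resample_closed_contour(contour: Contour2D, n: int) -> Contour2D:
    """Resample a closed contour to ``n`` points equally spaced in arc length."""
    if n < 8:
        raise ParameterError(f"need at least 8 resampling points, got {n}")
    pts = np.vstack([contour.points, contour.points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return Contour2D(np.column_stack([x, y]))


def resample_centerline(cl: Centerline, spacing: float) -> Centerline:
    """Resample to constant arc-length spacing; endpoints are preserved.

    The final segment may be shorter than ``spacing`` so that the distal
    endpoint is always kept.
    """
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    total = cl.length
    if spacing > total:
        raise ParameterError(
            f"spacing {spacing} mm exceeds centerline length {total:.6g} mm")
    s = cl.cumulative_arclength
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] > _MERGE_TOL:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    new = np.column_stack([np.interp(targets, s, cl.points[:, k]) for k in range(3)])
    return Centerline(new)


def _chord_tangents(pts: np.ndarray) -> np.ndarray:
    t = np.empty_like(pts)
    t[0] = pts[1] - pts[0]
    t[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        t[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidCenterlineError("coincident consecutive centerline points")
    return t / norms


def transport_frames(cl: Centerline) -> Centerline:
    """Attach rotation-minimizing frames via double-reflection transport.

    Tangents follow the local chord direction; the in-plane axes of
    consecutive frames are related by the minimal rotation taking one
    tangent to the next, so a straight centerline yields identical frames.
    """
    pts = cl.points
    t = _chord_tangents(pts)
    n = len(pts)
    frames = np.empty((n, 3, 3))
    # seed normal: least-aligned coordinate axis, projected and normalized
    seed = np.eye(3)[np.argmin(np.abs(t[0]))]
    r = seed - (seed @ t[0]) * t[0]
    r /= np.linalg.norm(r)
    frames[0] = np.vstack([t[0], r, np.cross(t[0], r)])
    for i in range(n - 1):
        ti, ri = frames[i, 0], frames[i, 1]
        v1 = pts[i + 1] - pts[i]
        c1 = v1 @ v1
        rl = ri - (2.0 / c1) * (v1 @ ri) * v1
        tl = ti - (2.0 / c1) * (v1 @ ti) * v1
        v2 = t[i + 1] - tl
        c2 = v2 @ v2
        r_next = rl if c2 < 1e-30 else rl - (2.0 / c2) * (v2 @ rl) * v2
        r_next = r_next - (r_next @ t[i + 1]) * t[i + 1]
        r_next /= np.linalg.norm(r_next)
        frames[i + 1] = np.vstack([t[i + 1], r_next, np.cross(t[i + 1], r_next)])
    out = Centerline(pts.copy())
    out.frames = frames
    return out


def plane_mesh_section(mesh: SurfaceMesh, plane: Plane) -> list[Contour2D]:
    """Intersect a mesh with a plane; closed loops in in-plane coordinates.

    Loops are expressed in the deterministic :func:`plane_basis` of the
    plane normal with the plane origin at (0, 0).  An empty list means the
    plane misses the mesh.
    """
    sec = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if sec is None:
        return []
    e1, e2 = plane_basis(plane.normal)
    out: list[Contour2D] = []
    for poly in sec.discrete:
        poly = np.asarray(poly, float)
        if len(poly) >= 2 and np.linalg.norm(poly[0] - poly[-1]) < 1e-8:
            poly = poly[:-1]
        if len(poly) < 3:
            continue
        rel = poly - plane.origin
        xy = np.column_stack([rel @ e1, rel @ e2])
        try:
            c = Contour2D(xy)
        except InvalidContourError:
            continue
        if c.area > 1e-12:
            out.append(c)
    return out


def contour_to_3d(contour: Contour2D, origin, e1, e2, normal,
                  centerline_index: int) -> Contour3D:
    """Lift an in-plane contour into 3D using the frame (e1, e2)."""
    o = np.asarray(origin, float)
    pts = o + np.outer(contour.points[:, 0], e1) + np.outer(contour.points[:, 1], e2)
    return Contour3D(pts, centerline_index=centerline_index, normal=normal)


def loft_tube(rings: list[np.ndarray], cap: bool = True) -> SurfaceMesh:
    """Triangulate a tube from ordered rings of equal point count.

    Rings must be consistently oriented (CCW viewed against the travel
    direction).  With ``cap`` the ends are closed by triangle fans, making
    the result watertight by construction.
    """
    if len(rings) < 2:
        raise ParameterError("lofting needs at least two rings")
    m = len(rings[0])
    if any(len(r) != m for r in rings):
        raise ParameterError("all rings must have the same point count")
    verts = np.vstack(rings)
    faces = []
    for i in range(len(rings) - 1):
        a, b = i * m, (i + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a + j, a + jn, b + j])
            faces.append([a + jn, b + jn, b + j])
    if cap:
        c0 = verts[:m].mean(axis=0)
        c1 = verts[-m:].mean(axis=0)
        i0, i1 = len(verts), len(verts) + 1
        verts = np.vstack([verts, c0, c1])
        base = (len(rings) - 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([i0, jn, j])                    # start cap (inward-facing)
            faces.append([i1, base + j, base + jn])      # end cap
    mesh = make_mesh(verts, faces)
    mesh.fix_normals()
    return mesh
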