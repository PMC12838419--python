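"""Calcification handling: blooming correction, cross-section metrics, embedding.

CT systematically overestimates calcification extent (blooming); the
CCTA-derived geometry is therefore shrunk by a uniform offset (default
0.5 mm) calibrated against calcification borders visible on OCT.
Cross-sections of OCT- and CCTA-derived calcifications are compared by
theoretical radius (equal-area circle), area and perimeter; corrected
calcification solids are finally merged into the vessel wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

from .errors import (CollapseError, EmbeddingError, EmptySectionError,
                     ParameterError)
from .geometry import (Contour2D, Plane, SurfaceMesh, make_mesh,
                       plane_mesh_section, polygon_area, polygon_perimeter,
                       theoretical_radius)
from .proximity import MeshDistance


@dataclass
class CalcificationModel:
    """One segmented calcification with its blooming offset (mm)."""

    mesh: SurfaceMesh
    bloom_offset_mm: float = 0.5

    def __post_init__(self):
        if self.bloom_offset_mm < 0:
            raise ParameterError("bloom offset must be >= 0")


@dataclass
class CalcCrossSection:
    """Planar calcification cut with its size metrics."""

    contour: Contour2D
    source: str                      # "OCT" or "CCTA"
    area: float = field(init=False)
    perimeter: float = field(init=False)
    theoretical_radius: float = field(init=False)

    def __post_init__(self):
        self.area = polygon_area(self.contour)
        self.perimeter = polygon_perimeter(self.contour)
        self.theoretical_radius = theoretical_radius(self.area)


def shrink_contour(contour: Contour2D, offset: float,
                   join_style: str = "round") -> Contour2D:
    """Inward polygon offset (erosion) by ``offset`` mm.

    Round joins by default — erosion of smooth anatomic contours should
    not mint corners; ``mitre`` is available for polygonal fixtures.
    """
    if offset < 0:
        raise ParameterError("offset must be >= 0")
    if offset == 0:
        return Contour2D(contour.points.copy())
    shrunk = contour.polygon().buffer(-offset, join_style=join_style,
                                      quad_segs=16)
    if shrunk.is_empty:
        raise CollapseError(f"offset {offset} mm collapses the contour")
    if isinstance(shrunk, MultiPolygon):
        shrunk = max(shrunk.geoms, key=lambda g: g.area)
    if not isinstance(shrunk, Polygon) or shrunk.area <= 0:
        raise CollapseError(f"offset {offset} mm collapses the contour")
    return Contour2D(np.asarray(shrunk.exterior.coords)[:-1])


def shrink_mesh(mesh: SurfaceMesh, offset: float) -> SurfaceMesh:
    """Isotropic inward mesh offset along vertex normals (3D bloom correction).

    Adequate for compact convex-ish calcification blobs; the per-section
    planar erosion is the validated reference mode.
    """
    m = mesh.copy()
    m.fix_normals()
    out = trimesh.Trimesh(vertices=m.vertices - offset * m.vertex_normals,
                          faces=m.faces.copy(), process=False)
    if out.volume <= 0:
        raise CollapseError(f"offset {offset} mm collapses the mesh")
    return out


def bloom_mesh(mesh: SurfaceMesh, offset: float) -> SurfaceMesh:
    """Outward mesh dilation — used to *synthesize* bloomed CT geometry."""
    m = mesh.copy()
    m.fix_normals()
    return trimesh.Trimesh(vertices=m.vertices + offset * m.vertex_normals,
                           faces=m.faces.copy(), process=False)


def calc_cross_section(calc: CalcificationModel, plane: Plane,
                       apply_bloom_correction: bool = False,
                       source: str = "CCTA") -> CalcCrossSection:
    """Cut the calcification with a plane; largest component, optional correction."""
    sections = plane_mesh_section(calc.mesh, plane)
    if not sections:
        raise EmptySectionError("plane does not intersect the calcification")
    contour = max(sections, key=polygon_area)
    if apply_bloom_correction and calc.bloom_offset_mm > 0:
        contour = shrink_contour(contour, calc.bloom_offset_mm)
    return CalcCrossSection(contour=contour, source=source)


def compare_calc_contours(oct_cs: CalcCrossSection,
                          ccta_cs: CalcCrossSection) -> dict:
    """Per-metric differences, CCTA minus OCT (positive = CT overestimates)."""
    return {
        "delta_radius_mm": ccta_cs.theoretical_radius - oct_cs.theoretical_radius,
        "delta_area_mm2": ccta_cs.area - oct_cs.area,
        "delta_perimeter_mm": ccta_cs.perimeter - oct_cs.perimeter,
    }


def _fast_signed_distance(mesh: SurfaceMesh, pts: np.ndarray,
                          refine_px: float) -> np.ndarray:
    """Approximate signed distance: nearest vertex + pseudo-normal sign.

    The sign comes from the angle-weighted vertex pseudo-normal of the
    nearest mesh vertex (exact for watertight meshes away from features);
    the magnitude is the nearest-vertex distance, which overestimates the
    true surface distance by at most one edge length — adequate for
    occupancy tests on a grid whose pitch bounds the needed accuracy.
    Samples within ``refine_px`` of the surface are re-evaluated with the
    exact point-to-triangle query.
    """
    from scipy.spatial import cKDTree
    pseudo = trimesh.geometry.weighted_vertex_normals(
        len(mesh.vertices), mesh.faces, mesh.face_normals, mesh.face_angles)
    d, vi = cKDTree(mesh.vertices).query(pts)
    sign = np.where(np.einsum("ij,ij->i", pts - mesh.vertices[vi],
                              pseudo[vi]) >= 0, 1.0, -1.0)
    sd = sign * d
    near = d <= refine_px
    if near.any():
        sd[near] = MeshDistance(mesh).signed_distance(pts[near])
    return sd


def voxel_union(meshes: list[SurfaceMesh], pitch: float = 0.15,
                pad: float = 0.5) -> SurfaceMesh:
    """Union of watertight solids on a signed-distance voxel grid.

    Occupancy is the union of per-mesh inside tests (signed distance < 0);
    marching cubes over the occupancy field yields a manifold surface.
    Accuracy is set by ``pitch`` (mm per voxel).
    """
    if not meshes:
        raise ParameterError("voxel_union needs at least one mesh")
    lo = np.min([m.bounds[0] for m in meshes], axis=0) - pad
    hi = np.max([m.bounds[1] for m in meshes], axis=0) + pad
    nx, ny, nz = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    gx = lo[0] + pitch * np.arange(nx)
    gy = lo[1] + pitch * np.arange(ny)
    gz = lo[2] + pitch * np.arange(nz)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sdf = np.full(len(pts), 2.0 * pad)
    for m in meshes:
        # the nearest-vertex sign test needs a fine tessellation
        if np.max(m.edges_unique_length) > 3.0 * pitch:
            v, f = trimesh.remesh.subdivide_to_size(
                m.vertices, m.faces, max_edge=3.0 * pitch)
            m = trimesh.Trimesh(vertices=v, faces=f, process=False)
        # only evaluate near/within each mesh's padded bounding box
        bb_lo, bb_hi = m.bounds[0] - pad, m.bounds[1] + pad
        near = np.all((pts >= bb_lo) & (pts <= bb_hi), axis=1)
        if not near.any():
            continue
        sd = _fast_signed_distance(m, pts[near], refine_px=2.0 * pitch)
        sdf[near] = np.minimum(sdf[near], sd)
    field3d = sdf.reshape(nx, ny, nz)
    if not (field3d < 0).any():
        raise EmbeddingError(None, "union occupancy is empty")
    verts, faces, _, _ = measure.marching_cubes(field3d, level=0.0,
                                                spacing=(pitch, pitch, pitch))
    # marching-cubes output is already manifold; vertex merging would
    # re-open it, so keep the raw topology and only fix orientation
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def embed_calcifications(wall_solid: SurfaceMesh,
                         calcs: list[CalcificationModel],
                         *, pitch: float = 0.15,
                         correct_bloom: bool = True) -> SurfaceMesh:
    """Merge bloom-corrected calcification solids into the wall solid.

    The union is evaluated on a voxel signed-distance grid; local wall
    thickness at calcified regions can only grow (union with the base
    wall), matching the requirement that calcification thickness adds to
    the total wall thickness.
    """
    if not calcs:
        return wall_solid.copy()
    solids = [wall_solid]
    for i, calc in enumerate(calcs):
        m = calc.mesh
        if correct_bloom and calc.bloom_offset_mm > 0:
            try:
                m = shrink_mesh(m, calc.bloom_offset_mm)
            except CollapseError as e:
                raise EmbeddingError(i, f"bloom correction collapsed mesh {i}: {e}")
        if not m.is_watertight:
            raise EmbeddingError(i, f"calcification mesh {i} is not watertight")
        solids.append(m)
    try:
        return voxel_union(solids, pitch=pitch)
    except EmbeddingError:
        raise
    except Exception as e:  # diagnostics with the failing context
        raise EmbeddingError("union", f"voxel union failed: {e}") from e
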