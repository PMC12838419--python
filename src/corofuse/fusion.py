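"""Data fusion: merge CCTA and OCT lumen points into one surface model.

The CCTA mesh is converted to a labelled point cloud, points closer than
the overlap radius (default 0.35 mm) to any OCT point are dropped via a
k-d tree radius query, residual clutter is removed by declarative region
predicates (the scriptable replacement for interactive point selection),
and the fused cloud is meshed by a centerline-guided loft.  A uniform
1 mm wall is finally offset outward to produce the printable solid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (EmptyCloudError, ParameterError, ReconstructionError)
from .geometry import (Centerline, SurfaceMesh, loft_tube, transport_frames)
from .registration import RegisteredStack

log = logging.getLogger(__name__)

LABEL_OCT = "OCT"
LABEL_CCTA = "CCTA"


@dataclass
class FusionConfig:
    """Fusion thresholds: CCTA/OCT overlap radius and wall thickness (mm)."""

    overlap_radius_mm: float = 0.35
    wall_thickness_mm: float = 1.0

    def __post_init__(self):
        if self.overlap_radius_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ParameterError("fusion thresholds must be positive")


@dataclass
class LabeledPointCloud:
    """3D points tagged by source modality (OCT or CCTA)."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.points):
            raise ParameterError("labels length must equal point count")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask: np.ndarray) -> "LabeledPointCloud":
        return LabeledPointCloud(self.points[mask], self.labels[mask])

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def mesh_to_point_cloud(mesh: SurfaceMesh, density: float,
                        seed: int | None = 0,
                        label: str = LABEL_CCTA) -> LabeledPointCloud:
    """Vertices plus area-weighted surface samples at ``density`` pts/mm²."""
    if density <= 0:
        raise ParameterError("density must be positive")
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ParameterError("cannot sample an empty mesh")
    n = int(round(density * mesh.area))
    pts = [np.asarray(mesh.vertices, float)]
    if n > 0:
        samples, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
        pts.append(np.asarray(samples, float))
    allpts = np.vstack(pts)
    return LabeledPointCloud(allpts, np.full(len(allpts), label, object))


def remove_overlapping_points(ccta: LabeledPointCloud, oct_cloud: LabeledPointCloud,
                              cfg: FusionConfig | None = None) -> LabeledPointCloud:
    """Drop CCTA points strictly closer than the overlap radius to any OCT point."""
    cfg = cfg or FusionConfig()
    if len(oct_cloud) == 0:
        log.warning("OCT cloud empty; overlap removal is a no-op")
        return LabeledPointCloud(ccta.points.copy(), ccta.labels.copy())
    d, _ = cKDTree(oct_cloud.points).query(ccta.points)
    return ccta.subset(d >= cfg.overlap_radius_mm)


# --- region predicates (scriptable stand-in for interactive point selection) ---

@dataclass
class SphereRegion:
    center: np.ndarray
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        return np.linalg.norm(pts - c, axis=1) <= self.radius


@dataclass
class BoxRegion:
    min_corner: np.ndarray
    max_corner: np.ndarray

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.min_corner, float)
        hi = np.asarray(self.max_corner, float)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class TubeRegion:
    """Points within ``radius`` of the centerline polyline between two indices."""

    centerline: Centerline
    index_range: tuple
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        i0, i1 = self.index_range
        seg_pts = self.centerline.points[i0:i1 + 1]
        d = _points_to_polyline(pts, seg_pts)
        return d <= self.radius


def _points_to_polyline(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance of each point to a polyline (exact, segment-wise)."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a                                     # (m, 3)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    best = np.full(len(pts), np.inf)
    for j in range(len(a)):
        t = np.clip(((pts - a[j]) @ ab[j]) / denom[j], 0.0, 1.0)
        proj = a[j] + t[:, None] * ab[j]
        best = np.minimum(best, np.linalg.norm(pts - proj, axis=1))
    return best


def select_points_region(cloud: LabeledPointCloud, region, keep: bool) -> LabeledPointCloud:
    """Keep or drop the points inside a region predicate (composable)."""
    inside = region.contains(cloud.points)
    mask = inside if keep else ~inside
    if not mask.any():
        raise EmptyCloudError("region selection removed every point")
    return cloud.subset(mask)


def fuse(ccta_filtered: LabeledPointCloud, stack: RegisteredStack) -> LabeledPointCloud:
    """Concatenate filtered CCTA points with the registered OCT contour points."""
    oct_pts = stack.all_points()
    if len(ccta_filtered) == 0 or len(oct_pts) == 0:
        raise ParameterError("fusion needs nonempty CCTA and OCT inputs")
    pts = np.vstack([ccta_filtered.points, oct_pts])
    labels = np.concatenate([ccta_filtered.labels,
                             np.full(len(oct_pts), LABEL_OCT, object)])
    return LabeledPointCloud(pts, labels)


def _pca_centerline(pts: np.ndarray, spacing: float) -> Centerline:
    """Fallback axis for clouds without an explicit centerline: principal axis."""
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    axis = vt[0]
    t = (pts - c) @ axis
    s = np.arange(t.min(), t.max() + spacing / 2, spacing)
    return Centerline(c + np.outer(s, axis))


def reconstruct_surface(cloud: LabeledPointCloud, centerline: Centerline | None = None,
                        *, n_theta: int = 64, min_station_points: int = 8,
                        station_spacing: float = 0.4,
                        outlier_factor: float = 2.0,
                        smooth_axial: int = 1) -> SurfaceMesh:
    """Mesh a tubular labelled cloud by a centerline-guided polar loft.

    Points are assigned to their nearest centerline station, expressed in
    the station's transported frame and binned by polar angle; the ring
    radius per bin is the median sample radius (radial outliers beyond
    ``outlier_factor`` x the station median — e.g. side-branch points —
    are discarded first).  Rings are smoothed axially and lofted into a
    capped, watertight triangle mesh.  Without a centerline the principal
    axis of the cloud is used, which is only adequate for nearly straight
    vessels.
    """
    pts = cloud.points
    if len(pts) < 100:
        raise ParameterError(f"reconstruction needs >=100 points, got {len(pts)}")
    cl = _pca_centerline(pts, station_spacing) if centerline is None else centerline
    rcl = transport_frames(cl)
    station_idx = cKDTree(rcl.points).query(pts)[1]

    radii = np.full((rcl.n_points, n_theta), np.nan)
    theta_bins = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    for i in range(rcl.n_points):
        sel = station_idx == i
        if np.count_nonzero(sel) < min_station_points:
            continue
        rel = pts[sel] - rcl.points[i]
        _, e1, e2 = rcl.frames[i]
        u, v = rel @ e1, rel @ e2
        rho = np.hypot(u, v)
        med = np.median(rho)
        ok = rho <= outlier_factor * med
        if np.count_nonzero(ok) < min_station_points:
            continue
        u, v, rho = u[ok], v[ok], rho[ok]
        ang = np.mod(np.arctan2(v, u), 2 * np.pi)
        b = np.minimum((ang / (2 * np.pi) * n_theta).astype(int), n_theta - 1)
        for k in range(n_theta):
            m = b == k
            if m.any():
                radii[i, k] = np.median(rho[m])
        # require reasonable angular coverage, else the ring is unreliable
        if np.count_nonzero(np.isfinite(radii[i])) < n_theta // 2:
            radii[i] = np.nan

    valid = np.nonzero(np.isfinite(radii).any(axis=1))[0]
    if len(valid) < 2:
        raise ReconstructionError(
            "too few usable stations; cloud is not tubular around the centerline")
    i0, i1 = valid.min(), valid.max()
    # fill angular gaps by periodic interpolation, axial gaps linearly
    for i in range(i0, i1 + 1):
        row = radii[i]
        fin = np.isfinite(row)
        if not fin.any():
            continue
        if not fin.all():
            radii[i] = np.interp(theta_bins, theta_bins[fin], row[fin],
                                 period=2 * np.pi)
    block = radii[i0:i1 + 1]
    for k in range(n_theta):
        col = block[:, k]
        fin = np.isfinite(col)
        if not fin.all():
            if not fin.any():
                raise ReconstructionError("empty angular column after interpolation")
            block[:, k] = np.interp(np.arange(len(col)), np.nonzero(fin)[0], col[fin])
    if smooth_axial > 0:
        kernel = np.ones(2 * smooth_axial + 1) / (2 * smooth_axial + 1)
        pad = np.pad(block, ((smooth_axial, smooth_axial), (0, 0)), mode="edge")
        block = np.apply_along_axis(lambda c: np.convolve(c, kernel, "valid"), 0, pad)

    rings = []
    for j, i in enumerate(range(i0, i1 + 1)):
        _, e1, e2 = rcl.frames[i]
        ring = (rcl.points[i]
                + np.outer(block[j] * np.cos(theta_bins), e1)
                + np.outer(block[j] * np.sin(theta_bins), e2))
        rings.append(ring)
    mesh = loft_tube(rings, cap=True)
    if not mesh.is_watertight:
        raise ReconstructionError("lofted surface is not watertight")
    return mesh


def add_wall(lumen_mesh: SurfaceMesh, cfg: FusionConfig | None = None) -> SurfaceMesh:
    """Offset the lumen outward to build a solid shell of uniform thickness.

    The outer surface moves each vertex along its area-weighted normal by
    the wall thickness; the inner surface is the lumen with reversed
    orientation, so the result is a closed solid bounded by both.
    """
    cfg = cfg or FusionConfig()
    if not lumen_mesh.is_watertight:
        raise ParameterError("add_wall requires a watertight lumen mesh")
    lm = lumen_mesh.copy()
    # vertex-normal offsets need edges short relative to the thickness,
    # otherwise sparse vertices carry averaged (beveled) normals
    if np.max(lm.edges_unique_length) > cfg.wall_thickness_mm:
        v, f = trimesh.remesh.subdivide_to_size(
            lm.vertices, lm.faces, max_edge=cfg.wall_thickness_mm)
        lm = trimesh.Trimesh(vertices=v, faces=f, process=False)
    lm.fix_normals()
    outer_v = lm.vertices + cfg.wall_thickness_mm * lm.vertex_normals
    outer = trimesh.Trimesh(vertices=outer_v, faces=lm.faces.copy(), process=False)
    inner = trimesh.Trimesh(vertices=lm.vertices.copy(),
                            faces=lm.faces[:, ::-1].copy(), process=False)
    # NOTE: do not let trimesh re-process the concatenation — winding
    # "repair" would flip the inner (cavity) component and fill the lumen
    return trimesh.util.concatenate([outer, inner])
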