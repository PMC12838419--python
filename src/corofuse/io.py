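"""Readers and writers for the pipeline's interchange formats.

Centerlines travel as whitespace-separated ``x y z`` text (mm, ``#``
comments); contour series as a versioned JSON archive; landmarks as
JSON; labelled point clouds as ``x y z label`` text or PLY with the
source modality encoded in the vertex colour (red = OCT, blue = CCTA);
meshes as STL/PLY/OBJ through trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .errors import ParameterError
from .fusion import LABEL_CCTA, LABEL_OCT, LabeledPointCloud
from .geometry import Centerline, Contour2D, SurfaceMesh
from .oct_processing import Calibration, PullbackSeries
from .registration import LandmarkPair

CONTOUR_ARCHIVE_VERSION = 1

_LABEL_COLORS = {LABEL_OCT: (255, 0, 0, 255), LABEL_CCTA: (0, 0, 255, 255)}


def read_centerline(path) -> Centerline:
    """Read an ``x y z`` per-line centerline text export (mm)."""
    pts = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParameterError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        pts.append([float(v) for v in parts])
    return Centerline(np.asarray(pts, float))


def write_centerline(cl: Centerline, path) -> None:
    with open(path, "w") as fh:
        fh.write("# centerline export: x y z [mm]\n")
        for p in cl.points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_contour_archive(series: PullbackSeries, path) -> None:
    """Versioned JSON archive of a pullback contour series (mm)."""
    cal = series.calibration
    doc = {
        "version": CONTOUR_ARCHIVE_VERSION,
        "calibration": {
            "px_per_mm": cal.px_per_mm,
            "frame_spacing_mm": cal.frame_spacing_mm,
            "pullback_speed": cal.pullback_speed,
            "pullback_length": cal.pullback_length,
        },
        "twist_angles_deg": series.twist_angles.tolist(),
        "frames": [
            {"index": int(i), "points_mm": np.round(c.points, 6).tolist()}
            for i, c in zip(series.frame_indices, series.contours)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contour_archive(path) -> PullbackSeries:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != CONTOUR_ARCHIVE_VERSION:
        raise ParameterError(f"unsupported contour archive version {doc.get('version')}")
    cal = Calibration(**doc["calibration"])
    contours = [Contour2D(np.asarray(f["points_mm"], float)) for f in doc["frames"]]
    indices = [int(f["index"]) for f in doc["frames"]]
    return PullbackSeries(contours=contours, calibration=cal,
                          frame_indices=indices,
                          twist_angles=np.asarray(doc.get("twist_angles_deg", []), float))


def read_landmarks(path) -> LandmarkPair:
    doc = json.loads(Path(path).read_text())
    return LandmarkPair(
        oct_frame_index=int(doc["oct_frame_index"]),
        oct_carina_point=np.asarray(doc["oct_carina_point_mm"], float),
        ccta_main_point=np.asarray(doc["ccta_main_point"], float),
        ccta_side_point=np.asarray(doc["ccta_side_point"], float))


def write_landmarks(lm: LandmarkPair, path) -> None:
    Path(path).write_text(json.dumps({
        "oct_frame_index": lm.oct_frame_index,
        "oct_carina_point_mm": lm.oct_carina_point.tolist(),
        "ccta_main_point": lm.ccta_main_point.tolist(),
        "ccta_side_point": lm.ccta_side_point.tolist(),
    }))


def write_point_cloud_txt(cloud: LabeledPointCloud, path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z label\n")
        for p, lab in zip(cloud.points, cloud.labels):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {lab}\n")


def read_point_cloud_txt(path) -> LabeledPointCloud:
    pts, labels = [], []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        x, y, z, lab = line.split()
        pts.append([float(x), float(y), float(z)])
        labels.append(lab)
    return LabeledPointCloud(np.asarray(pts, float), np.asarray(labels, object))


def write_point_cloud_ply(cloud: LabeledPointCloud, path) -> None:
    """PLY export with the modality encoded as vertex colour."""
    colors = np.array([_LABEL_COLORS.get(str(l), (128, 128, 128, 255))
                       for l in cloud.labels], np.uint8)
    pc = trimesh.PointCloud(cloud.points, colors=colors)
    pc.export(str(path))


def read_point_cloud_ply(path) -> LabeledPointCloud:
    pc = trimesh.load(str(path))
    colors = np.asarray(pc.colors)
    labels = np.where(colors[:, 0] > colors[:, 2], LABEL_OCT, LABEL_CCTA)
    return LabeledPointCloud(np.asarray(pc.vertices, float),
                             labels.astype(object))


def read_mesh(path) -> SurfaceMesh:
    m = trimesh.load(str(path), force="mesh")
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise ParameterError(f"{path} did not contain a triangle mesh")
    return m


def write_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.export(str(path))


def write_frames_tiff(frames, directory) -> list[Path]:
    """Write annotated frames as numbered single-page TIFFs."""
    import tifffile
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = directory / f"frame_{f.frame_index:04d}.tiff"
        tifffile.imwrite(p, f.image)
        paths.append(p)
    return paths


def read_frames(source, annotation_color=None, color_tol=None):
    """Load annotated frames from a directory of TIFF/PNG files or a multi-page TIFF.

    Frame indices come from the trailing integer in each filename, or the
    page number for multi-page files.
    """
    import re

    import tifffile
    from .oct_processing import (DEFAULT_ANNOTATION_COLOR, DEFAULT_COLOR_TOL,
                                 AnnotatedFrame)
    color = annotation_color or DEFAULT_ANNOTATION_COLOR
    tol = color_tol if color_tol is not None else DEFAULT_COLOR_TOL
    source = Path(source)
    frames = []
    if source.is_dir():
        for p in sorted(source.iterdir()):
            if p.suffix.lower() not in (".tif", ".tiff", ".png"):
                continue
            m = re.search(r"(\d+)\D*$", p.stem)
            idx = int(m.group(1)) if m else len(frames)
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio
                img = np.asarray(iio.imread(p))[..., :3]
            else:
                img = tifffile.imread(p)
            frames.append(AnnotatedFrame(image=img, frame_index=idx,
                                         annotation_color=color, color_tol=tol))
    else:
        stack = tifffile.imread(source)
        if stack.ndim == 3:
            stack = stack[None]
        for k, img in enumerate(stack):
            frames.append(AnnotatedFrame(image=img, frame_index=k,
                                         annotation_color=color, color_tol=tol))
    frames.sort(key=lambda f: f.frame_index)
    return frames
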