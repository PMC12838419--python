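"""Synthetic coronary phantoms with full ground truth.

Parametric vessels — a centerline (straight, arc, helix or random
spline), an elliptical lumen with Gaussian stenoses, side branches,
wall calcifications — from which every pipeline input can be generated:
annotated pseudo-OCT pullback frames (with a known catheter twist
profile and speckle background), a CCTA-like quantized noisy surface
point cloud, bloomed calcification meshes and a centerline text export.
The analytic truth (area profile, %AS, branch positions, twist) makes
each stage and the end-to-end loop testable without any patient data.

Geometry scale follows the clinical setting: vessels up to 75 mm, lumen
radii 1-2 mm, 1024 px frames at 103 px/mm, 0.4 mm CT resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .calcification import bloom_mesh
from .errors import ParameterError, RenderError, SpecError
from .geometry import (Centerline, SurfaceMesh, loft_tube, transport_frames)
from .oct_processing import (DEFAULT_ANNOTATION_COLOR, AnnotatedFrame,
                             Calibration)
from .validation import AreaProfile

_FOV_MARGIN_PX = 8


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic vessel.

    stenoses: list of (position mm, depth fraction in [0, 1), width mm);
    the radius profile is r(s) = base * (1 - sum depth_i * exp(-(s-pos_i)^2 / 2w_i^2)).
    side_branches: (position mm, radius mm, angle deg around the vessel).
    calcifications: (position mm, angular extent deg, thickness mm, bloom mm).
    twist_profile: cumulative catheter rotation per frame (deg); None means
    no twist.  noise: radial contour perturbation sd (mm) emulating manual
    delineation jitter.
    """

    centerline_kind: str = "straight"
    length: float = 75.0
    base_radius: float = 1.5
    stenoses: list = field(default_factory=list)
    ellipticity: float = 1.0
    side_branches: list = field(default_factory=list)
    calcifications: list = field(default_factory=list)
    twist_profile: np.ndarray | None = None
    noise: float = 0.02
    seed: int = 0
    ds: float = 0.25               # centerline sampling step, mm

    def __post_init__(self):
        if self.length <= 0 or self.base_radius <= 0 or self.ellipticity < 1.0:
            raise SpecError("length/base_radius must be > 0, ellipticity >= 1")
        for pos, depth, width in self.stenoses:
            if not (0 <= depth < 1) or width <= 0 or not (0 <= pos <= self.length):
                raise SpecError(f"bad stenosis ({pos}, {depth}, {width})")
        positions = [p for p, _, _ in self.side_branches]
        if len(positions) != len(set(positions)):
            raise SpecError("side branches overlap at the same position")
        for pos, radius, _ in self.side_branches:
            if radius <= 0 or not (0 <= pos <= self.length):
                raise SpecError("branch radius must be > 0 and position on-vessel")
        if self.twist_profile is not None:
            self.twist_profile = np.asarray(self.twist_profile, float)

    def radius_at(self, s) -> np.ndarray:
        """Lumen equivalent radius r(s) of the stenosed profile."""
        s = np.asarray(s, float)
        r = np.full_like(s, self.base_radius, dtype=float)
        for pos, depth, width in self.stenoses:
            r = r - self.base_radius * depth * np.exp(-(s - pos) ** 2 / (2 * width ** 2))
        return r

    def semi_axes_at(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Ellipse semi-axes (a, b) preserving the area pi r(s)^2."""
        r = self.radius_at(s)
        q = math.sqrt(self.ellipticity)
        return r * q, r / q


@dataclass
class PhantomTruth:
    """Ground truth bundled with a built phantom."""

    spec: PhantomSpec
    centerline: Centerline                 # fine sampling, frames attached
    area_profile: AreaProfile
    true_pct_AS: float
    branch_positions: list
    branch_frames: list                    # (base_point, direction3, angle_deg)
    calcification_meshes: list[SurfaceMesh]
    twist_profile: np.ndarray | None

    def section_contour(self, s: float, n: int = 128) -> np.ndarray:
        """Analytic lumen cross-section at arclength ``s`` in frame coords."""
        a, b = self.spec.semi_axes_at(s)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([a * np.cos(th), b * np.sin(th)])


def _centerline_points(kind: str, length: float, ds: float,
                       rng: np.random.Generator) -> np.ndarray:
    n = int(round(length / ds)) + 1
    s = np.linspace(0.0, length, n)
    if kind == "straight":
        return np.column_stack([np.zeros(n), np.zeros(n), s])
    if kind == "planar-arc":
        turn = math.pi / 3                     # 60 degrees over the full length
        R = length / turn
        phi = s / R
        return np.column_stack([R * (1 - np.cos(phi)), np.zeros(n), R * np.sin(phi)])
    if kind == "helix":
        Rh, pitch = 8.0, 30.0
        c = pitch / (2 * math.pi)
        rate = 1.0 / math.sqrt(Rh ** 2 + c ** 2)
        t = s * rate
        return np.column_stack([Rh * np.cos(t), Rh * np.sin(t), c * t])
    if kind == "spline-through-points":
        from scipy.interpolate import CubicSpline
        n_ctrl = 6
        zc = np.linspace(0, length, n_ctrl)
        amp = length / 15.0
        xc = rng.normal(0, amp, n_ctrl)
        yc = rng.normal(0, amp, n_ctrl)
        cs_x, cs_y = CubicSpline(zc, xc), CubicSpline(zc, yc)
        # reparametrize to arc length so s keeps its meaning
        zf = np.linspace(0, length, 20 * n)
        pts = np.column_stack([cs_x(zf), cs_y(zf), zf])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        s_t = s * arc[-1] / length
        return np.column_stack([np.interp(s_t, arc, pts[:, k]) for k in range(3)])
    raise SpecError(f"unknown centerline kind {kind!r}")


def build_phantom(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Loft the lumen mesh from analytic cross-sections; populate truth."""
    rng = np.random.default_rng(spec.seed)
    cl = transport_frames(Centerline(_centerline_points(
        spec.centerline_kind, spec.length, spec.ds, rng)))
    s = cl.cumulative_arclength
    a, b = spec.semi_axes_at(s)
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    rings = []
    for i in range(cl.n_points):
        _, e1, e2 = cl.frames[i]
        rings.append(cl.points[i]
                     + np.outer(a[i] * np.cos(th), e1)
                     + np.outer(b[i] * np.sin(th), e2))
    main = loft_tube(rings, cap=True)

    branch_meshes = []
    branch_frames = []
    for pos, radius, angle in spec.side_branches:
        i = int(np.argmin(np.abs(s - pos)))
        _, e1, e2 = cl.frames[i]
        phi = math.radians(angle)
        dir3 = math.cos(phi) * e1 + math.sin(phi) * e2
        axis = dir3 + 0.4 * cl.frames[i][0]
        axis /= np.linalg.norm(axis)
        u = np.cross(axis, cl.frames[i][0])
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        length_b = 6.0
        bth = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        brings = []
        for t in np.linspace(0.0, length_b, 13):
            c = cl.points[i] + t * axis
            brings.append(c + np.outer(radius * np.cos(bth), u)
                          + np.outer(radius * np.sin(bth), v))
        branch_meshes.append(loft_tube(brings, cap=True))
        branch_frames.append((cl.points[i], dir3, angle))

    calc_meshes = []
    for pos, extent_deg, thickness, _bloom in spec.calcifications:
        i = int(np.argmin(np.abs(s - pos)))
        _, e1, e2 = cl.frames[i]
        tangent = cl.frames[i][0]
        phi = math.radians(90.0)   # default angular placement; extent sets size
        # circumferential size from the angular extent at the lumen surface
        r_here = float(spec.radius_at(pos))
        circ = math.radians(extent_deg) * r_here
        dirr = math.cos(phi) * e1 + math.sin(phi) * e2
        center = cl.points[i] + (r_here + thickness / 2 + 0.05) * dirr
        sph = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        circ_dir = np.cross(tangent, dirr)
        R = np.column_stack([dirr, circ_dir, tangent])
        scaled = sph.vertices * np.array([thickness / 2, circ / 2, 1.0])
        calc_meshes.append(trimesh.Trimesh(
            vertices=scaled @ R.T + center, faces=sph.faces.copy(), process=False))

    mesh = trimesh.util.concatenate([main] + branch_meshes) if branch_meshes else main

    areas = math.pi * spec.radius_at(s) ** 2
    profile = AreaProfile(np.arange(cl.n_points), areas)
    i_min = int(np.argmin(areas))
    if i_min == 0:
        true_as = 0.0
    else:
        ref = float(np.max(areas[:i_min]))
        true_as = (ref - float(areas[i_min])) / ref * 100.0
    truth = PhantomTruth(
        spec=spec, centerline=cl, area_profile=profile, true_pct_AS=true_as,
        branch_positions=[p for p, _, _ in spec.side_branches],
        branch_frames=branch_frames, calcification_meshes=calc_meshes,
        twist_profile=spec.twist_profile)
    return mesh, truth


def smooth_twist_profile(n_frames: int, max_rate_deg: float = 1.0,
                         seed: int = 0) -> np.ndarray:
    """Cumulative catheter twist with a smooth bounded per-frame rate.

    The per-frame increment is a sum of two low-frequency sinusoids scaled
    so |increment| <= max_rate_deg everywhere.
    """
    rng = np.random.default_rng(seed)
    k = np.arange(n_frames)
    f1, f2 = rng.uniform(0.5, 2.0, 2)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    rate = 0.6 * np.sin(2 * np.pi * f1 * k / n_frames + p1) \
        + 0.4 * np.sin(2 * np.pi * f2 * k / n_frames + p2)
    rate *= max_rate_deg
    cum = np.concatenate([[0.0], np.cumsum(rate[1:])])
    return cum


def _ring_mask(shape: int, contour_px: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Rasterize a closed contour as a band of ~2*half_width+1 px."""
    from skimage.draw import polygon
    rr, cc = polygon(contour_px[:, 1], contour_px[:, 0], (shape, shape))
    filled = np.zeros((shape, shape), bool)
    filled[rr, cc] = True
    grown = ndimage.binary_dilation(filled, iterations=half_width)
    shrunk = ndimage.binary_erosion(filled, iterations=half_width)
    return grown & ~shrunk


def n_pullback_frames(truth: PhantomTruth, cal: Calibration) -> int:
    return int(math.floor(truth.spec.length / cal.frame_spacing_mm)) + 1


def render_frame(truth: PhantomTruth, cal: Calibration, k: int,
                 *, image_size: int = 1024, catheter_offset=(0.0, 0.0),
                 annotation_color=DEFAULT_ANNOTATION_COLOR,
                 n_contour_points: int = 180) -> AnnotatedFrame:
    """Render one annotated pseudo-OCT frame (frame index ``k``).

    The analytic lumen section at k * frame_spacing is rotated by the spec
    twist profile and drawn as a coloured border band on an exponential
    speckle background with a bright catheter ring.  The grey background
    never matches the annotation colour tolerance, so colour thresholding
    is stressed but well-posed.  The noise stream is seeded per frame for
    reproducibility independent of rendering order.
    """
    spec = truth.spec
    rng = np.random.default_rng((spec.seed + 1) * 100003 + k)
    twist = truth.twist_profile
    if twist is not None and k >= len(twist):
        raise ParameterError(f"twist profile has no entry for frame {k}")
    off = np.asarray(catheter_offset, float)
    half_fov = (image_size / 2 - _FOV_MARGIN_PX) / cal.px_per_mm
    c = (image_size - 1) / 2.0
    s_k = k * cal.frame_spacing_mm
    pts = truth.section_contour(s_k, n=n_contour_points)
    if spec.noise > 0:
        th = np.arctan2(pts[:, 1], pts[:, 0])
        # six low-order harmonics, normalized so the pointwise radial sd
        # equals spec.noise (var = sigma^2 * (1 + 5/2))
        coef = rng.normal(0, spec.noise / math.sqrt(3.5), 6)
        pert = (coef[0] + coef[1] * np.cos(th) + coef[2] * np.sin(th)
                + coef[3] * np.cos(2 * th) + coef[4] * np.sin(2 * th)
                + coef[5] * np.cos(3 * th))
        rho = np.linalg.norm(pts, axis=1) + pert
        pts = np.column_stack([rho * np.cos(th), rho * np.sin(th)])
    if twist is not None:
        ang = math.radians(twist[k])
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        pts = pts @ R.T
    pts = pts - off   # catheter at the image centre
    if np.max(np.abs(pts)) > half_fov:
        raise RenderError(
            f"section at {s_k:.1f} mm exceeds the {2 * half_fov:.1f} mm field of view")
    col = c + pts[:, 0] * cal.px_per_mm
    row = c - pts[:, 1] * cal.px_per_mm
    ring = _ring_mask(image_size, np.column_stack([col, row]))
    gray = np.clip(rng.exponential(30.0, (image_size, image_size)),
                   0, 180).astype(np.uint8)
    img = np.stack([gray, gray, gray], axis=2)
    yy, xx = np.ogrid[:image_size, :image_size]
    rad = np.hypot(xx - c, yy - c)
    img[(rad > 8) & (rad < 13)] = 230       # bright catheter ring
    img[ring] = annotation_color
    return AnnotatedFrame(image=img, frame_index=k,
                          annotation_color=annotation_color)


def render_pullback(truth: PhantomTruth, cal: Calibration,
                    **kw) -> list[AnnotatedFrame]:
    """All pullback frames as a list (see :func:`render_frame`)."""
    return [render_frame(truth, cal, k, **kw)
            for k in range(n_pullback_frames(truth, cal))]


def iter_rendered_frames(truth: PhantomTruth, cal: Calibration, **kw):
    """Lazy generator over pullback frames (bounded memory)."""
    for k in range(n_pullback_frames(truth, cal)):
        yield render_frame(truth, cal, k, **kw)


def make_ccta_like_cloud(mesh: SurfaceMesh, truth: PhantomTruth,
                         resolution: float = 0.4, density: float = 10.0,
                         seed: int | None = None):
    """CCTA-like lumen surface cloud: sampled, noisy, grid-quantized.

    Surface samples at ``density`` pts/mm² get radial (face-normal) noise
    with sd = resolution / 2 and are snapped to a ``resolution`` lattice,
    emulating CT voxelization.  Samples falling inside the main lumen or
    a branch (mesh-junction artifacts) are discarded using the analytic
    truth.
    """
    from .fusion import LABEL_CCTA, LabeledPointCloud
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    spec = truth.spec
    rng_seed = spec.seed + 2 if seed is None else seed
    n = max(int(round(density * mesh.area)), 100)
    samples, fidx = trimesh.sample.sample_surface(mesh, n, seed=rng_seed)
    samples = np.asarray(samples, float)
    normals = mesh.face_normals[fidx]
    rng = np.random.default_rng(rng_seed)
    noisy = samples + normals * rng.normal(0, resolution / 2, (len(samples), 1))
    # discard junction artifacts: points clearly interior to the main lumen
    from scipy.spatial import cKDTree

    from .fusion import _points_to_polyline
    cl = truth.centerline
    d_axis = _points_to_polyline(noisy, cl.points)
    si = cKDTree(cl.points).query(noisy)[1]
    r_local = spec.radius_at(cl.cumulative_arclength[si])
    keep = d_axis > 0.6 * r_local
    noisy = noisy[keep]
    quant = np.round(noisy / resolution) * resolution
    return LabeledPointCloud(quant, np.full(len(quant), LABEL_CCTA, object))


def phantom_landmarks(truth: PhantomTruth, cal: Calibration,
                      branch: int = 0):
    """Carina landmark pair for one phantom side branch.

    Emulates the manual annotation: the OCT carina point is the lumen
    border point in the branch direction on the frame nearest the branch
    (in that frame's rendered, i.e. twisted, coordinates); the CCTA
    main/side projection points straddle the ostium surface point so
    their midpoint sits on the ostium.
    """
    from .registration import LandmarkPair
    spec = truth.spec
    pos = truth.branch_positions[branch]
    base, dir3, angle = truth.branch_frames[branch]
    k = int(round(pos / cal.frame_spacing_mm))
    s_k = k * cal.frame_spacing_mm
    a, b = spec.semi_axes_at(s_k)
    phi = math.radians(angle)
    # ellipse border radius along direction phi
    r_dir = (a * b) / math.hypot(b * math.cos(phi), a * math.sin(phi))
    p = np.array([r_dir * math.cos(phi), r_dir * math.sin(phi)])
    if truth.twist_profile is not None:
        ang = math.radians(truth.twist_profile[k])
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        p = R @ p
    surface_pt = base + r_dir * dir3
    return LandmarkPair(
        oct_frame_index=k, oct_carina_point=p,
        ccta_main_point=surface_pt - 0.5 * dir3,
        ccta_side_point=surface_pt + 0.5 * dir3)


def bloomed_calcifications(truth: PhantomTruth) -> list[SurfaceMesh]:
    """CT-style bloomed versions of the true calcification meshes."""
    out = []
    for (pos, ext, th, bloom), m in zip(truth.spec.calcifications,
                                        truth.calcification_meshes):
        out.append(bloom_mesh(m, bloom))
    return out


# --- shipped scenarios -----------------------------------------------------

def preset_spec(name: str, seed: int = 0) -> PhantomSpec:
    """Named phantom scenarios used throughout the tests and examples.

    ``patient12-like``: severe 89 %AS stenosis, two side branches 16 mm
    apart, no calcification.  ``patient7-like``: 80 %AS with one bloomed
    calcification.  Both are 40 mm gently curved vessels — long enough to
    carry two branches and a stenosis while keeping the rendered pullback
    small.
    """
    if name == "patient12-like":
        return PhantomSpec(
            centerline_kind="planar-arc", length=40.0, base_radius=1.75,
            stenoses=[(20.0, 0.668, 2.5)], ellipticity=1.3,
            side_branches=[(12.0, 0.6, 60.0), (28.0, 0.7, 200.0)],
            calcifications=[], noise=0.02, seed=seed)
    if name == "patient7-like":
        return PhantomSpec(
            centerline_kind="planar-arc", length=40.0, base_radius=1.6,
            stenoses=[(18.0, 0.553, 2.5)], ellipticity=1.25,
            side_branches=[(10.0, 0.6, 90.0), (26.0, 0.7, 250.0)],
            calcifications=[(24.0, 60.0, 0.5, 0.5)], noise=0.02, seed=seed)
    raise ParameterError(f"unknown preset {name!r}")


PRESETS = ("patient12-like", "patient7-like")
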