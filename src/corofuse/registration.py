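"""Catheter twist correction and OCT-to-CCTA stack registration.

Pullback catheters rotate axially during withdrawal; consecutive frames
are therefore re-aligned by searching a small rotation window (default
±3°) for the angle maximizing the polygon overlap with the previously
corrected frame, and the corrections accumulate along the pullback.  The
corrected stack is then anchored on the CCTA centerline at the carina of
a bifurcation visible in both modalities and stacked frame-by-frame in
planes orthogonal to the centerline.  Out-of-plane rotations are not
modelled; the inter-frame relative pose is kept rigid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import (CoverageError, LandmarkMismatchError, ParameterError,
                     ZeroOverlapError)
from .geometry import (Centerline, Contour2D, Contour3D, contour_to_3d,
                       resample_centerline, resample_closed_contour,
                       transport_frames)
from .oct_processing import PullbackSeries

log = logging.getLogger(__name__)


@dataclass
class TwistConfig:
    """Search window for the pairwise twist angle.

    angle_range_deg: symmetric bound of the per-pair search (default 3.0)
    angle_step_deg: grid resolution (default 0.1)
    resample_n: contour samples used for the overlap polygons
    """

    angle_range_deg: float = 3.0
    angle_step_deg: float = 0.1
    resample_n: int = 256

    def __post_init__(self):
        if self.angle_range_deg <= 0 or self.angle_step_deg <= 0:
            raise ParameterError("twist range and step must be positive")
        if self.angle_step_deg > self.angle_range_deg:
            raise ParameterError("twist step must not exceed the range")

    def grid(self) -> np.ndarray:
        n = int(round(self.angle_range_deg / self.angle_step_deg))
        return np.linspace(-n, n, 2 * n + 1) * self.angle_step_deg


@dataclass
class LandmarkPair:
    """Carina landmark seen in both modalities.

    The OCT side is a frame index plus the carina point in that frame's
    mm coordinates; the CCTA side is a pair of 3D projection points on
    the main and side branch whose midpoint defines the registration
    point.
    """

    oct_frame_index: int
    oct_carina_point: np.ndarray        # (x, y) mm, frame coordinates
    ccta_main_point: np.ndarray         # (x, y, z) mm
    ccta_side_point: np.ndarray         # (x, y, z) mm

    def __post_init__(self):
        self.oct_carina_point = np.asarray(self.oct_carina_point, float)
        self.ccta_main_point = np.asarray(self.ccta_main_point, float)
        self.ccta_side_point = np.asarray(self.ccta_side_point, float)
        if self.oct_carina_point.shape != (2,):
            raise ParameterError("oct_carina_point must be (x, y)")
        if np.allclose(self.ccta_main_point, self.ccta_side_point):
            raise ParameterError("CCTA main and side projection points coincide")


@dataclass
class RegisteredStack:
    """OCT contours placed in 3D on the resampled centerline."""

    contours3d: list[Contour3D]
    centerline: Centerline
    landmark_centerline_index: int
    frame_indices: list[int] = field(default_factory=list)

    def all_points(self) -> np.ndarray:
        return np.vstack([c.points for c in self.contours3d])


def _rotated_polygon(points: np.ndarray, angle_deg: float) -> Polygon:
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return Polygon(points @ R.T)


def pairwise_twist_angle(c_prev: Contour2D, c_next: Contour2D,
                         cfg: TwistConfig | None = None) -> float:
    """Rotation of ``c_next`` about the origin maximizing overlap with ``c_prev``.

    Grid search over the ±range window; ties are broken toward the
    smallest |angle| and then toward the negative angle, so rotationally
    symmetric contours return 0.
    """
    cfg = cfg or TwistConfig()
    p_prev = Polygon(resample_closed_contour(c_prev, cfg.resample_n).points)
    pts_next = resample_closed_contour(c_next, cfg.resample_n).points
    best_area = -1.0
    best_angle = 0.0
    # iterate in tie-break priority order: |angle| ascending, negative first
    for angle in sorted(cfg.grid(), key=lambda a: (abs(a), a)):
        inter = p_prev.intersection(_rotated_polygon(pts_next, angle))
        area = inter.area
        if area > best_area * (1.0 + 1e-12) and area > best_area + 1e-15:
            best_area, best_angle = area, float(angle)
    if best_area <= 0.0:
        raise ZeroOverlapError("contours share no area at any candidate rotation")
    return best_angle


def correct_twist(series: PullbackSeries, cfg: TwistConfig | None = None) -> PullbackSeries:
    """Accumulate pairwise corrective rotations along the pullback.

    Frame k is first rotated by the cumulative correction of frame k-1,
    then refined within the ±range window against the already-corrected
    predecessor.  Angles at the window boundary are logged: the true
    inter-frame twist may exceed the window and the residual is then not
    recoverable.
    """
    cfg = cfg or TwistConfig()
    if len(series) < 2:
        raise ParameterError("twist correction needs at least 2 contours")
    corrected = [series.contours[0]]
    cum = np.zeros(len(series))
    for k in range(1, len(series)):
        carried = series.contours[k].rotated(cum[k - 1])
        try:
            a = pairwise_twist_angle(corrected[-1], carried, cfg)
        except ZeroOverlapError as e:
            raise ZeroOverlapError(
                f"zero overlap at frame {series.frame_indices[k]}: {e}") from e
        if abs(abs(a) - cfg.angle_range_deg) < 1e-9:
            log.warning("twist window boundary hit at frame %d (angle %+.1f deg); "
                        "residual twist may remain", series.frame_indices[k], a)
        cum[k] = cum[k - 1] + a
        corrected.append(series.contours[k].rotated(cum[k]))
    return PullbackSeries(contours=corrected, calibration=series.calibration,
                          frame_indices=list(series.frame_indices),
                          twist_angles=cum)


def carina_registration_point(lm: LandmarkPair, cl: Centerline,
                              gate_mm: float = 5.0) -> tuple[np.ndarray, int]:
    """Midpoint of the CCTA projection points, snapped to the centerline.

    Returns the nearest (resampled) centerline point and its index; the
    raw midpoint farther than ``gate_mm`` from the centerline indicates a
    mislabelled landmark and raises.
    """
    mid = 0.5 * (lm.ccta_main_point + lm.ccta_side_point)
    d = np.linalg.norm(cl.points - mid, axis=1)
    i = int(np.argmin(d))
    if d[i] > gate_mm:
        raise LandmarkMismatchError(
            f"carina midpoint is {d[i]:.2f} mm from the centerline (gate {gate_mm} mm)")
    return cl.points[i].copy(), i


def _signed_angle(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """CCW angle (radians) taking v_from to v_to in the plane."""
    return math.atan2(v_from[0] * v_to[1] - v_from[1] * v_to[0],
                      float(v_from @ v_to))


def register_pullback(series: PullbackSeries, cl: Centerline, lm: LandmarkPair,
                      *, mode: str = "anchor", gate_mm: float = 5.0,
                      reverse: bool = False) -> RegisteredStack:
    """Place the twist-corrected contour stack onto the CCTA centerline.

    The centerline is resampled so point spacing matches the frame
    spacing; the landmark frame is anchored at the carina registration
    point by an in-plane translation (carina pixel point -> CCTA carina
    midpoint) and an in-plane rotation aligning the frame's carina
    direction with the projected side-branch direction.  All other frames
    reuse the same in-plane pose in their transported frames, preserving
    the inter-frame relative position; each contour lies in the plane
    orthogonal to the local tangent.  ``mode='centroid'`` additionally
    snaps every contour centroid onto its centerline point (catheter path
    = centerline assumption).  Frames falling off the centerline are
    dropped with a warning.
    """
    if mode not in ("anchor", "centroid"):
        raise ParameterError(f"unknown placement mode {mode!r}")
    spacing = series.calibration.frame_spacing_mm
    rcl = transport_frames(resample_centerline(cl, spacing))
    _, i_car = carina_registration_point(lm, rcl, gate_mm=gate_mm)
    if lm.oct_frame_index not in series.frame_indices:
        raise ParameterError(
            f"landmark frame {lm.oct_frame_index} not in the pullback series")
    k_car = series.frame_indices.index(lm.oct_frame_index)

    # carina direction in the (twist-corrected) landmark frame
    p_car = np.asarray(lm.oct_carina_point, float)
    if series.twist_angles.size:
        a = math.radians(series.twist_angles[k_car])
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        p_car = R @ p_car
    if np.linalg.norm(p_car) < 1e-9:
        raise ParameterError("OCT carina point coincides with the catheter axis")

    # target direction & translation in the landmark plane
    _, e1, e2 = rcl.frames[i_car]
    origin = rcl.points[i_car]
    mid = 0.5 * (lm.ccta_main_point + lm.ccta_side_point)
    side = lm.ccta_side_point - origin
    side_ip = np.array([side @ e1, side @ e2])
    if np.linalg.norm(side_ip) < 1e-9:
        raise LandmarkMismatchError("side-branch direction is parallel to the tangent")
    alpha = _signed_angle(p_car, side_ip)
    Ra = np.array([[math.cos(alpha), -math.sin(alpha)],
                   [math.sin(alpha), math.cos(alpha)]])
    mid_ip = np.array([(mid - origin) @ e1, (mid - origin) @ e2])
    t_ip = mid_ip - Ra @ p_car

    step = -1 if reverse else 1
    contours3d: list[Contour3D] = []
    kept_indices: list[int] = []
    dropped = 0
    for k, contour in enumerate(series.contours):
        i = i_car + step * (k - k_car)
        if i < 0 or i >= rcl.n_points:
            dropped += 1
            continue
        local = contour.points @ Ra.T + t_ip
        if mode == "centroid":
            local = local - Contour2D(local).centroid()
        _, f1, f2 = rcl.frames[i]
        c3 = contour_to_3d(Contour2D(local), rcl.points[i], f1, f2,
                           rcl.frames[i][0], i)
        contours3d.append(c3)
        kept_indices.append(series.frame_indices[k])
    if dropped:
        log.warning("dropped %d frames extending beyond the centerline "
                    "(%.1f mm)", dropped, dropped * spacing)
    if not contours3d:
        raise CoverageError("no OCT frame could be hosted on the centerline")
    return RegisteredStack(contours3d=contours3d, centerline=rcl,
                           landmark_centerline_index=i_car,
                           frame_indices=kept_indices)
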