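"""Model validation: vertex-distance statistics, lumen-area profiles,
stenosis quantification and regression summaries.

Two complementary comparisons of an original model (OM) against a
derivative model (DM): (1) per-vertex nearest-surface distances with a
small-distance exclusion (default 0.05 mm) to avoid bias from negligible
meshing differences, summarized as median and IQR; (2) centerline-resolved
lumen areas, compared both absolutely (area difference) and as z-scores
(A - mu) / sigma, which removes systematic size offsets between the
models.  Stenosis severity is %AS = (RVA - MLA) / RVA * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NoReferenceError, ParameterError, ProfileError
from .geometry import (Centerline, Plane, SurfaceMesh, plane_mesh_section,
                       polygon_area, transport_frames)
from .proximity import MeshDistance


@dataclass
class ValidationConfig:
    """Vertex-distance exclusion threshold (mm, default 0.05)."""

    vd_exclusion_mm: float = 0.05

    def __post_init__(self):
        if self.vd_exclusion_mm < 0:
            raise ParameterError("exclusion threshold must be >= 0")


@dataclass
class AreaProfile:
    """Per-centerline-point lumen areas with z-score normalization.

    Missing sections are NaN; mu and sigma (population convention) are
    computed over the finite entries.
    """

    centerline_indices: np.ndarray
    areas: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    zscores: np.ndarray = field(init=False)

    def __post_init__(self):
        self.centerline_indices = np.asarray(self.centerline_indices, int)
        self.areas = np.asarray(self.areas, float)
        if len(self.centerline_indices) != len(self.areas):
            raise ParameterError("indices and areas must have equal length")
        fin = np.isfinite(self.areas)
        if not fin.any():
            raise ProfileError("area profile has no finite entries")
        self.mean = float(np.mean(self.areas[fin]))
        self.sd = float(np.std(self.areas[fin]))   # population convention
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zscores = ((self.areas - self.mean) / self.sd
                            if self.sd > 0 else np.zeros_like(self.areas))


@dataclass
class StenosisMetrics:
    """Reference vessel area, minimum lumen area and %AS."""

    RVA: float
    MLA: float
    pct_AS: float
    mla_index: int
    rva_index: int


@dataclass
class VDStats:
    """Vertex-distance summary; ``degenerate`` when all distances were excluded."""

    median: float
    iqr: tuple
    distances: np.ndarray
    n_excluded: int
    degenerate: bool = False


@dataclass
class ValidationReport:
    """Full OM-vs-DM comparison (VD, AD, z-scores, regression)."""

    vd_median: float
    vd_iqr: tuple
    ad_median: float
    ad_iqr: tuple
    zdiff_mean: float
    zdiff_sd: float
    r_squared: float
    per_vertex_distances: np.ndarray
    degenerate_vd: bool = False


def pct_area_stenosis(RVA: float, MLA: float) -> float:
    """Percent area stenosis, (RVA - MLA) / RVA * 100."""
    if RVA <= 0:
        raise ParameterError(f"RVA must be positive, got {RVA}")
    if MLA < 0 or MLA > RVA:
        raise ParameterError(
            f"MLA must satisfy 0 <= MLA <= RVA (got MLA={MLA}, RVA={RVA}); "
            "the reference must be the larger, healthier area")
    return (RVA - MLA) / RVA * 100.0


def _moving_median(a: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(a, float)
    for i in range(len(a)):
        lo, hi = max(0, i - half), min(len(a), i + half + 1)
        out[i] = np.median(a[lo:hi])
    return out


def stenosis_from_profile(profile: AreaProfile, search_window=None,
                          median_window: int = 5) -> StenosisMetrics:
    """Locate the MLA and a proximal reference area on an area profile.

    The profile runs proximal -> distal.  MLA is the minimum area in the
    search window (last occurrence on ties); the RVA automates the manual
    "healthier proximal segment" choice as the maximum of a moving-median
    smoothed profile over the indices proximal to the MLA.
    """
    fin = np.isfinite(profile.areas)
    idx = np.nonzero(fin)[0]
    if search_window is not None:
        lo, hi = search_window
        idx = idx[(profile.centerline_indices[idx] >= lo)
                  & (profile.centerline_indices[idx] <= hi)]
    if len(idx) < 5:
        raise ProfileError("stenosis search needs at least 5 profile points")
    a = profile.areas[idx]
    mla_pos = int(np.nonzero(a == a.min())[0][-1])
    mla = float(a[mla_pos])
    if mla_pos == 0:
        raise NoReferenceError(
            "MLA at the proximal boundary; no proximal reference segment")
    smoothed = _moving_median(a[:mla_pos], median_window)
    rva_pos = int(np.argmax(smoothed))
    rva = float(smoothed[rva_pos])
    return StenosisMetrics(RVA=rva, MLA=mla,
                           pct_AS=pct_area_stenosis(rva, mla),
                           mla_index=int(profile.centerline_indices[idx[mla_pos]]),
                           rva_index=int(profile.centerline_indices[idx[rva_pos]]))


def lumen_area_profile(mesh: SurfaceMesh, cl: Centerline,
                       min_sections: int = 5) -> AreaProfile:
    """Lumen area at every centerline point from perpendicular plane cuts.

    When a cut yields several closed components the one nearest the
    centerline point is the lumen; points with no intersection are NaN
    (missing), not zero.
    """
    rcl = cl if cl.frames is not None else transport_frames(cl)
    areas = np.full(rcl.n_points, np.nan)
    for i in range(rcl.n_points):
        plane = Plane(rcl.points[i], rcl.frames[i][0])
        sections = plane_mesh_section(mesh, plane)
        if not sections:
            continue
        best = min(sections, key=lambda c: float(np.linalg.norm(c.centroid())))
        areas[i] = polygon_area(best)
    if np.count_nonzero(np.isfinite(areas)) < min_sections:
        raise ProfileError("fewer than 5 valid cross-sections along the centerline")
    return AreaProfile(np.arange(rcl.n_points), areas)


def vertex_distance_stats(dm: SurfaceMesh, om: SurfaceMesh,
                          cfg: ValidationConfig | None = None) -> VDStats:
    """DM-vertex to OM-surface distances with small-distance exclusion.

    Point-to-triangle (not vertex-to-vertex) distances; values below the
    exclusion threshold are dropped from the median/IQR but kept in the
    full list for heatmap export.  If everything is excluded the result
    is flagged degenerate with NaN statistics.
    """
    cfg = cfg or ValidationConfig()
    if len(dm.vertices) == 0 or len(om.vertices) == 0:
        raise ParameterError("both meshes must be nonempty")
    _, d, _ = MeshDistance(om).query(dm.vertices)
    retained = d[d >= cfg.vd_exclusion_mm]
    if len(retained) == 0:
        return VDStats(median=float("nan"), iqr=(float("nan"), float("nan")),
                       distances=d, n_excluded=len(d), degenerate=True)
    q1, med, q3 = np.percentile(retained, [25, 50, 75])  # linear interpolation
    return VDStats(median=float(med), iqr=(float(q1), float(q3)), distances=d,
                   n_excluded=int(len(d) - len(retained)))


def area_difference_stats(om_profile: AreaProfile, dm_profile: AreaProfile) -> dict:
    """Paired |area difference| and |z-score difference| statistics.

    Profiles must live on the same resampled centerline; indices missing
    in either profile are dropped pairwise.  z-differences use z-scores
    recomputed over the shared support so that affine (shift/scale)
    perturbations of one profile cancel exactly.
    """
    shared, ia, ib = np.intersect1d(om_profile.centerline_indices,
                                    dm_profile.centerline_indices,
                                    return_indices=True)
    a_om = om_profile.areas[ia]
    a_dm = dm_profile.areas[ib]
    fin = np.isfinite(a_om) & np.isfinite(a_dm)
    if np.count_nonzero(fin) < 5:
        raise ProfileError("fewer than 5 shared profile indices")
    a_om, a_dm = a_om[fin], a_dm[fin]
    z_om = (a_om - a_om.mean()) / a_om.std()
    z_dm = (a_dm - a_dm.mean()) / a_dm.std()
    ad = np.abs(a_om - a_dm)
    zdiff = np.abs(z_om - z_dm)
    q1, med, q3 = np.percentile(ad, [25, 50, 75])
    slope, intercept, r2 = regression_slope_r2(z_om, z_dm)
    return {
        "ad_median": float(med), "ad_iqr": (float(q1), float(q3)),
        "zdiff_mean": float(zdiff.mean()), "zdiff_sd": float(zdiff.std()),
        "z_slope": slope, "z_intercept": intercept, "r_squared": r2,
        "n_pairs": int(len(ad)),
    }


def regression_slope_r2(x, y) -> tuple[float, float, float]:
    """OLS slope/intercept and R² (squared Pearson correlation)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ParameterError("regression needs >=3 paired values")
    if np.ptp(x) == 0:
        raise ParameterError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def side_branch_distance(series_or_stack, frame_i: int, frame_j: int) -> int:
    """Along-pullback distance between two side-branch frames, in whole mm.

    |i - j| x frame spacing, rounded to the millimetre for report parity
    with clinically read inter-branch distances.
    """
    if frame_i == frame_j:
        raise ParameterError("side-branch frames must differ")
    if hasattr(series_or_stack, "calibration"):
        spacing = series_or_stack.calibration.frame_spacing_mm
        indices = series_or_stack.frame_indices
    else:
        cl = series_or_stack.centerline
        spacing = float(cl.cumulative_arclength[1] - cl.cumulative_arclength[0])
        indices = series_or_stack.frame_indices
    for f in (frame_i, frame_j):
        if f not in indices:
            raise ParameterError(f"frame {f} not in the series")
    return int(round(abs(frame_i - frame_j) * spacing))


def validate_models(om: SurfaceMesh, dm: SurfaceMesh, cl: Centerline,
                    cfg: ValidationConfig | None = None) -> ValidationReport:
    """Full OM-vs-DM report: VD stats plus centerline-resolved area comparison."""
    cfg = cfg or ValidationConfig()
    vd = vertex_distance_stats(dm, om, cfg)
    rcl = cl if cl.frames is not None else transport_frames(cl)
    om_prof = lumen_area_profile(om, rcl)
    dm_prof = lumen_area_profile(dm, rcl)
    ad = area_difference_stats(om_prof, dm_prof)
    return ValidationReport(
        vd_median=vd.median, vd_iqr=vd.iqr,
        ad_median=ad["ad_median"], ad_iqr=ad["ad_iqr"],
        zdiff_mean=ad["zdiff_mean"], zdiff_sd=ad["zdiff_sd"],
        r_squared=ad["r_squared"], per_vertex_distances=vd.distances,
        degenerate_vd=vd.degenerate)
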