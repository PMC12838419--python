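# Methods

This note records the models, parameter choices and numerical decisions
behind `corofuse`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Imaging model and assumptions

The workflow fuses two acquisitions of the same coronary segment:

- an intravascular OCT pullback (motorized, nominally 40 mm/s over 75 mm)
  whose frames carry a pre-annotated lumen border in a distinct colour,
  1024×1024 px with 103 px per mm;
- a CCTA-derived export: a centerline as an `x y z` text point list, a lumen
  surface mesh, and optional calcification meshes (all in mm).

Assumptions inherited from the acquisition setting:

1. **Catheter ≈ centerline.** The OCT catheter is assumed to follow the
   vessel centerline approximately; each frame is treated as a rigid planar
   section orthogonal to the centerline.  Out-of-plane rotations are not
   modelled.  Placement offers two modes: *anchor* (default), which applies
   the single landmark-derived in-plane pose to every frame so the relative
   frame-to-frame position is untouched, and *centroid*, which additionally
   snaps each contour centroid onto its centerline point.
2. **Axial twist is slow.** Catheter rotation between consecutive frames is
   within ±3°; larger jumps are clamped at the window edge and logged (the
   residual is then unrecoverable by design — widening the window would
   trade robustness for it).
3. **The annotated border is trustworthy.** No raw-image lumen detection is
   attempted; the annotation colour (default pure green, ±30 per channel) and
   its band thickness are properties of the upstream export.

## Stage-by-stage choices

### Contour extraction

Colour threshold → Gaussian smoothing (σ = 2 px) → re-threshold at 0.3 of
the smoothed maximum.  The relative threshold makes the stage exposure-
independent: an isolated stray pixel of the annotation colour smooths to a
few percent of a border band's plateau and dies, while dashed gaps up to
about 2σ bridge.  The mask is closed by a convex hull.  Because the
annotation is a band of finite thickness centred on the true border, the
hull traces the band's *outer* edge; when the mask is band-like (foreground
area < half the hull area) the hull is offset inward by the estimated band
half-thickness (foreground area / hull perimeter / 2).  Filled masks are
left untouched.  The corrected hull is densified along its edges and fitted
with a periodic cubic B-spline (smoothing s = 0 by default, exposed), then
sampled at 256 points and converted to mm: origin at the image centre
(catheter axis), y up.  Any constant origin error is absorbed by the
registration translation.

### Twist correction

For each consecutive pair the corrective rotation is the grid argmax
(±3°, step 0.1°) of the exact polygon intersection area between the
candidate (pre-rotated by the predecessor's cumulative correction) and the
corrected predecessor, both resampled to 256-gons.  Exact clipping rather
than rasterized overlap keeps the objective deterministic and resolution-
independent.  Ties break toward the smallest |angle| and then the negative
angle, so rotationally symmetric lumens return 0.  The sign convention is:
positive = counter-clockwise in the frame plane viewed against the tangent.
On near-circular lumens the per-pair estimate is noise-limited — rotation is
then ill-determined but also geometrically inconsequential (it changes no
area and no centroid).

### Registration

The centerline is resampled to the OCT frame spacing so stack index maps to
centerline index, and given rotation-minimizing frames by double-reflection
transport.  Frenet frames were rejected: they are undefined on straight
segments and inject torsion-driven spin that would masquerade as catheter
twist.  The carina registration point is the midpoint of the CCTA main/side
projection points snapped to the nearest resampled centerline point (gate:
5 mm).  The landmark frame's in-plane rotation aligns its carina direction
(after twist correction) with the side-branch direction projected into the
contour plane — the geometrically meaningful reference, since no rotation
reference is otherwise defined.  Frames extending beyond the centerline are
dropped with a warning.

### Fusion and reconstruction

CCTA mesh → labelled point cloud (vertices + area-weighted samples,
default 10 points/mm²).  CCTA points strictly closer than 0.35 mm to any
OCT point are removed (equality keeps the point).  Residual clutter removal
is declarative — sphere/box/centerline-tube predicates recorded in the
config — replacing interactive point selection so runs are reproducible.

Surface reconstruction is a centerline-guided polar loft: points are
assigned to their nearest centerline station, expressed in the station's
transported frame, trimmed of radial outliers (> 2× the station median
radius, which discards side-branch points), binned into 64 angular sectors
whose ring radius is the median sample radius, interpolated across empty
sectors and sparse stations, smoothed axially (window 3), lofted and capped.
The result is watertight by construction.  This choice favours robustness
on noisy multi-source tubular clouds over generality: it cannot represent
bifurcation lumens as such (branch stubs survive only in the point cloud),
and it assumes the cloud is star-shaped around the centerline — true for
coronary lumens at CT/OCT scales.

The wall is a uniform outward offset (default 1 mm) along area-weighted
vertex normals; meshes with edges longer than the thickness are subdivided
first, since sparse vertices carry averaged (beveled) normals.  The solid is
bounded by the offset surface and the reversed lumen surface.

### Calcifications

CT blooming systematically enlarges calcifications; a uniform 0.5 mm inward
offset compensates.  Two equivalent modes are provided: per-section polygon
erosion (shapely, round joins — erosion of smooth anatomic contours should
not mint corners; mitre available) which is the validated reference, and a
3D inward vertex-normal offset for embedding.  Cross-sections are taken as
the largest-area component of the plane–mesh intersection, and summarized
by area, perimeter and the equal-area-circle radius √(A/π).

Embedding is a boolean union evaluated on a voxel signed-distance grid
(default pitch 0.15 mm) followed by marching cubes.  The signed distance
uses a nearest-vertex angle-weighted pseudo-normal test, with exact
point-to-triangle refinement in a shell around the surface; inputs are
subdivided so edge lengths stay within 3 voxel pitches.  The marching-cubes
output is kept raw — it is manifold as produced, and vertex merging would
re-open it.

### Validation metrics

- **Vertex distance (VD):** for each derivative-model vertex, the distance
  to the nearest point on the original-model *surface* (point-to-triangle,
  not vertex-to-vertex, avoiding tessellation-density artifacts; direction
  DM→OM by default).  Distances below 0.05 mm are excluded from the
  median/IQR — a conservative convention, since dropping near-zero values
  can only raise the median; if everything is excluded the comparison is
  flagged degenerate rather than reported as 0.
- **Area profiles:** lumen area at every centerline point from
  perpendicular plane sections (nearest component when several); missing
  sections are missing, not zero.  z-scores use the population σ (divide by
  N); the convention is switchable and documented because it is
  report-facing.  Quartiles use linear interpolation.
- **Stenosis:** %AS = (RVA − MLA)/RVA × 100.  The MLA is the profile
  minimum (last index on exact ties, so a constant profile yields 0 %AS
  rather than a spurious no-reference failure); the RVA automates the
  manual "healthier proximal segment" choice as the maximum of a moving-
  median (window 5) over the proximal indices.  An MLA at the proximal
  boundary has no reference and raises.
- **Regression:** OLS slope/intercept; R² as squared Pearson correlation.
- **Side-branch separation:** |Δframe| × frame spacing, rounded to whole mm
  to match how inter-branch distances are clinically read.

## The synthetic phantom generator

`corofuse.phantom` generates parametric vessels with full ground truth:
centerline (straight / planar arc / helix / seeded spline), elliptical lumen
of area πr(s)² with Gaussian stenoses
r(s) = r₀(1 − Σ dᵢ exp(−(s−pᵢ)²/2wᵢ²)), side branches, wall calcifications
(ellipsoids just outside the lumen), a per-frame cumulative twist profile,
and smooth low-order-harmonic delineation noise whose pointwise radial sd
equals the `noise` parameter (default 0.02 mm ≈ 2 px of manual jitter).

What it emulates: annotation-colour border bands of realistic thickness on
an exponential-speckle background with a bright catheter ring (stressing
colour thresholding and the band-centring correction); CT voxelization as
surface sampling with radial noise (sd = resolution/2) snapped to a 0.4 mm
lattice; CT blooming as a 0.5 mm outward mesh dilation.

What it does not emulate: OCT light transport (no attenuation, guide-wire
shadows, blood artifacts), CT reconstruction physics, cardiac motion,
catheter eccentricity dynamics, or the lumen opening at bifurcation ostia
(frames are always full ellipses).  Passing the synthetic loop therefore
demonstrates the geometry pipeline — calibration, twist bookkeeping,
registration arithmetic, fusion and metric computation — not robustness to
clinical image artifacts, which the upstream annotation software handles.

The Gaussian stenosis parameterization was chosen for differentiable
analytic truth (true %AS = (1 − (1−d)²)·100 for an isolated narrowing).
Two shipped scenarios mirror headline severities: `patient12-like`
(89 %AS, no calcification) and `patient7-like` (80 %AS, one calcification);
the labels are scenario names, not reproduction claims.  Both use 40 mm
gently curved vessels sampled at 0.4 mm frame spacing (101 frames) — long
enough for two side branches 16 mm apart plus a stenosis, while keeping a
full simulated pullback comfortably fast; the clinical defaults (75 mm,
0.2 mm) remain the `Calibration`/`PhantomSpec` defaults.

## Degenerate inputs and tie-breaks (summary)

- Duplicate consecutive contour/centerline points merged at 1e−6 mm.
- Contours reoriented counter-clockwise on construction.
- Plane-section basis: e1 = normalized projection of global x (fallback y),
  e2 = n × e1 — deterministic, so sections are reproducible.
- Twist grid ties → smallest |angle|, then negative.
- MLA ties → most distal index.
- Overlap removal at exactly the radius → point kept.
- VD with all distances excluded → flagged degenerate, statistics NaN.

## Known limitations

- The loft reconstruction cannot mesh true bifurcation lumens; branch
  geometry survives only until meshing.
- Vertex-normal offsets (wall, 3D bloom correction) are approximate near
  high-curvature rims; the voxel-grid union bounds, but does not remove,
  self-intersection artifacts of aggressive offsets.
- Per-frame twist estimates on near-circular lumens are noise-limited;
  only elliptical lumens (eccentricity ≳ 1.2) support accurate recovery.
- The CCTA-like cloud is a geometric emulation; no claim is made about
  robustness to real CT segmentation error modes.
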