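# Methods

## Scope and data model

All grids are 3D arrays indexed `(z, y, x)`, 0-based, with voxel-centre
geometry. Voxel spacing (µm) is carried as metadata only: both thickness
measures count voxels, never micrometres, because the underlying method
is explicitly relative — absolute thickness is not comparable across
specimens of different body size, and the package makes no attempt to
calibrate it. A warning is logged when spacing is anisotropic.

Formats: NIfTI-1 for volumes, masks, thickness fields and label maps
(search radius and legend in a JSON sidecar next to the file), numbered
TIFF stacks (`slice_0000.tif` …) for grayscale volumes, ASCII PLY (with
inline RGBA) and OBJ (with a `*_thickness.csv` sidecar, since OBJ has no
vertex-scalar slot) for meshes.

## Voxel ray-run encoder

For a foreground voxel `v` and unit direction `d`, step `k` samples the
voxel `rint(v + k·d)` (numpy `rint`; an odd function, so encodings
commute with grid reflections and 90° rotations). The run counts
consecutive similar samples starting at `k = 0` (the origin always
counts) and stops at the first dissimilar sample, the grid boundary, or
when the count reaches `rmax` — so the cap is exactly `rmax`, never
`rmax + 1`. Similarity is either foreground membership (`mask` mode, the
default, since the measure is applied to segmented cuticle) or
`|g − g(v)| ≤ tol` on the grayscale (`gray_tol` mode, matching the
"similar grayscale values" formulation). The encoded value is the
maximum run over the direction set; background encodes 0.

Direction sets: 6 (axes), 26 (grid neighbours, the default — closed
under negation, so slab phantoms rotated by 90° about a grid axis encode
to exactly permuted fields), or a deterministic Fibonacci sphere lattice
for any other count. Adding directions can only increase encoded values
(tested as a property).

The production encoder is vectorised: per direction it maintains an
"alive" mask and accumulates counts through shifted-array AND steps,
breaking early once no ray survives. An independent brute-force encoder
(plain per-voxel/per-direction/per-step loops, guarded to ≤ 64³ grids)
defines the contract; the two must agree exactly, and do on every test
phantom including noisy `gray_tol` cases.

**Interpretation.** The longest similar run through a thin plate is
tangential, not transmural. On curved shells the tangential chord within
a wall of thickness `t` at outer radius `R` grows like `√(8Rt)`, so the
encoding is strictly increasing in wall thickness at fixed curvature —
the property that justifies using it for *relative* colour mapping. The
measured medians on hollow spheres (outer radius 60; walls 3, 6, 9
voxels) are 27, 39, 48: ordered correctly, far from the voxel
thicknesses. Regional ratios of this encoding are therefore reported as
ordering evidence only.

## Mesh inverse-normal measure

Marching cubes (scikit-image) on the binary mask at level 0.5. Face
winding is flipped if needed so normals point away from the foreground,
verified by sampling the mask one step along each normal (majority
vote; binary masks provide no gradient direction for free).

From each vertex, samples are taken at positions
`v − (k + ½)·step·n̂`, `k = 0, 1, …` with nearest-voxel lookup
(`step = 1.0` voxel by default; no interpolation, matching voxel-count
semantics). The half-step start matters: a marching-cubes vertex lies
exactly midway between a foreground and a background voxel centre, so
half-step sampling makes the count on an axis-aligned plate of thickness
`t` exactly `t`. Counting stops at the first background sample, the grid
boundary, or the `rmax = 105` cap.

Smoothing is Taubin-style (shrink `λ = strength`, inflate
`µ = −(strength + 0.03)` per iteration over the uniform graph
Laplacian), chosen over plain Laplacian smoothing because shrinkage
would bias thickness low on curved walls; enclosed volume changes by
< 0.1% at the default 2 iterations, and the raw ~9% staircase excess in
marching-cubes surface area drops within 5% of the analytic value on a
sphere.

Decimation is quadric edge collapse implemented in-package, targeting an
exact vertex budget (each collapse removes one vertex, so the default
30% reduction is hit exactly on well-formed meshes; the ±1% contract
covers meshes that run out of valid collapses). Candidate placements per
edge are midpoint and the two endpoints, cheapest-first by quadric
error; a tiny edge-length term breaks the ties of flat regions, which
otherwise concentrate collapses and degenerate the mesh. Collapses that
would flip a face normal, create a zero-area face, or violate the edge
link condition are rejected. Winding — hence outward orientation — is
preserved; normals are recomputed after every geometry-changing stage
and re-verified against the mask before thickness is measured.

Inner shell surfaces measure the same wall from the opposite side and
are deliberately kept; both surfaces carry the transmural count.

Colour coding: scalars are affinely windowed (default: observed
min/max; a constant field requires an explicit window) to [0, 1] and
mapped through a piecewise-linear palette whose default runs blue →
cyan → green → yellow → red, preserving scalar order in palette
position.

## Phantoms

A voxel is foreground iff its centre lies inside the analytic surface;
the grayscale volume is `fg_gray`/`bg_gray` plus seeded Gaussian noise,
and the mask is computed from geometry only — noise never moves it.
Ground truth carries the analytic local wall thickness (0 on
background), region labels, and the true pouch depth / capsule length.

* **slab** — plate of thickness `t` along z, optionally rotated about
  the x index axis (generated from half-space tests, not resampling, so
  rotated geometry is exact). Truth: `t` everywhere.
* **spherical_shell** — `R − t < ‖p − c‖ ≤ R`. Truth: `t`.
* **solid_cube** — fills the grid minus margins; the saturation case.
* **capsule_pouch** — cylindrical capsule (tube wall + flat end discs,
  thickness `t`) along z; a cylindrical pouch of lumen radius ≈ `R/5`
  bored from the anterior disc to depth `DP = fraction × CL`, closed by
  an end cap. The bore's annular wall has thickness `f·t` on the ventral
  sector (±60° about the ventral pole), `t` on the dorsal sector, with a
  linear angular blend between them — the blend keeps the wall surface
  continuous (a radial step would corrupt mesh normals at the seam).
  Labels: 1 ventral wall, 2 dorsal wall, 3 brood-canal analogue (a
  ventral strip of the capsule wall thinning linearly from `f·t` to `t`
  toward the posterior), 4 control, 5 the blend wedges. Label 5 exists
  so that regions 1 and 2 have exactly constant truth; blend vertices
  and voxels are excluded from the ventral/dorsal ratio. `CL` is the
  grid z-extent minus the 2-voxel margins.

Flat end discs (rather than hemispherical caps) keep every wall an
axis-aligned slab or annulus with exact analytic thickness. Default
demonstration geometry: grid 100×64×64, `R = 27`, `t = 5`, factor 2,
fraction 0.25 — large enough that both walls span many voxels, small
enough that the full pipeline runs in tens of seconds.

**Cohorts.** Species trait quartets (DP, CL, PL, LA) are drawn from a
seeded multivariate Gaussian over (DP, PL, LA) with target correlation
`ρ` of DP with PL and with LA; corr(PL, LA) is set to `ρ²`, the value
induced by the latent model PL, LA = ρ·DP + independent noise, which is
positive semi-definite for every `ρ ∈ [−1, 1]`. No distributional form
is prescribed by the source analysis; the Gaussian is chosen for
analytic tractability. Rows violating positivity or LA ≤ PL are redrawn
(rare at the default means: DP 200 ± 40, PL 210 ± 40, LA 60 ± 12 µm,
a plausible stylopid scale). CL is set to 5 × DP (pouch depth 20% of
cephalothorax length, the range reported for well-developed stylopid
pouches) since the cohort model does not otherwise constrain it.

**What the phantoms do not emulate:** X-ray physics (phase retrieval,
ring artefacts, beam hardening), staining contrast, segmentation error
beyond additive Gaussian noise, the true free-form anatomy of pouch and
auricles, or the unknown landmarking protocol behind real DP/CL
measurements (the capsule convention — DP along the bore axis, CL the
capsule z-extent — is this package's own). Passing tests show the
measures behave correctly on controlled geometry; they do not certify
segmentation quality on real scans.

## Morphometrics

`pouch_depth_percent(DP, CL) = 100·DP/CL` (scale-invariant; errors on
DP > CL or CL ≤ 0). `fit_ratio(PL, DP) = PL/DP`, with 1.0 encoding a
geometrically perfect fit; the full 3D virtual-insertion rendering is
reduced to this scalar. Regional contrast averages the encoded field
over labelled voxels (or mesh scalars over vertices mapped to their
nearest foreground voxel via an exact Euclidean distance transform);
the site/control ratio pools the two pouch walls by voxel count.
Correlation is Pearson (primary) with a Fisher-z 95% CI
(`tanh(atanh r ± 1.96/√(n−3))`), Spearman alongside with a seeded
bootstrap CI; cohorts of n ≤ 8 are flagged underpowered in pipeline
reports. Degenerate cases (|r| = 1 or n = 3) report the widest honest
interval rather than a Fisher interval.

## Numerical and design choices

* Run counting includes the origin and saturates at exactly `rmax`,
  fixing the off-by-one ambiguity of "within a 90-voxel radius".
* Unit steps + `rint` rounding (not Bresenham supercover): symmetric,
  deterministic, and identically implemented in the brute-force oracle.
* Duplicate sample positions on oblique rays are counted once per step,
  in both encoders — runs measure steps survived, not unique voxels.
* Volume boundaries are dissimilar/background: runs simply stop there.
* Decimation determinism: heap ties break on insertion order; all
  container iteration is over integer keys, so repeated runs are
  bit-identical (verified end-to-end by checksum in the test suite).
* The pipeline writes uncompressed `.nii` (gzip embeds timestamps,
  which would break bit-identical manifests).
* Thickness fields are stored as integers with their `rmax` in a
  sidecar; writing a field that violates `value ≤ rmax` is refused.

## Known limitations

* The voxel encoder's value on thin flat plates of large lateral extent
  is dominated by in-plane runs (up to `rmax`); only the mesh measure
  recovers plate thickness. On curved shells the voxel encoder is a
  monotone proxy only.
* Quadric decimation targets vertex count, not error; extremely coarse
  targets (< ~100 vertices) may stall before the budget when no valid
  collapses remain.
* `gray_tol` similarity compares each sample to the *origin's* gray
  value, so long runs across slow intensity gradients can break earlier
  than a segmentation-based run would.
* Meshes are assumed to come from marching cubes on a clean mask; no
  repair of self-intersecting or non-manifold input is attempted.
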