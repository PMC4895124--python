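# Methods

## Geometry and conventions

World coordinates are metric (mm) with the origin at the tool center
point (TCP) and the rotation axis as the vertical `y` axis, pointing
up; a seed held on the tool tip occupies `y > 0`. Images use the
raster convention: 0-based pixels, `x` right, `y` down, pixel centers
at integer coordinates. A positive turntable angle turns the object
counter-clockwise seen from above; since the world frame rotates with
the object, view `i` gets `P_i = K (R_i | t_i)` with `R_i` the
rotation about `y` by `α_i` (composed with the y-down flip) and a pure
`z` translation of the working distance `d`. The world origin
therefore projects to the principal point in every view, which is what
makes principal-point shifting equivalent to lateral TCP drift under
the near-parallel viewing rays of a macro lens: all projection math is
in pixels, all world coordinates in mm, and the pixel pitch `μ` links
the two. Projection matrices are stored unnormalized; dehomogenization
happens only when a point is projected.

The rotation sign is a package convention (the carving result for a
rotationally symmetric object is sign-invariant, and the tests cover
the symmetric case); lateral components of `t_i` are deliberately
zero — all lateral pose error is modelled in the principal point.

## Segmentation and TCP estimation

Segmentation is plain gray-value thresholding (Otsu by default — the
bright uniform paper background makes it stable — or a fixed value),
followed by removal of connected components below `min_object_px` and
filling of interior holes up to `max_hole_px` (specular reflections on
the metal tool). An all-background *or* all-foreground result raises
instead of silently producing a mask that would erase (or never carve)
the volume.

The TCP finder works on the single foreground component touching the
bottom border (detached seed fragments are ignored; if several touch,
the widest is taken — the tool). Per row it records the leftmost and
rightmost pixel of that component and walks upward from the border
while the visible width is non-increasing, with a one-pixel jitter
allowance per row for aliasing on slanted edges, and stays above the
minimum tip width. `x_tcp` is the mean of all left/right edge
x-positions seen so far; each edge is then tracked further on its own
for as long as it keeps approaching `x_tcp` (again with the 1-px
allowance), which carries the estimate past partial occlusion of the
tip by the seed; `y_tcp` is the higher (smaller y) of the two stopping
points, and if both edges peak in the same row that row is taken. The
estimate is deliberately pixel-accurate; no subpixel refinement is
attempted.

For seeds large enough to occlude the whole tip, the TCP's image
y-coordinate follows a sinusoid of the rotation angle (the physical
tip travels a small ellipse, up to ~200 µm across). The series
corrector fits `y(α) = A sin α + B cos α + C` by linear least squares
with iterative outlier rejection: residuals are centred on their
median, scaled by the MAD (`σ = 1.4826·MAD`), points beyond `2σ`
dropped, refit, at most five rounds. Estimates whose final residual
exceeds the replacement threshold — `max(3σ_fit, 1 px)` unless
configured — are replaced by the fitted value and flagged. The
x-series can optionally be corrected by the same mechanism (the
elliptic trajectory implies an x-sinusoid too) but is off by default.
At least four estimates are required for the three-parameter fit.

For affordable turntable/SLR setups where a static structure moving
with the object is visible, normalized cross-correlation template
matching supplies an integer per-view shift instead; the shift is
applied to the projection the same way (principal point).

## Carving, tool removal, QC

A voxel survives carving iff its *center* projects into foreground in
every mask (nearest-neighbour lookup after rounding; masks are binary
indicators, no interpolation). Projections falling outside an image
count as background; the working volume should be configured to
project fully inside the image. An empty input mask or an empty carved
result is an error — both always indicate an upstream failure. The
grid is cubic, `R³` voxels of size `side/R`; the TCP sits either at
the center of the bottom face (small seeds: the tool is simply never
reconstructed) or at the grid center (when seed and tool overlap).

Tool removal offers three modes. *Plane cut*: discard everything at or
below the tip plane. *Known cone*: delete voxel centers inside the
truncated cone of the gripper, inflated by one voxel by default so no
digitization shell survives around the tool; the cone slope continues
below the modelled base, since the physical tool does. *Fitted cone*:
sum voxels of horizontal planes from the bottom up; while these areas
are non-increasing (plateaus tolerated — strict decrease would
misfire on digitization steps of shallow cones) the planes are pure
tool and are deleted; at the first strict increase the seed has been
reached, the deleted areas are converted to radii via `area = π ρ²`
and fit linearly in `y`, and the extrapolated cone is removed up to
where its radius reaches the (optionally known, default 0) tip
radius. A seed-only grid fails the fit, as it must.

Back-projection QC projects all eight corners of every surface voxel
(occupied, with at least one exposed face) and fills each projected
convex hull; the union is compared against the segmentation mask with
the Overlap Ratio and Dice coefficients (both defined as 1 when both
masks are empty). The back-projected mask may be slightly dilated
relative to the segmentation — subpixel effects of hull filling — and
matches it within ±1 px once the voxel size projects to about a pixel.
Pose refinement alternates (1) shifting each view's principal point by
the difference of the mask's and the back-projection's centers of mass
and (2) recarving the full grid, accepting iterations while the mean
overlap does not decrease and stopping at `min_improvement`. Only
*relative* per-view offsets are observable: a common shift of all
principal points is exactly silhouette-consistent (it just moves the
world origin), so recovery of an injected shift is assessed against
the consensus of the remaining views.

Surfaces are extracted as the 0.5-level set of the (zero-padded)
occupancy by marching cubes and returned as a `trimesh` mesh, oriented
outward. The isosurface bevels corners, so an isolated voxel meshes to
its dual octahedron (`s³/6`); at object scale mesh volume and voxel
count agree within one surface shell (tested at 1% on a digitized
ball). Voxel count × voxel volume is the primary volume measure; the
mesh volume is reported alongside.

## Accuracy simulator

For an ideal sphere of radius `r0` on the rotation axis, each camera
constrains the reconstruction to the cone with apex at the camera
center `C_i` (distance `d` on the equatorial circle) tangent to the
sphere, half-angle `asin(r0/d)`; under parallel projection the cone
degenerates to a cylinder of radius `r0`. The visual hull is the
intersection of the `N` cones and always contains the sphere, so the
volume error `E = (V_num − V0)/V0`, `V0 = 4/3 π r0³`, is
non-negative. No closed form is known for general `N`; the surplus is
integrated by Monte Carlo.

Sampling exploits the configuration's symmetries: mirror symmetry
about the equatorial plane and about every vertical plane through a
camera or through a bisector between adjacent cameras. These mirrors
sit every `π/N` in azimuth, so the spherical shell `r0 ≤ r ≤ r1`
decomposes into `2·2N` congruent pieces and it suffices to sample
`θ ∈ [0, π/2]`, `φ ∈ [0, π/N]` (camera plane to adjacent bisector
plane — the full fundamental wedge; half of it would not be
representative, since the surplus concentrates at the bisector),
`r ∈ [r0, r1]`. The outer radius `r1` bounds the carved body: in the
equatorial plane every cone contributes two half-plane constraints
`X·n̂ ≤ r0` with normals at the tangent-point azimuths `γ_i ± acos(r0/d)`;
the outermost corner between angularly adjacent constraints lies at
`r0 / cos(gap/2)` of the largest gap. (For odd-`N` parallel projection
this reduces to the textbook `r0/cos(π/(2N))`.) A runtime guard
enlarges `r1` and re-runs if inliers ever saturate the outer boundary.

Azimuth and radius are sampled uniformly; the altitude through
`θ = arccos(1 − χ)` so its density is `sin θ`, and each point carries
the radial Jacobian weight `r²`, giving the weighted estimator
`V_num = V0 + 2·2N · V_reg · Σ_in r_p² / Σ_all r_p²` with
`V_reg = Δφ (r1³ − r0³)/3`. The standard error follows from the
weighted ratio-estimator variance and scales as `1/√K`. The estimator
is cross-validated in the tests against naive Cartesian
bounding-box rejection sampling (the correctness anchor) and against
closed forms: for `m` distinct parallel directions the hull's
horizontal cross-sections are regular `2m`-gons, so
`E = (2m tan(π/(2m)) − π)/π`, and four equally spaced parallel views
give the Steinmetz bicylinder `16/3 r³`.

Two structural facts the simulator reproduces: under parallel
projection, doubling an odd number of views adds only opposite cameras
seeing the same contour, so `E(2k) = E(k)` (exact for odd `k`; for
even `k` the direction sets differ and the identity does not hold);
under central projection opposite cameras *do* add information. This
makes the error curve alternate between even and odd `N` in a way that
depends on `r0/d` — at the production working distance (69.9 mm,
nearly telecentric) odd view counts are markedly better (E(11) ≈ 0.8%
vs E(12) ≈ 1.7%), while at short working distances the even counts
win. At `N = 36` the theoretical surplus is +0.10%.

The TCP-offset experiment renders the bearing-ball stack, carves it
once with exact poses and once with the first view's principal point
shifted 7 px in y, and reports the volume difference. A shifted mask
only removes voxels, so the loss is non-negative, bounded below by the
volume of the sphere outside the shifted tangent cone, and monotone in
the offset.

## Synthetic data generator

The generator renders exactly what the reconstruction assumes: binary
silhouettes of analytic solids under the same central-projection
turntable model, on a white-paper-like background (dark foreground 40,
background 220 by default). Rays through supersampled sub-pixel
positions (4× by default; doubling changes silhouette areas by <0.1%)
are tested analytically against spheres, ellipsoids and the
truncated-cone tool, and by 96-step ray marching against
superellipsoids; a pixel is foreground at ≥50% coverage, so edges are
placed with sub-pixel fidelity — necessary because the volume error
targets live at the 0.1% level. Per-view TCP jitter moves the
rendering principal point on an ellipse
(`dx = a_x cos(α+φ0)`, `dy = a_y sin(α+φ0)`), emulating the physical
tool drift; ground truth (analytic volume, per-view TCP) is returned
with every stack. The optional noise model (background salt speckles,
foreground pinholes) exists to exercise segmentation cleanup and is
off for accuracy experiments. Scenes that are exactly rotation
invariant (centred sphere, no jitter, no noise) are rendered once and
reused across views.

The bearing-ball preset models the production sensor: 2448×2048
square pixels of 3.45 µm, working distance 69.9 mm, and a focal length
chosen for exactly 1:1 magnification (`f_px = d/μ`), which puts the
1.5 mm ball's silhouette at 434.9 px radius. The rendered stacks are
ideal in ways real acquisitions are not: no blur, no shading or
specularity, no background texture, no segmentation ambiguity, and
jitter that is exactly sinusoidal. Passing tests on them validate the
geometry, the estimators and the pipeline plumbing — not robustness to
real imaging artefacts.

## Problem sizes and defaults

The accuracy experiments use the study configuration: `d = 69.9` mm,
`r0 = 1.5` mm, 36 views, 256³ voxels of (12 µm)³ — a grid tightly
surrounding the 3 mm ball. Reconstructed volumes plateau above
`R = 256` (tested: |V(512) − V(256)|/V(256) < 1% on an ellipsoidal
barley-like fixture), so 256 is the default resolution. Monte-Carlo
runs default to `K = 10⁷` samples, where the symmetry reduction puts
the standard error of `E` near 10⁻⁴ percentage points; unit tests use
smaller `K` since even 10⁵–10⁶ samples leave the checked contrasts
many standard errors wide. One seeded generator drives each run;
fixed seeds make every stack and every estimate bit-reproducible.

## Known limitations

Shape-from-silhouette cannot recover true concavities, only valleys
and saddles — adequate for most seeds, not for deeply folded ones.
The pose model corrects lateral drift only (principal point); it does
not estimate rotation-angle errors or axis tilt, and the iterative
refinement can redistribute a single bad view's offset into a common
(unobservable) shift. Tool fitting assumes the tool enters from the
bottom image border and is rotationally symmetric about the rotation
axis. The back-projection QC loops over surface voxels in Python and
is intended for moderate grid sizes.
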