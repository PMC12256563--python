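# Methods

This note records the models, parameter choices and numerical decisions behind
`helixreg`, and what the synthetic experiments do and do not demonstrate.

## Coordinate conventions

All transforms are 4×4 homogeneous matrices named `Ta2b` (points in frame `a`
→ frame `b`); frames are robot base `r`, tool attachment `e`, phantom `p`,
transducer `h`, CBCT `c`. Lengths are millimetres; serialized matrices are
row-major with an explicit frame pair, and the reader validates the bottom
row, so a silently inverted transform cannot enter the pipeline. Volumes are
axis-aligned (identity direction matrix); world coordinates refer to voxel
centers and the CBCT volume center coincides with the isocenter at world
(0, 0, 0), which makes `Tp2c` directly interpretable as the phantom's offset
from isocenter.

Although the initial least-squares estimate of `Tp2c` is affine, the final
registration output is rigid: physical robot motion cannot realize scale or
shear, so the affine estimate is projected to its polar rotation factor
before refinement. The projection is exact when the residual non-rigidity is
a pure right-multiplied scale and is idempotent in general.

## Phantom model

The digital phantom places 32 fiducial centers on the surface of a cylinder
of diameter 108 mm (radius 54 mm), along a helix of pitch 62 mm, spaced
32 mm apart in **arc length along the helical path** (the chord
interpretation would shrink the axial span and change the visibility counts).
With one helix turn measuring √((π·108)² + 62²) ≈ 344.9 mm, each fiducial
advances 5.752 mm axially and 33.4° azimuthally; the 32-fiducial set spans
178.3 mm and is centered axially on the phantom origin, phase 0 at local +X.
Consequently, in a centered cubic FOV of side 160 mm, exactly the two
outermost positions at each helix end (1, 2, 31, 32) protrude — for both
fiducial sizes — leaving 28 fiducials fully inside.

The physical phantom's large/small arrangement is not published. The shipped
`DEFAULT_LARGE_INDICES = (1, 4, 5, 12, 18, 20, 23, 28, 29, 32)` is a
**reconstruction**, found by a deterministic seeded search over patterns
constrained to (a) require exactly 4 large fiducials for unique
identification, including reversed runs, and (b) carry exactly one large
fiducial among the two outermost positions at each end, so the centered
160 mm FOV sees 8 large and 20 small fiducials. Any pattern satisfying these
constraints reproduces the phantom's documented behaviour; the specific
arrangement of the clinical phantom may differ.

Visibility uses full sphere containment in the FOV cube. For the default
geometry this is equivalent to centroid-only containment (verified in tests):
the truncated fiducials sit several millimetres beyond the FOV face, so the
choice of containment rule does not affect the counts.

`min_unique_large_count` enumerates every contiguous run of m large
fiducials, in both orientations, and requires the distance-pattern
correspondence to assign each run member to its true index with a strictly
unique minimum. The pattern cost is order-free (it compares distance *sets*),
so a forward run and its reversal score identically; the reversed enumeration
guards against mirror-symmetric patterns, which would produce ties caught by
the uniqueness margin.

## Synthetic CBCT generation

The registration consumes segmented centroids, not projections, so volumes
are synthesized directly in the reconstruction domain:

* **Geometry** — cubic FOV of side 160 mm, 0.5 mm isotropic voxels (320³).
  The scanner's native spacing is not published; 0.5 mm is typical of mobile
  C-arm CBCT reconstructions.
* **Fiducials** — spheres of intensity 3000 over background 0 (arbitrary
  units; the pipeline only relies on fiducials being the brightest voxels),
  rendered with midpoint-quadrature partial-volume weighting at 3×3×3
  subsamples per voxel. The integrated excess intensity of a sphere matches
  its analytic volume to better than 2%. Spheres are truncated exactly by
  the cube.
* **Noise** — additive Gaussian, σ = 10 (0.33% of fiducial contrast), seeded;
  identical seeds give bitwise-identical volumes. No beam hardening, streaks
  or scatter: those degrade detectability on physical scans but not the
  contract being tested, which is recovery of a known pose from segmented
  centroids.
* **Treatment phantom** — alternating layers along Z (3.5 mm "agar" at 800,
  1 mm "agar + barium" at 2400, period 4.5 mm) and a post-treatment volume in
  which voxels inside an ellipsoidal zone are replaced by the mean layer
  intensity (1600), emulating homogenized layers after a bubble-cloud
  treatment. Pre and post share one noise realization, so they differ only
  inside the zone.

Passing tests on these volumes show the algorithm chain is correct and
attains the centroid-estimation noise floor; they do not show robustness to
metal artifacts, scatter, or gantry-flex FOV drift, which only physical scans
can probe.

## Fiducial detection

The threshold τ is a nearest-rank (ceiling) percentile of all voxel
intensities — no interpolation, so the dialect is unambiguous — and the mask
is strict `> τ`. Two modes:

* `fixed-percentile` (default 99.99), matching routine use on noisy scans,
  where the percentile lands in the noise tail and the minimum-component-size
  filter (4 voxels) removes isolated noise voxels;
* `expected-volume`, where the percentile is derived from the summed sphere
  volumes of the visible fiducials (e.g. 99.9964 for 28 fiducials at 0.5 mm
  in a 160 mm FOV). This mode makes the mask size match the true fiducial
  volume, which is what makes equivalent diameters meaningful; it is also the
  right mode for noise-free volumes, where a fixed percentile degenerates
  (τ = background keeps every partial-volume voxel).

Components use 26-connectivity (fiducials are compact blobs); centroids are
unweighted means of member-voxel world positions ("geometric" centroids);
equivalent diameter is `(6·count·voxel_volume/π)^(1/3)`; the small/large
split is 2.25 mm with ties classified large.

**Voxel-size sensitivity.** Thresholded voxel counts approximate sphere
volumes only while the voxel is small relative to the fiducial. At 1 mm
voxels a 1.5 mm fiducial's mask — under a fixed low percentile — consists
mostly of partial-volume voxels and its equivalent diameter inflates past the
2.25 mm split. The test suite therefore exercises detection accuracy at the
0.5 mm default; 1 mm volumes appear only where sub-voxel sizing is not
asserted.

## Correspondence, estimation, refinement

The distance-pattern cost compares, for each detected large fiducial, its
distances to the other detected large fiducials against each model
candidate's distances to all other model large fiducials, summing per-distance
absolute best matches (the absolute value is required; a signed difference
has no sensible minimum). Distances are rigid invariants, so matching needs
no pose initialization. The per-fiducial argmin is checked post hoc for
injectivity and for a ≥ 0.5 mm gap to the runner-up, failing loudly on
ambiguous or degenerate patterns rather than mis-registering. With clean
positions any run of 4 from the shipped pattern matches correctly; with
0.1 mm centroid jitter, runs of 5–8 match correctly and agree with an
exhaustive-assignment oracle.

The affine fit solves `Tp2c·[f(model);1] = [f(CBCT)]` by least squares using
complete orthogonal decomposition (LAPACK `gelsy`), requiring ≥ 4
non-coplanar pairs.

Refinement is a compass (pattern) direct search over six rigid parameters:
an axis-angle rotation increment whose radians are scaled by the 54 mm
phantom radius — so a unit parameter step moves a surface fiducial about
1 mm, commensurate with the translation parameters — plus translation in mm.
Each iteration polls ± the current step along each parameter and accepts the
best improvement; the step halves when no poll improves. The cost is the RMSE
of each detected fiducial (both size classes) to its nearest model fiducial
under the current transform, which is also the reported FRE. Termination
rules, checked in this order: 2000 iterations; an accepted improvement below
10⁻³ mm (cost tolerance); step below 10⁻³ mm (step tolerance). A pattern
search was chosen over a simplex method because these rules map one-to-one
onto its semantics, letting the diagnostics report exactly which rule fired;
accepted cost never increases by construction. Nearest-neighbour pairing in
the cost makes refinement tolerant of extra detections (truncated-sphere
fragments) and missed small fiducials.

## Treatment evaluation

Zone segmentation is a seeded region grower — 6-connected breadth-first
growth admitting voxels within a tolerance (default 400, between the noise
level and half the layer contrast) of the region's running mean — standing in
for the interactive grow-cut segmentation used clinically, whose
modifications are unpublished. The measurable contract is the centroid after
the published post-processing, which is implemented as stated: largest
connected component, median smoothing and morphological closing plus hole
filling, all with 1 mm kernels (rounded up to odd voxel counts). Directional
error is observed centroid minus planned target on the CBCT axes (−Z toward
the transducer); TRE is its Euclidean norm; unsigned errors are component-wise
absolute values.

## Statistics

Day-to-day differences use two-tailed pooled-variance Student t-tests
(df = n₁+n₂−2) with 95% CIs of the mean difference. User-variability tests
are two-tailed variance-ratio F-tests on day-centered residuals,
F = var(single)/var(multi), with df = (N_single−1, N_multi−1) — F(15, 11)
for the reference design of 16 + 12 trials — even though centering consumes
one mean per day; the p-value doubles the smaller
tail. Benjamini–Hochberg is the standard step-up procedure. Pooled summaries
combine per-day mean ± SD with the exact combined-variance formula (N−1
denominator), reproducing the flat statistics of the concatenated
observations. Pooled means recomputed from rounded per-day summaries agree
with experiment-wide means to the printed precision, while pooled SDs
generally cannot be reconstructed from rounded rows and are not asserted.

## Problem sizes in the test suite

Rendered registration scenes use 320³ volumes at 0.5 mm (three end-to-end
seeds plus one truncated-FOV worst case with 7 large + 14 small fiducials
visible); the registration noise-floor suite runs 10 seeds of 0.05 mm
centroid jitter without rendering; matching oracles run 20–25 seeds per run
length. These sizes were chosen to keep the full suite within a few minutes
while leaving every tolerance at its stated value.

## Known limitations

* The large/small pattern is a constrained reconstruction, not the clinical
  phantom's (unpublished) arrangement.
* No projection-domain physics: detectability under metal artifacts, scatter
  and exposure variation is out of scope.
* The region grower is not grow-cut; segmentations of low-contrast or highly
  textured zones may differ from the interactive tool's.
* `Te2p` and `Te2h` are consumed as given calibration files; estimating them
  (multi-pose hand-eye calibration) is out of scope.
* Refinement assumes the affine initialization is close (it is, whenever
  matching succeeds); it is a local search and makes no global optimality
  claim.
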