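# Methods

This note documents the models, parameters, and numerical choices behind
each pipeline stage, and what the synthetic-data tests do and do not show
about real microscopy data.

## Projection geometry

Z-stacks are stored apical-side-first (readers can reverse
substrate-to-apical acquisitions with `apical="last"`). Slabs are half-open
depth windows `[z_lo, z_hi)` in µm below the apical-most slice; a slice at
depth `i * z_step` is included when it falls inside the window, and the
projection takes the per-(y, x) maximum over the included slices. Default
windows: apical = top 4 µm; basal = 13–16 µm (the basal cell plane sits
roughly 13 µm below the apical surface in well-differentiated cultures,
overridable per field of view since real layer heights vary by several µm);
fiber = a 1.5 µm slab starting 2.2 µm below the basal slab, toward the
substrate. Fixed windows replace interactive per-slice region selection:
they are reproducible, at the cost of not tracking tissue-height variation
within a field of view.

## Cell segmentation

Cortical actin renders cell boundaries as bright ridges, so the
(preprocessed) intensity surface itself is the watershed topography.
Preprocessing is plane-specific: apical projections get morphological
opening-by-reconstruction followed by closing-by-reconstruction (disk
radius 2 px), which removes bright/dark specks below the structuring scale
without displacing ridge geometry; basal projections get a local adaptive
Wiener-type filter (5 px window, reflect padding so borders and constant
images are fixed points). Markers are the regional minima after h-minima
suppression at depth `marker_h` (default 200 gray levels) — the single
over-segmentation control; watershed lines carry label 0 and regions are
4-connected. A perfectly uniform image returns one full-field label with a
warning instead of failing mid-pipeline.

Boundary QC targets over-segmentation: for each watershed ridge separating
exactly two cells we compute tortuosity (ordered ridge path length over
endpoint chord; exactly 1 for a straight ridge), length in µm, and mean
underlying image intensity. Defaults dissolve ridges with tortuosity
> 1.6, length < 3 µm, or mean intensity strictly below the 30th percentile
of all ridges. The strict inequality matters: in a field whose ridges are
all equally bright (e.g. a noise-free synthetic tessellation) no ridge is
"dimmer than the percentile" and nothing is dissolved. All thresholds are
configuration, since they express imaging-dependent artifact scales rather
than biology. Dissolution merges labels through union–find, so QC can only
reduce the cell count. Area filtering (defaults 20–2000 µm²) runs last.

The ellipse fit treats each pixel as a unit square: the region covariance
is the pixel-center covariance plus I/12. This makes the aspect ratio of an
axis-aligned a × b rectangle exactly a/b, makes a single pixel exactly
AR = 1 (the degenerate-region convention), and keeps AR invariant under
90° rotation and pixel-size rescaling. Cell density divides the retained
cell count by the full field-of-view area (a flag for segmented-area
normalization was considered and rejected as the default because the
searched area depends on QC configuration). Per-FOV summaries are
unweighted means over retained cells.

## Stress fibers

**Masking.** In jammed controls, cortical actin at cell boundaries
confounds fiber tracing, so the basal watershed ridges, dilated to 1.5 µm
total width, are zeroed and excluded from the searched area before
tracing. Masking is per-condition configuration: unjammed fields, where
cortical actin is sparse, are analyzed unmasked.

**Tracing.** Ridges are enhanced by zero-mean oriented line kernels
(12 orientations, 2 µm long — matching the few-µm fiber scale) and the
maximum response is thresholded (Otsu by default). Because the kernel
response smears up to half a kernel length beyond fiber tips, the mask is
intersected with an intensity threshold of the raw image, which restores
tip localization. The mask is skeletonized, the skeleton is split at branch
points, and arms are bridged back across a junction when continuing
through it turns by ≤ 35° — this is what resolves two crossing fibers into
two straight fragments instead of four arms. Polylines are
endpoint-anchored box-smoothed (window 5) before measuring length, which
removes the chain-code staircase bias (a digitized straight segment
otherwise reads several percent long); a rendered 50 µm line measures
50.2 µm. Fragments shorter than 1 µm are discarded.

**Joining.** Fragments of one fiber split by gaps are reconnected when an
endpoint pair lies within 3 µm, the two end tangents agree axially within
20°, the connecting segment deviates from both tangents by ≤ 20°, and —
the intensity-continuity constraint — the mean bilinearly-sampled image
intensity along the straight connector is at least 0.6 × the dimmer
fragment's mean intensity. Candidates are scored by normalized gap plus
normalized angles and accepted greedily (best first, each endpoint once,
cycles refused, ties broken by endpoint index so the result is independent
of input order). Joining therefore never decreases total traced length.
Metrics: mean fiber length per field of view, and total length divided by
the searched area (µm⁻¹). The gap/angle defaults are scaled to the ~3 µm
mean fiber lengths these cultures show; all are configuration.

**Orientation field.** The image is tiled into 3 × 3 µm subregions; within
each, the structure tensor of Gaussian-derivative gradients (σ = 1 px) is
summed and the fiber orientation is taken perpendicular to the dominant
gradient direction, i.e. θ = ½·atan2(2Jxy, Jxx − Jyy) + 90°, axial on
[0°, 180°). Subregions are invalidated when they overlap the excluded
mask, have mean intensity strictly below the 35th percentile of subregion
means of the boundary-free image (tiles without fibers), have no gradient
energy (uniform), or touch the image border (padding-contaminated
gradients). On synthetic stripe patterns all interior tiles are within
0.01° of truth.

**Alignment AUC.** For all valid subregion pairs within 50 µm, the
alignment cos 2(θᵢ − θⱼ) — the dot product in double-angle space, +1 for
parallel, −1 for perpendicular — is averaged in 1 µm distance bins. The
null randomly permutes the orientations over the valid positions
(conserving the orientation multiset, as repositioning requires, rather
than regenerating orientations) and re-bins; 20 replicates are averaged.
The AUC is the trapezoidal area between the experimental and mean-null
curves, in µm. Under the null the observed assignment is exchangeable with
the permutations, so the AUC's null spread is estimated as the standard
deviation of the per-replicate AUCs times √(1 + 1/R) — not divided by √R,
because the experimental curve itself carries one replicate's worth of
variance. Identical orientations give AUC = 0 exactly; AUC is invariant
under global rotation of all orientations.

The field reports this statistic per µm⁻¹ in some of the literature even
though an alignment-versus-distance area carries units of µm; the
normalization is not standardized, so the unnormalized area is reported
here (a normalization-by-max-distance² option exists but is not default).

## Migration

Dense optical flow between consecutive frames uses the variational TV-L1
estimator by default. A windowed iterative Lucas–Kanade option exists and
is several times faster, but its local estimates are biased in
texture-poor patches, and because those biases travel with the texture
they accumulate along trajectories instead of averaging out; TV-L1's
global regularization keeps per-seed speed errors under 10% on analytic
rotation fields where ILK exceeds 30% at isolated seeds. Seeds start on a
10 µm grid, and each step samples the current flow field at the seed's
position by bilinear interpolation (forward Euler, one step per frame
interval). Trajectories leaving the frame are frozen and excluded from the
field-of-view mean rather than extrapolated. Speed is net displacement
over elapsed time — a closed loop has speed 0 — matching the definition
used for slow epithelial collectives; a path-length alternative is
computed alongside for comparison.

## Statistics

Fields of view are the replicates; wells are available as an aggregation
level (unweighted means, missing values reduce the recorded n). Group
comparison is one-way ANOVA plus the Tukey–Kramer studentized-range test,
|mᵢ − mⱼ| / √(MSW/2 · (1/nᵢ + 1/nⱼ)) against the studentized-range
distribution with k groups and N − k degrees of freedom (valid for unequal
group sizes). The implementation is direct (with a cached critical value
so large Monte-Carlo calibrations run in seconds, and an option to skip
p-value computation when only significance flags are needed) and is
verified against statsmodels' `pairwise_tukeyhsd` to 10⁻⁸ in the tests.
Degenerate inputs: all values identical → F = 0, p = 1; groups internally
constant but different → F = ∞ and every differing pair flagged. Pearson
correlations use the standard two-sided p-value and refuse zero-variance
input. Both procedures calibrate to the nominal 5% level within Monte
Carlo error over 2,000 null simulations. Dispersion is reported as
mean ± s.d.

## Synthetic data

The generators define the test conditions; each returns the rendered image
plus ground truth computed from generator internals, never from rendered
pixels, and identical specs yield bit-identical output.

*Cell fields* are Voronoi tessellations of best-candidate (approximately
Poisson-disk) seeds with two Lloyd relaxation iterations, which removes
sliver cells and stabilizes ground-truth shapes. Anisotropy is imposed by
generating seeds and measuring distances in a frame compressed along x by
`target_ar`, which gives an analytic elongation axis; the realized mean
truth AR tracks the target (≈1.29 at target 1 — relaxed Voronoi cells are
compact but not circular — rising monotonically to ≈3.0 at target 3).
Boundaries render as Gaussian-profile ridges (σ 0.4 µm) over a dark
interior, with optional additive clipped Gaussian noise and background
gradient. Defaults follow the static-imaging geometry (563 × 356 µm field
of view; 0.5 µm/px; ~1300 cells, matching the ~150 µm² mean cell areas of
these epithelia).

*Fiber fields* render line segments with Gaussian cross-section (FWHM
0.5 µm) at lengths N(3.0, 0.5²) µm, fully inside the field of view, with
uniform, globally-aligned, or patchwise-aligned orientations (patch grid,
one orientation per patch). The default count reproduces a total-length
density near 0.12 µm⁻¹ over the default field of view.

*Time-lapses* warp a fixed band-limited random texture with an analytic
flow (static, translation, rigid rotation, or Gaussian-core swirl),
sampling the texture at backward-advected pixel positions so rendered
motion matches the analytic trajectories to interpolation accuracy;
rotation-family flows invert exactly because their angular rate depends
only on the rotation-invariant radius. Defaults follow the live-imaging
protocol (frames every 6 min over 1.5 h). Per-frame displacements above
25% of the field of view are refused as unrecoverable by flow estimation.

**What passing these tests does not show.** The generators contain no
pseudostratified 3D structure, no nuclei or multi-channel bleed-through,
no photobleaching or illumination drift, no cortical-actin/fiber
superposition in one channel (real F-actin staining puts boundaries and
fibers in the same channel at unspecified relative intensity, so the
generators deliberately keep them in separate images — the masking stage
is exercised with explicit label maps instead), and only additive
Gaussian noise. Recovery
within tolerance on these fields demonstrates correctness of the
algorithms under controlled conditions, not robustness to every real
imaging artifact; the QC and threshold parameters exist precisely because
real data need tuning that synthetic data do not.

## Problem sizes in the tests

The test suite and acceptance script use reduced field sizes chosen to
exercise every code path with comfortable statistical margins: 100-cell
fields at 250 × 250 µm for segmentation recovery, 200 fibers in
150 × 150 µm for length/density recovery, 120 × 120 µm patchwise fields
(10 seeds × 2 patch sizes) for the alignment-AUC ordering, 200 × 200 µm
16-frame sequences for migration recovery, and 2,000 simulations for the
statistical calibrations.
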