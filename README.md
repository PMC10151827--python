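# epimorph

Quantification of basal stem-cell remodeling during the epithelial
unjamming transition (UJT): when a confluent airway epithelium switches
from a jammed, solid-like state to an unjammed, collectively migratory
one, its basal stem cells elongate, shrink in area, assemble longer and
locally aligned stress fibers, and move faster. `epimorph` implements the
full image-analysis pipeline needed to measure those changes from
F-actin-stained z-stacks and phase-contrast time-lapses, plus a synthetic
ground-truth generator so that every stage has a parameter-recovery test.

It is intended for quantitative cell biologists analyzing pseudostratified
epithelial cultures (e.g. air–liquid-interface airway epithelium), and for
anyone who needs a tested, scriptable implementation of the individual
stages.

## What it computes

**Plane projection** (`epimorph.imaging`) — maximum-intensity projections
of apical, basal, and stress-fiber slabs from calibrated z-stacks, with
depth windows in µm measured from the apical surface.

**Cell morphometry** (`epimorph.cells`) — marker-controlled watershed
segmentation of cortical-actin boundaries (markers from h-minima
suppression), boundary quality control (tortuosity, length, and a ridge
mean-intensity percentile dissolve over-segmented ridges), area filtering,
and per-cell ellipse-fit shape metrics. The aspect ratio is
AR = a/b of the ellipse with the same normalized second central moments as
the pixel region (unit-square pixel model), so a 40 × 20 px rectangle gives
AR = 2 exactly and AR ≥ 1 always.

**Stress fibers** (`epimorph.fibers`) — cortical-actin masking (basal
ridges dilated to 1.5 µm), iterative fiber-fragment tracing (oriented line
filters → skeleton → junction bridging, so crossing fibers resolve into
straight fragments), gap-joining of fragments under distance, orientation,
and intensity-continuity constraints, mean fiber length and total length
per searched area (µm⁻¹), per-subregion (3 × 3 µm) axial orientations from
the intensity structure tensor, and the **alignment AUC**: the area between
the pairwise alignment-versus-distance curve, alignment =
cos 2(θᵢ − θⱼ), of the observed orientation field and that of the same
orientations randomly repositioned. Positive AUC means fibers align more
with near neighbors than with the field at large.

**Migration** (`epimorph.motion`) — dense optical flow between consecutive
phase-contrast frames (variational TV-L1 by default), forward integration
of a 10 × 10 µm seeded grid, and net-displacement speed
|x(T) − x(0)| / T in µm/h, averaged per field of view.

**Statistics** (`epimorph.stats`) — per-FOV / per-well aggregation,
one-way ANOVA with Tukey–Kramer post-hoc tests, Pearson correlations.

**Synthetic data** (`epimorph.synth`) — Lloyd-relaxed Voronoi cell fields
with controllable mean aspect ratio, fiber planes with controllable length
distribution and orientation-correlation structure, and time-lapses
advected by analytic flows (translation, rotation, swirl), all with exact
exported ground truth.

## Worked example

Generate a synthetic apical plane (64 cells, target aspect ratio 2) and a
patchwise-aligned fiber plane, then run the pipeline:

```python
import numpy as np, tifffile
from epimorph import synth

spec = synth.CellFieldSpec(fov_width_um=200, fov_height_um=200,
                           pixel_size_um=0.5, n_cells=64, target_ar=2.0,
                           rng_seed=11)
img, truth = synth.generate_cell_field(spec)       # truth mean AR 1.976
tifffile.imwrite("demo_apical.tif", img.astype(np.uint16))

fspec = synth.FiberFieldSpec(fov_width_um=100, fov_height_um=100,
                             pixel_size_um=0.25, n_fibers=150,
                             orientation_mode="patchwise",
                             patch_size_um=30.0, rng_seed=11)
fimg, ftruth = synth.generate_fiber_field(fspec)   # truth mean length 3.003 µm
tifffile.imwrite("demo_fiber.tif", fimg.astype(np.uint16))
```

```sh
$ epimorph segment-cells --image demo_apical.tif --plane apical \
      --pixel-size 0.5 --marker-h 500 --min-area 0 --max-area 1e9 --no-qc
64 cells, mean AR 1.991, mean area 604.1 µm²

$ epimorph segment-fibers --image demo_fiber.tif --pixel-size 0.25
137 fibers, mean length 3.223 µm, density 0.0442 µm⁻¹

$ epimorph fiber-align --image demo_fiber.tif --pixel-size 0.25 --seed 1
alignment AUC 0.924 µm (null SE 0.206)
```

The segmentation recovers all 64 cells and the truth mean aspect ratio to
within 1%; the traced mean fiber length (3.22 µm) sits within the
tolerance of the 3.00 µm truth; and the patchwise-aligned field shows an
alignment AUC more than four null standard deviations above zero, i.e.
strong local-over-global alignment. Each command also writes per-cell /
per-fiber CSV tables and label maps next to the input.

Time-lapse speed works the same way (`epimorph track --stack lapse.tif
--pixel-size 1.0 --interval-min 6 --grid-um 10`), and
`epimorph stats --table tidy.csv --metric apical_ar` compares a metric
across condition/timepoint groups with ANOVA + Tukey–Kramer.

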