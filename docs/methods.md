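# Methods

## The counting problem

A segmented crop layer is a raster in which an upstream classifier has
kept only the plant-class pixels of a UAV orthomosaic (everything else is
black). At ~3 cm/px ground sampling an agave crown (1–2 m diameter) is a
blob of roughly 33–66 px across, rows are ~100–130 px apart, and plants
along a row are ~33–40 px apart — closer than a large crown is wide, so
adjacent blobs fuse. The task is to count plants, not blobs.

## Pipeline and assumptions

**Preprocessing** converts the RGB layer to luminance
(`0.299 R + 0.587 G + 0.114 B`, kept in floating point), binarizes at
strictly positive luminance (the background is pure black by construction
of the layer, so any nonzero pixel is plant class), removes isolated
foreground pixels, and fills interior holes. "Isolated" means 8-connected
components of area below `min_area` (default 2 px, i.e. exactly the
single-pixel specks); "holes" are 4-connected background regions with no
path to the image border — the standard dual connectivity pairing, which
gives consistent Jordan-curve behavior. Both filters are idempotent;
cleaning only removes foreground, filling only adds it.

**Object separation** is an opening followed by a closing with a 3×3
square element. Opening first is essential: it cuts the 1–2 px necks
where crowns touch, and the subsequent closing repairs intrusions into
plant bodies without re-welding necks (the gap after opening is wider
than the closing can bridge).

**Counting** alternates equivalent-diameter thresholding with erosion.
Components with `d = sqrt(4·area/π) < Th` are harvested as single plants
into an accumulator `IS`; the rest, `IG`, are eroded with a city-block
diamond of radius 2 (13 offsets, `|dy|+|dx| ≤ 2`) and the loop repeats
until `IG` is empty. Erosion pinches the bottleneck between two fused
crowns apart after a few iterations, after which each half shrinks
independently until it drops under `Th` and is harvested. The recorded
centroid/area of a detection are those of the eroded fragment at capture
time; the procedure counts fragments and does not reconstruct original
footprints.

The loop terminates because every erosion strictly shrinks each remaining
component's bounding box, so at most ~max(H, W)/2 iterations are possible;
`max_iterations` (default 200) is a safety net that flags pathological
inputs (e.g. a solid foreground slab) with a warning and a
`converged=False` result rather than an endless loop.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `th_px` | 13 | equivalent-diameter harvest threshold, px; 39 cm at 3 cm/px. Calibrated to the plant pattern at the survey's flight altitude |
| `erosion_se` | diamond:2 | per-iteration erosion element of the counting loop |
| `opening_se` | square:3 | element of the opening/closing separation stage |
| `connectivity` | 8 | foreground pixel adjacency for component extraction |
| `strict_less` | true | harvest at `d < Th`; a `≤` variant exists for sensitivity analysis |
| `min_area` | 2 | preprocessing speck-removal threshold, px |
| matching `radius_px` | 17 | detection-to-ground-truth match radius; ≈ 0.5 m, half the along-row plant spacing |

The threshold comparison is strict (`<`), matching the calibration
statement that components with equivalent diameter *less than* 13 px are
single-plant candidates.

## Numerical and design choices

- **Border policy.** Outside-image pixels are background for erosion
  *and* dilation. Plants touching the frame therefore erode from the
  frame side like interior plants. One consequence is accepted
  deliberately: closing is not extensive on the 1-px frame rim (a
  foreground pixel on the border cannot survive the closing's final
  erosion), so algebraic properties of closing hold on the interior only.
- **Fragment identity.** If fragments harvested at different iterations
  happen to touch in the accumulated binary `IS`, a plain component count
  of `IS` would merge them. The implementation stores `IS` as a label
  raster and counts harvested fragments; the stricter binary-union count
  is also computed (`binary_union_count`) and a divergence is logged. On
  all synthetic fixtures the two agree.
- **Label order.** Components are labeled in raster-scan order of their
  first pixel, so detection tables are deterministic.
- **Matching.** Greedy nearest-first one-to-one matching within the
  radius. On instances of ≤ 8 points it provably equals the optimal
  assignment (cross-checked in the tests against exhaustive enumeration);
  at field plant spacings the greedy/optimal distinction is immaterial.
- **Pooling.** The multi-region summary micro-pools confusion counts
  (Σtp/Σgt etc.) so every plant weighs equally; a macro-average over
  regions would weight small regions up and gives different numbers.
- **Degenerate inputs.** Empty masks count 0 in 0 iterations; metrics
  raise on undefined denominators (no ground truth / no detections)
  rather than returning 0/0 conventions.

## The synthetic field generator

The generator emulates the *segmented layer*, not raw photographs: plants
are near-circular disks of a green-dominant color on black, placed on a
jittered row lattice (defaults: rows 117 px ≈ 3.5 m apart, plants 37 px ≈
1.1 m apart, crown radii 16–33 px ≈ 1–2 m diameters at 3 cm/px). Because
a large crown is wider than the along-row spacing, the overlap flag is
enforced pairwise while walking each row: a plant drawn for overlap
(probability `overlap_prob`) is pulled toward its left neighbor until the
disks intersect at 70–95 % of the sum of radii; a non-overlap plant is
pushed right until a 1-px gap separates the disks. This keeps the stated
guarantee that `overlap_prob = 0` yields pairwise-disjoint plants while
still allowing heavy fusion at high overlap probabilities. Ground truth
is the list of final disk centers, including plants later erased by
degradations.

Degradations, each consuming the single seeded generator in a fixed
order: interior holes (removed by preprocessing; they exercise the fill
stage), illumination dropout (erases an angular sector of a plant, or,
with probability 0.15 given dropout, the whole plant — a guaranteed false
negative), and weed speckle (disks of radius 1–4 px anywhere in the
frame; the smallest die in cleaning/opening, the larger ones survive as
false positives, the dominant FP source in real fields).

The three presets encode the qualitative survey descriptions: `field1`
has a wide crown-size range and heavy overlap with little weed, `field2`
moderate overlap with weeds and frequent dropouts (the illumination-
affected field), `field3` homogeneous crown sizes with moderate overlap
and weeds. Preset numbers (radius ranges, rates) are fixed design
choices, not fitted quantities.

What the generator does **not** emulate: irregular crown silhouettes
(real segmented agaves are star-shaped, not circular), segmentation bleed
between adjacent rows, soil-texture false positives with plant-scale
area, and spatially correlated illumination loss spanning many plants.
Passing the synthetic end-to-end checks therefore shows the counting
machinery is correct under the stated geometry; it does not certify
accuracy values on any particular real survey.

## Problem sizes used in tests and the acceptance script

Synthetic fields are 600×600 px (defaults, ~50 plants) and 700×800 px
(presets, ~100 plants); the oracle cross-check uses 200 random 32×32
masks; disjoint-recovery runs 20 seeds; presets are averaged over 3 seeds
in the acceptance script and 2 per preset in the test suite. These sizes
make every statistic stable at a few seconds of runtime while exercising
10–20 erosion iterations per field, the same regime as plant-scale blobs
in real layers.

## Known limitations

- Fragments are counted where they drop below `Th`; a plant overlapped by
  more than ~30 % of its diameter can still be absorbed into its neighbor
  and undercounted — the same failure mode reported for heavily
  overlapped field regions.
- A dropout sector can split one plant into two surviving fragments,
  producing an extra detection (a false positive co-located with a true
  one).
- The counter consumes an already-segmented layer; segmentation errors
  (missed small plants, weed classified as agave) propagate directly and
  are not corrected.
- Pixel coordinates only; georeferencing is out of scope (the GSD is
  carried solely to express `Th` in ground units).
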