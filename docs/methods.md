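# Methods

This note records the models, conventions and numerical choices behind
`mycovision`, what the synthetic benchmark scenes do and do not emulate,
and the known limitations.

## Image model and conventions

Grayscale images are 2-D float arrays with intensities in [0, 1]; binary
images are boolean arrays.  File input rescales integer images by the
dtype maximum (255 / 65535) and converts RGB to gray as the plain average
of the three channels.  All component labeling and the hysteresis flood
fill use **8-connectivity**, so one-pixel-wide diagonal hyphae remain
single objects.  Both binarization thresholds are strict (`value > b`).

## Segmentation and shape descriptors

Hysteresis binarization takes foreground = {p > b1} ∪ {p > b2 connected
through pixels > b2 to some p > b1}.  With b1 = b2 it degenerates to a
plain threshold; lowering either threshold can only add foreground
(monotonicity, property-tested against a brute-force flood fill).

Component gates are closed intervals (a value equal to the bound passes),
matching the semantics of a calibration slider whose chosen value is
admissible.  Filtering happens in pixel units; the physical scale
(microns/pixel) is applied only to reported measurements.

Shape descriptors per component:

* area — pixel count;
* perimeter — the **Crofton estimator** (4-direction contour length), not
  a boundary-pixel count, because pixel counting biases the circularity
  of rasterized disks by up to ~10% depending on orientation.  With
  Crofton, a radius-20 rasterized disk scores circularity 1.004;
* best-fit ellipse — the ellipse with the same normalized second central
  moments as the pixel set; length/width are its major/minor axes;
* elongation — `1 − minor/major`, bounded in [0, 1] (0 = circle, → 1 =
  line).  This definition is monotone in the axis ratio, which is all the
  "long and narrow" filter needs; absolute elongation thresholds from
  other implementations with different definitions are not portable;
* circularity — `2·sqrt(π·area)/perimeter`; exactly 1 for an ideal disk,
  0 returned for a degenerate zero perimeter.

Touching spores are counted as one component; no watershed declumping is
attempted (an extension point).

## Mycelium pipeline

Order of operations: Gaussian background subtraction → hysteresis
binarization → 3×3 box dilation → thinning → skeleton cleaning → optional
mask subtraction → graph extraction.

*Background subtraction* blurs the image with a Gaussian kernel of radius
`gaussian_radius` pixels (σ = radius/2, kernel truncated at the radius,
reflected borders) and subtracts the blur from the original, clipping at
0.  Slowly varying background — uneven illumination, dye gradients — is
removed while thin bright structures survive; the default radius (15 px
for the synthetic scenes) is ~5× the hypha width.

*Dilation* with the 3×3 box closes one-pixel gaps from out-of-focus or
weakly stained stretches.  *Thinning* uses iterative morphological
thinning (Guo–Hall class, `skimage.morphology.thin`), which preserves
connected components and holes; tests assert topological properties, not
exact pixel sets.  *Cleaning* removes skeleton components with fewer than
`min_hyphae` pixels and iteratively prunes terminal branches shorter than
`min_hyphae` back to their junction, to a fixed point (idempotent).
Because 8-adjacency can glue the last branch pixel to the junction
cluster, pruning may leave at most one pixel of a removed branch; that
pixel joins the junction node and does not affect tips or lengths.  The
optional mask (e.g. a well edge) is subtracted from the cleaned skeleton.

*Graph extraction*: skeleton pixels with ≠ 2 neighbors become node
pixels.  Adjacent junction pixels (degree ≥ 3) are merged into a single
node at their centroid — thinning routinely emits 2×2 junction clusters,
and merging prevents spurious zero-length edges.  Maximal chains of
degree-2 pixels become edges carrying their pixel path; a pure closed
loop becomes one node with a self-loop (counted twice in the degree); an
isolated pixel is an isolated node and — like any degree-0 node — is
**not** a tip.  Edge length uses the orthogonal/diagonal step rule
(1 / √2), which is unbiased for diagonal hyphae where a pixel count would
overestimate by up to √2; absolute lengths from tools that count pixels
will differ by a bounded factor.

Metrics: total length = Σ edge lengths × scale; tips = degree-1 nodes;
area = convex hull **of the node coordinates** (shoelace area via Qhull),
0 when fewer than 3 non-collinear nodes exist.  Hull-over-nodes slightly
underestimates the colonized area when long unbranched arcs bow outward,
since arc interiors contribute no nodes.

The segmentation-accuracy evaluation scores the **pre-skeleton binary**
(background subtraction + hysteresis + small-object removal, no
dilation): accuracy tables compare binary segmentations against
ground-truth masks, and the 3×3 dilation is a gap-closing aid for
skeletonization, not part of the segmentation claim.

## Validation metrics

Pixelwise TP/FP/FN/TN with the ground truth as reference; precision,
recall, F (harmonic mean) and MCC.  Zero denominators report the metric
as 0 rather than NaN so batch tables stay numeric; affected rows are
flagged in a `notes` column.  Batch tables append an `Average` row that
is the true column mean over the images.

## Synthetic scenes

Defaults are 1024×1024 images with 8-bit-equivalent intensity levels, one
explicit `numpy` RNG stream per scene (bit-reproducible under a seed).

* **Spore scenes** — non-overlapping ellipses (rejection-sampled
  placement; > 30% planned coverage raises a generation error), major
  semi-axis 6–12 px, elongation 0–0.4; brightfield (background 0.85,
  objects ~0.2) or fluorescence (0.08 / ~0.8) polarity; distractors are
  1.5-px-half-width bars (elongation ~0.95) and sub-gate dust dots;
  additive Gaussian noise (default σ = 0.05).
* **Mycelium scenes** — a random planar tree: constant-step (2 px)
  polyline branches with angular jitter, children spawning at interior
  vertices at 0.5–1.1 rad.  Every branch claims an exclusion corridor of
  3 × width + 2 px, and junctions stay ≥ 24 px from branch ends, so the
  planted topology (recorded exactly as a graph with Euclidean centerline
  lengths) survives rendering, dilation, thinning, pruning and moderate
  noise.  Centerlines are dilated to an odd `branch_width` (default 3 px)
  at intensity ~0.72 with along-branch variation, over background 0.05
  plus a low-frequency sinusoidal illumination gradient (amplitude 0.1 by
  default) and Gaussian noise.
* **Trap scenes** — clusters of 6–10 overlapping annuli whose centers sit
  one ring-radius from the trap center (union connected, compact, low
  elongation, area ≫ hypha cross-section) over faint thin hyphae
  (intensity 0.55 on 0.85 background), so a trap-scale calibration counts
  exactly the planted clusters.
* **Growth series** — one tree grown once; frame k renders its first
  k·`growth_per_frame` branches, so frames are nested and planted length
  strictly increases.

What passing on these scenes does and does not show: the renderer draws
hard-edged binary structures with no point-spread function, no depth of
field and no focal loss (optics simulation is out of scope), so with the
reference calibrations the threshold margins are wide — counting errors
are typically zero and pixelwise segmentation scores saturate at or near
1.0.  Meeting the accuracy floors therefore demonstrates end-to-end
pipeline correctness under noise, gradients and distractors, not expected
performance on real micrographs, which lose contrast to blur and uneven
staining and must be calibrated per image set.

## Reference calibrations and benchmark design

`mycovision.presets` records the parameter sets for the three synthetic
families (rationale documented in the module).  The spore-counting
benchmark nonetheless re-calibrates at run time on a held-out scene
(index 0 of the seed family): a coarse grid over the strong threshold and
minimum area, ties broken toward the reference values — the grid analogue
of slider calibration against a manually counted image — and applies the
single winning parameter set to all 20 evaluation scenes (25–200 spores
each, σ = 0.05, 10 distractors).  The mycelium suite uses the fixed
reference calibration on 10 scenes.  Scene seeds derive as
`base_seed·1000 + index`.

## Degenerate inputs and numerical conventions

Empty images yield empty component lists, empty graphs and all-zero
metrics.  `gaussian_radius = 0` returns an all-zero background-subtracted
image (the image minus itself); `min_hyphae = 0` disables cleaning;
`scale = 1` keeps pixel units.  Convex hulls of collinear node sets
return area 0 (Qhull degeneracy is caught).  `droplet_to_dish` rounds to
the nearest integer.  Percent error is undefined for a zero manual count
and raises.  Batch processing orders images lexicographically, which also
defines time-series order; reruns are byte-identical because nothing
depends on wall clock or unseeded randomness.

## Limitations

2-D only: aerial hyphae and other 3-D structures are outside the model.
No declumping of touching spores; no trap-type discrimination (rings vs
networks — detection is purely size + elongation); no growth-curve
fitting (the time-series output is the raw metric trajectory); hulls use
graph nodes, not all foreground pixels.  Thinning shortens each terminal
branch by roughly half the hypha width, so measured total length
underestimates the drawn centerline length by ~0.5·width per tip.
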