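# Methods

`vastree` models a retinal vascular network as a *tree model*: a root node
(the optic disc, OD) plus one binary tree per vessel, each node holding one
traced vessel segment and a five-component feature vector that is invariant
to rotation, translation and uniform scaling up to raster discretization.
Two images of the same retina are compared by matching these trees.

## The tree model

A vessel segment runs from the OD boundary or a splitting landmark
(bifurcation or branch point) to the next splitting landmark or a terminal
tip.  Every split produces exactly two daughters, so each vessel is a
binary tree; crossovers (2-D projections of two vessels crossing) do *not*
split a segment — tracing continues straight through them and the crossing
is recorded as an attribute of the segment.  Each node carries:

| feature          | definition                                                         | invariance argument |
|------------------|--------------------------------------------------------------------|---------------------|
| `lw_ratio`       | segment length / average width                                     | ratio of lengths    |
| `bibr_code`      | 1 = ends at a bifurcation, 0 = branch (or terminal)                | discrete            |
| `crossover_flag` | 1 iff a crossover lies on the segment                              | discrete            |
| `crossover_pos`  | pixel index of first crossover / segment pixel count               | ratio along one line|
| `acute_angle`    | acute angle between the widest and narrowest of {parent, daughters} at the landmark, radians in [0, π/2] | angles are isometry-invariant |

Children are ordered deterministically: the left child is the daughter of
larger measured width (ties: smaller angle to the parent direction, then
lexicographic start pixel).  An optional normalization pass divides every
`lw_ratio` by the model-wide maximum and every angle by π/2; it is OFF by
default, and the matcher undoes it through the stored parameters so results
do not depend on it.

## Matching

Two trees are aligned position-by-position along the preorder traversal of
the complete binary tree of depth 2 (7 positions; absent positions are
explicit gaps).  A position matches when both are gaps, or both nodes agree
on the discrete features, on `lw_ratio` within a ±5% relative tolerance, on
`crossover_pos` within ±0.05, and on the angle within 5% of a right angle
(≈4.5°; setting the angle tolerance to 0 recovers a strictly literal
discrete-plus-ratio rule).  The tree distance is the number of mismatching
positions — an integer in [0, 7] at depth 2, and a pseudometric under exact
(zero-tolerance) matching.  Vessel correspondence between two models is
greedy: each tree of the first model takes the closest unmatched tree of
the second, even when the best distance is nonzero.  The inter-model
distance sums the pair distances plus a 7-node penalty per unmatched
vessel, computed once per unordered pair so the matrix is symmetric.

The ±5% tolerance exists because rasters quantize positions: rotating an
image and rebuilding the model shifts every continuous feature slightly.
The package's headline property, checked end-to-end in the tests, is that
for clean synthetic scenes rotated by 5°–30°, same-vessel distances are 0
under the tolerance while distances to other vessels stay large.

## Pipeline numerics

**Fragmentation.** The centerline is cut at landmark *zones* — all
centerline pixels within Chebyshev radius 3 of the (snapped) landmark.
Radius 3 rather than the 8-neighbourhood matters: two junction arms
meeting at ~50° remain 8-adjacent up to ~4 px past the junction, and a
smaller zone leaves sibling fragments connected.  Landmarks more than 2 px
off the centerline are snapped with a warning; more than 5 px is an error.

**Tracing.** Region growing over the 8-neighbourhood with visited flags,
choosing among multiple candidates the pixel that deviates least from the
mean of the last 5 step directions.  A trace runs both ways from its start
pixel so a segment always covers its whole fragment.  At a crossover zone
the continuation is the fragment pixel across the zone whose outgoing
direction deviates least (up to 75°) from the incoming direction; the two
parts are bridged through the zone and form one segment, with the crossing
recorded at the bridge pixel nearest the crossover landmark.

**Length.** Euclidean polyline length with chords every 10 pixels,
extended to the adjacent landmark positions at both ends.  Raw pixel count
is *not* rotation invariant (a 100-px horizontal run becomes an 87-pixel
digital line at 30°), and the fragment cut position jitters by ±2 px
between rasterizations; chord resampling plus landmark anchoring keeps the
length stable to ~1%.  The pixel count is kept for `crossover_pos`, whose
numerator and denominator quantize identically.

**Width.** Measured from the binary mask as a subpixel boundary estimate,
not a point-sampled distance transform: distance-transform values are
distances to background pixel *centres*, quantized to levels like 2, √5,
2√2 — on a 3-px-wide tube nearly aligned with a raster axis every sample
locks to one level and the estimate can be ~25% off with zero variance.
Instead, mask pixels are binned by position along the fitted segment axis;
in each 1-px bin the tube boundary is bracketed between the outermost
covered and innermost uncovered pixel on each side.  Per-bin two-sided
midpoints cancel axis tilt and average the quantization sawtooth; a joint
feasibility fit over all bins (scanning a small residual tilt, taking the
tilt that maximizes the smaller side margin) pins the boundary to a
fraction of a pixel once the subpixel phase drifts through a period along
the segment.  Nine path pixels are trimmed at landmark-adjacent ends
(junction masks are inflated by the parent tube), pixels within 8 px of a
crossover are excluded (the mask there is a union of two tubes), runs
shorter than 25 px are dropped when a longer run exists, and bins whose
midpoint width juts more than 2 px from the median are discarded as
contaminated.  Accuracy on isolated tubes: ≤±0.1 px across orientations
≥2.5° from raster axes/diagonals for widths 2.5–8 px.

**Angle.** Directions are total-least-squares (PCA) line fits over the 30
path pixels nearest the landmark, a window chosen so that the angle noise
between two independent rasterizations stays well below the 4.5°
tolerance (at 20 px it is marginal).

## The synthetic generator

The generator emulates the *output* of upstream vessel segmentation,
centerline extraction and landmark classification — the stages this
package deliberately does not implement — with exact ground truth.
Defaults define the study conditions:

- 512×512 image, OD of radius 30 px at the centre (the OD size is a free
  parameter of the problem; 30 px leaves the largest rotation-safe growth
  budget), 5 vessels, 2 levels of splits → 7 segments per vessel;
- root width 8 px, daughter width = parent × 0.8, the narrow daughter
  scaled by a further 0.7 so the smallest daughter is always unique
  (nominal widths 8, 6.4/4.48, 5.12/3.58/2.51);
- segment lengths uniform in (62, 74) px, ×0.9 per level, narrow leaves
  ×1.3 — thin tubes need more centerline length for a given relative width
  accuracy;
- branching: the narrow daughter leaves the parent at 0.5–1.3 rad (the
  acute-angle feature), the wide daughter at 0.40–0.55 rad on the opposite
  side, with at least 0.9 rad between daughters so their rasterized arms
  separate cleanly beyond the landmark zone;
- splits are branches vs bifurcations with probability 0.5 each;
  crossings are created per vessel with probability 0.5 by rerouting a
  wide-child leaf through another vessel's *root* segment at 60–90°
  (roots are the widest and longest segments, so both crossing parties
  still measure their widths well from the leftover profile runs; only
  wide children are rerouted because the crossing locally inflates the
  measured width, which could otherwise flip the width order against the
  narrow sibling).

All segment directions are snapped to a 5°-grid offset by 2.5°.  A thin
digital bar within ~1.5° of a raster axis or diagonal is *phase-locked*:
its rendered width quantizes to whole pixels and no estimator can recover
it to 5%.  On this grid, every rotation by a multiple of 5° — the rotation
protocol evaluated here — keeps every segment at least 2.5° away from such
degenerate alignments.  Geometry is rejection-sampled against clearance
rules (≥6 px between unrelated centerlines, ≥16 px between landmarks,
angular sector confinement per vessel) before rasterization; the
centerline is Bresenham-rasterized and the mask is the exact tube (pixel
centres within width/2 of the float polyline), which keeps rendered width
independent of orientation.

**Rotation.** Landmarks, the OD and the ground truth are rotated
analytically about the image centre and rounded; with ground truth
available the rasters are re-rendered from the rotated geometry.
Nearest-neighbour resampling of a 1-px 8-connected centerline disconnects
it wherever the digital line steps diagonally, so raster-resampled
rotation is only used when no ground truth exists (and is documented to
possibly break connectivity).  Re-rendering still re-quantizes every
coordinate at the new orientation — exactly the discretization error the
±5% tolerance is there to absorb.  Junction landmarks of the rotated truth
are re-derived from the rotated exact geometry, because rotating the
already-rounded originals displaces them ~1 px from the re-rendered
junctions.

### What the generator does and does not emulate

It produces the right *class* of input — binary centerline and vessel
rasters, labelled landmarks, an OD circle, vessels as full binary trees
with decaying widths and occasional crossings — with clean geometry:
straight segments, exact landmark labels, no segmentation noise, no
missing or spurious landmarks, no pathology, no tortuosity, no
illumination artefacts.  Passing tests therefore demonstrate that the
representation, features and matcher behave as designed on rasters with
pure discretization error; they do not demonstrate robustness to
segmentation failures or landmark misclassification on real fundus
photographs, which the matching distance would convert into nonzero
same-vessel distances.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the default scene
size (5 vessels × 7 segments, 512² rasters); rotation robustness is
checked over 6 angles × 5 seeds and topology recovery over 10 seeds, a
few seconds each.  Randomized invariants (oracle equivalence on 1,000 tree
pairs, pseudometric on 500 triples) use seeded NumPy generators;
hypothesis property tests run derandomized.  A given `SceneSpec` (seed
included) reproduces bit-identical scenes, and all writers are
byte-deterministic.

## Known limitations

- The narrowest rendered vessels (≈2.5 px) sit near the information limit
  of a binary raster: a width estimate cannot beat ~±0.1 px there.  In a
  large seed sweep, a few scenes in a hundred show one node-angle pair
  whose L/W difference lands just above the 5% tolerance (same-vessel
  distance 1 instead of 0 at one rotation angle).
- The width estimator assumes locally straight vessels over ~100 px (the
  synthetic scenes are piecewise straight); strongly tortuous vessels
  would need a shorter profile chunk at the cost of accuracy.
- Comparison depth 2 means vessels that differ only below the second split
  are indistinguishable to the matcher; this mirrors the method's own
  upper-levels design and its Table-2-style saturation at 7.
- Greedy correspondence is order-dependent when several trees tie; a
  globally optimal assignment is deliberately not used, matching the
  sequential description of the method.
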