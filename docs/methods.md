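# Methods

## Scope and model

`visprobe` tests whether a layered visual feature representation exhibits
twelve classic perceptual/neural regularities, using only distances between
activation vectors.  For a stimulus image the extractor produces one unit
response vector per layer; the dissimilarity between two stimuli at a layer
is the Euclidean distance between the corresponding vectors (cityblock and
one-minus-Pearson are available as alternatives).  Almost every experiment
reduces to a normalized difference of two dissimilarities,

    index = (d_a − d_b) / (d_a + d_b) ∈ [−1, 1],

with the roles of d_a and d_b chosen so that a positive index is the
direction observed in human perception or high-level (inferotemporal)
visual cortex.  Per-layer profiles carry the mean index, the s.e.m. across
items (sd/√n), the item count, and an exclusion tally for items with
d_a + d_b = 0 (undefined indices are excluded and counted, never imputed as
0 — imputation would silently bias a bounded statistic toward "absent").

A property receives a *presence verdict* from the last fully connected
layer of the extractor: **present** if the signed quantity there is
positive and its magnitude exceeds its s.e.m., **absent** otherwise,
**undefined** if the layer is flagged.  For extractors without a fully
connected layer (the pixel extractor) the final layer is the read-out
stage.  Experiments whose primary result is not a contrast index use
documented signed quantities (see `battery._PRESENCE_RULES`): the
normalization verdict requires both fitted slopes within 0.1 of the
divisive-normalization values 1/2 and 1/3; the Weber verdict uses
r_rel − r_abs; the sparseness verdict uses the reference-vs-morph
correlation; the two-condition experiments (3D, occlusion) require the
weaker condition to be positive.

## The twelve procedures

1. **Thatcher effect.** d_upright = distance between a face and its
   locally-inverted (eyes/mouth flipped) version, both upright;
   d_inverted = the same after 180° in-plane rotation of both images.
   Index (d_upright − d_inverted)/(d_upright + d_inverted).  Because
   rotation permutes pixels identically in both pair members, any
   pixel-like representation gives exactly 0 — a built-in null.
2. **Mirror confusion.** (d_horizontal − d_vertical)/(sum), where the
   distances are from an object to its up-down and left-right mirror
   images; positive = left-right mirrors are more confusable.
3. **Scene incongruence.** Per object, the average feature vector over all
   of that object's images (isolated + congruent scene + incongruent
   scene); the index contrasts the incongruent scene's distance to this
   average against the congruent scene's.  Averaging only the two scenes
   would place the average at their midpoint and force the index to zero
   identically, so the isolated object is included.  A classifier-based
   variant reports top-1/top-5 accuracy on congruent vs incongruent scenes
   with a deterministic ascending-class-index tie-break.
4. **Multiple-object normalization.** Units are kept only if they respond
   differently to at least one image within *each* of the three singleton
   locations; for each kept unit and multi-object display the point
   (sum of singleton responses, display response) is pooled, and an OLS
   slope (free intercept) is fit for pairs and triplets separately.
   Averaging responses imply slopes 1/2 and 1/3; summing implies 1.
   Note that units with spatially local receptive fields cannot vary
   across all three locations, so convolutional layers of a local network
   are typically flagged undefined here by design.
5. **Correlated sparseness.** Sparseness
   S = (1 − (Σrᵢ/n)²/Σ(rᵢ²/n)) / (1 − 1/n) per unit and stimulus subset
   (0 = uniform, 1 = one-hot), after min-max normalization of each unit
   over the compared subsets; units must be visually active (response
   variance above a relative tolerance of 1e−12) on both subsets.  The
   reported quantities are Pearson correlations across units between
   subset sparseness values (reference vs mean-over-morphlines, texture vs
   silhouette); morphline sparseness is averaged over the four morphlines
   before correlating.
6. **Weber's law.** Over all unordered bar pairs, r_abs = correlation of
   distances with |Lᵢ − Lⱼ| and r_rel = with |Lᵢ − Lⱼ|/(0.5(Lᵢ + Lⱼ));
   r_rel − r_abs > 0 indicates Weber-like coding.  The default length
   ladder mixes geometric and arithmetic spacing so the two predictors
   decorrelate (their correlation is kept below 0.95).
7. **Relative size.** Two-part objects with part sizes crossed 2×2.  Per
   (unit, tetrad) the interaction |r11 + r22 − r12 − r21| is computed over
   visually responsive units; the top ⌈7%·N⌉ entries per layer are kept
   (stable tie-break in unit-major order); each entry scores
   (d1 − d2)/(d1 + d2) with d1 = |r12 − r21| (incongruent cells) and
   d2 = |r11 − r22| (congruent cells).  The within-unit "distance" between
   two scalar responses is the absolute difference, matching per-neuron
   analyses.  Responses linear in the levels have exactly zero interaction
   and are excluded by the selection itself; an all-zero layer is flagged
   undefined.  The s.e.m. is across selected (unit, tetrad) entries.
8. **Surface invariance.** Same machinery on pattern×surface tetrads with
   the top 9% of interactions, after per-unit min-max normalization over
   the stimulus set.
9. **3D processing.** Per shape family (cuboid, cube, frustum), d1 =
   distance between the two 3D-interpretation drawings and d2 = distance
   between the members of a 2D control pair carrying the identical
   changed-stroke mask; the two control conditions are reported separately
   rather than averaged.
10. **Occlusion.** (d2 − d1)/(d2 + d1) with d1 the distance across the
    occlusion (or depth-order) manipulation and d2 across the matched 2D
    feature control; positive = the occlusion is discounted.  The source
    literature states this index with both orderings of d1/d2 in different
    places; this package fixes positive = perception-like.
11. **Part decomposition.** (A) break index (d_u − d_n)/(d_u + d_n) from
    the intact object to its unnatural- and natural-cut versions.  (B) the
    part-sum model d(AB,CD) = C_AC + C_BD + X_AD + X_BC + W_AB + W_CD +
    constant is fit by least squares to all C(49,2) = 1176 pairwise
    distances within each 49-object composite set (a seeded subsampling
    option that always retains the common pairs is available); each fit is
    evaluated as the Pearson correlation between observed and predicted
    distances on the 21 pairs of the 7 common objects, and the natural
    part advantage is r_natural − r_unnatural.  Same-part relations map to
    zero so each term family keeps exactly C(7,2) = 21 columns; part pairs
    are canonicalized unordered; rank-deficient designs fall back to the
    minimum-norm solution with a warning.
12. **Global advantage.** d_global = mean distance over the 147 pairs
    sharing the local shape, d_local over the 147 pairs sharing the global
    shape; the index is a ratio of means, so its s.e.m. comes from a
    seeded bootstrap (1000 resamples) over the two pair sets.

## Synthetic stimuli

All stimulus families are generated programmatically as 8-bit grayscale
rasters (default canvas 224×224, configurable; the battery default is
64×64), each a pure function of its parameters and seed.  What they emulate
and what they do not:

- **Faces** are parametric schematics (oval head, eyes with brows and
  offset pupils, nose, smiling mouth) with eye/mouth boxes known exactly by
  construction, replacing landmark registration on photographs.  Box
  content is vertically asymmetric so local inversion is visible.
- **Mirror objects** are asymmetric radial-contour silhouettes; half the
  bases are 90° rotations of the other half, balancing elongation.
- **Scenes** pair blob objects with band-pass noise contexts; congruence is
  defined by construction (context i belongs to object class i).  There is
  no semantic content — only the statistical association is modelled.
- **Multi-object displays** place blob sprites at three disjoint
  locations, so every pair/triplet is the exact pixelwise composition of
  its singletons.
- **Shape sets**: 8 reference radial-contour silhouettes; 4 morphlines by
  linear interpolation of contour parameters (5 steps, endpoints exact);
  128 band-pass textures; 128 silhouettes.
- **Bars, tetrads, line drawings, occlusion displays, part objects,
  hierarchical stimuli** follow the geometric contracts asserted in the
  test suite (e.g. identical changed-stroke masks across a 3D family;
  breaks that open a gap while preserving foreground area; composite
  diagonals reproducing the original objects; element positions depending
  only on the global shape).

Because the stimuli are schematic, passing tests demonstrate that the
*procedures* behave correctly and that each index separates its intended
coding schemes; they do not by themselves establish how a network trained
on natural images would score on photographs.

## Extractors and surrogates

The pixel extractor exposes one input layer whose units are the image
intensities.  The reference convnet is a small untrained network (three
conv→relu→pool blocks, two fully connected layers, zero biases, Gaussian
weights with std 1/√fan-in — the fan-in scaling keeps deep activations in
range so selectivity analyses are nondegenerate) with all weights drawn
from a seed; it stands in wherever a deep layered representation is needed
without any training.  External pretrained networks can be plugged in
through the extractor contract (ordered layer specs + per-layer matrices);
no weights are bundled.

Analytic surrogates read stimulus metadata rather than pixels and realize
a declared response law exactly, serving as oracles: averaging/summing
over display constituents, linear/logarithmic length tuning, global-only/
local-only tuning, size-ratio tuning, a context-boosted classifier, and a
part-sum generative model.  For the generative model the "world" is the
natural decomposition: distances for the unnatural composite set are
produced from latent part labels ((left, (left+right) mod 7)) that
deliberately differ from the tagged ones, so a part-sum fit using the
tagged unnatural labels is imperfect by construction and the natural part
advantage is strictly positive under zero noise.  Per-tag surrogate vectors
are derived via CRC32-keyed generators, so they are stable across processes
and call orders.

## Numerical choices

- Visual activity threshold: response variance above 1e−12 × mean-square
  response (exact zero variance is fragile in floating arithmetic); an
  absolute tolerance can be supplied instead.
- Top-k% tetrad selection keeps ⌈fraction·N⌉ pooled (unit, tetrad)
  entries with a stable tie-break.
- OLS slopes include a free intercept; all analytic oracle cases are
  intercept-insensitive.
- Pearson correlation throughout; degenerate (zero-variance) inputs yield
  flagged undefined values or errors rather than silent zeros.
- The reference convnet runs in float32; distances and statistics are
  computed in float64.
- Battery seeds: each experiment derives its stimulus seed from the config
  seed through a SeedSequence, so experiments are independent but the whole
  run is reproducible bit-for-bit (hash-stable CSV/JSON, config hash
  recorded in both).

## Problem sizes

The default battery runs all twelve experiments at the study-scale counts
(20 faces, 100 mirror objects, 40 scene objects, 49×3 singletons + 200
pairs + 200 triplets, 8+20+256 shape-set images, ~11 bar lengths, 24 size
tetrads, 24 surface tetrads, 18 line drawings, 7 occlusion displays, 119
part-object images, 49 hierarchical stimuli) on a 64×64 canvas with the
64×64-input reference convnet; a full run takes well under a minute on one
CPU.  Canvas size, counts, and extractor width are configurable upward.

## Known limitations

- Reported human/monkey reference values exist only as figure annotations
  in the source literature; the bundled constants file records their
  provenance with null values rather than inventing numbers, so plots show
  no dashed reference lines by default.
- The geometry of most stimulus families (sizes, spacing, stroke widths)
  is a declared default, not an inferred one.
- The "natural vs unnatural cut" distinction for synthetic contour objects
  (waist junction vs fixed offset into a part) is a geometric stand-in for
  the perceptual definition.
- Weber's law for image *intensity* is not implemented (the length variant
  is); cross-architecture comparisons and pretrained-network replication
  require user-supplied extractors.
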