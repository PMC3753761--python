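# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic phantom does and does not
emulate, and the numerical choices made where the original workflow left
the design open.

## Scope and data model

The pipeline operates on 3D microCT volumes calibrated to Hounsfield
Units (HU), axis order `(x, y, z)` with `z` the slice axis and the egg's
blunt-to-pointed direction. The reference geometry is 604 slices of
256 × 256 pixels at isotropic 0.216032 mm voxels; all tunables are
expressed in voxels or mm so other geometries work unchanged. Label
maps carry one semantic class per voxel from the rule set's vocabulary
(background, bed, coarse egg/bed composites, egg, shell, shell border,
interior, temporaries, skeleton). Connectivity conventions: 26-neighbor
for connected components, 6-neighbor (voxel faces) for borders and
growth fronts.

## Automatic threshold (AT)

`automatic_threshold` maximizes Otsu's between-class variance on a
256-bin histogram and returns the cut, or *none* when no acceptable cut
exists. Two exits produce *none*:

* the best cut's between-class variance is below `min_gain` (default
  1e-4) of the total variance — degenerate input;
* the best cut's *normalized* between-class variance (Otsu's η ∈ [0,1])
  is at most `min_separation` (default 0.70) — homogeneous input.

The second exit is the load-bearing one. Splitting a single Gaussian
mode yields η = 2/π ≈ 0.637 *no matter where the cut falls*, so a pure
variance-gain test can never recognize "nothing left to separate"; every
genuinely bimodal contrast in this problem (air/bed ≈ 0.99, shell/interior
≈ 0.99, interior/bone ≥ 0.75) clears 0.70 comfortably. This floor
operationalizes the homogeneity component of the original (proprietary)
AT and is what lets the nested bone loops exit.

Tie-break: with an empty histogram gap between two modes the criterion
is exactly flat across the gap; the cut is placed at the midpoint of the
maximal plateau, which is deterministic and keeps the threshold centered
between well-separated modes.

## Egg detection

1. **Background separation.** Gaussian blur with kernel 51 × 51 × 99
   voxels (σ = kernel/6, so the kernel spans ±3σ; the original states
   only the kernel size), min-max normalization, cut at 0.1, largest
   connected component kept.
2. **Egg/bed split.** The blurred object carries a wide air skirt, so
   slice sub-objects are defined on its intensity-tight restriction: a
   recursive AT finds the air/matter boundary (a single Otsu cut on the
   trimodal air/soft/shell histogram may isolate the bright shell
   minority; when a cut leaves < 35% of mass above it, the lower part is
   re-split), then the cut is pushed 45% of the way toward the
   soft-tissue median so mostly-air partial-volume voxels cannot bridge
   the egg/bed tangent contact. Per axial slice, a 5-voxel 2D erosion
   defines sub-objects: it erases the thin bed slab entirely and breaks
   the contact zone; surviving components are scored by roundness
   (largest enclosed disc radius via the distance transform over the
   minimum enclosing circle radius; threshold 0.65 — egg cross-sections
   score > 0.9, bed slabs < 0.1) and tight voxels within erosion + 1.5
   of a round component are reconstructed onto it. The bed is modeled
   *before* any regrowth — AT over background-plus-peeled-material
   (separation floor 0.85), largest component — so that the `Bed` class
   blocks the subsequent growth from leaking back along `z`. The round
   cores then regrow into the remaining `Temporary` material, first
   along `z` (surface tension 9/26: locally flat fronts advance, which
   recovers thin egg end caps; fronts along thin remnants stall) and
   then in-plane at the stringent 0.5 (nothing flat grows back — the
   cores are already full-extent, so in-plane growth only smooths
   concavities). Finally the bed is pushed along `z` through the coarse
   object (tension 0.1, so even one-voxel bed wedges are swept out).
3. **Refinement.** Voxels above coarse-egg mean + 500 HU seed the egg
   (in practice the bright shell ring), three expansion/reduction rounds
   (iterated 6-neighbor closing) smooth it, and hole filling makes it
   solid.

Surface tension is implemented as: a candidate voxel is absorbed only if
at least θ of its 26 neighbors already belong to the growing class, with
synchronous per-iteration updates (deterministic). Note the geometry of
this rule: a locally flat front exposes 9/26 ≈ 0.35 of a candidate's
neighborhood, so θ = 0.5 stalls *all* flat fronts — that is the
"stringent" setting that stops leakage through necks — while θ just
below 9/26 admits flat fronts but stalls convex/narrow ones. The stage
defaults above were chosen from this analysis.

## Shell segmentation

AT over the egg's HU separates `Shell` (above) from `Interior` (below);
the error path (AT *none*) covers eggs without internal contrast. The
two-voxel `Shell Border` is built by two face-dilation passes of the
shell restricted to interior voxels. It sits on the interior side
because that is what makes the bone stage's shell-contact test
meaningful: a bone near the shell touches the border layer, not the
shell itself.

## Bone segmentation

Three nested loops, state kept in the label map:

* **Outer loop** (cap 20): repeats full rounds; terminates when a round
  adds fewer than `gain_min` (default 5e-5, i.e. 0.005%) of the current
  skeleton voxel count.
* **First inner loop** (cap 10): AT over `Interior`; voxels above the
  cut form `Temporary Skeleton` components. A component is promoted to
  `Skeleton` if its relative border to `Shell Border` is ≤ 0.1 and — on
  outer passes after the first — it also touches existing `Skeleton`
  (relative border > 0, the literal reading of "shares a border"). The
  loop exits when AT returns *none* or repeats the previous cut.
* **Second inner loop** (cap 10): unpromoted candidates are
  re-thresholded; the sub-cut fraction becomes `Temporary No Skeleton
  2`, and each remaining core is scored by a fuzzy AND (minimum) of two
  decreasing memberships — over its relative border to the shell border
  and to the split-off fringe. Default membership is linear over
  [0, 0.2] (twice the promotion cap; a normalized logistic alternative
  is available); a score ≥ 0.5 accepts the core. Exit on AT *none*
  ("best separating value reached").

Relative border is face-counted: of an object's exposed faces, the
fraction adjacent to the query class. Rejected material returns to
`Interior` between rounds. Components under 4 voxels are discarded as
sub-resolution noise (configurable). Skeleton growth is monotone across
outer passes by construction, and re-running the stage on its own output
is a no-op (the recycled material re-thresholds to the same rejection).

## Morphometry

The eigen box takes the covariance of the object's voxel centers (in
mm), adds the voxel-extent correction `spacing²/12` to each diagonal
(the variance of a uniform distribution over one voxel), and
eigendecomposes. Edges are `eᵢ = k·√λᵢ` with `k` fixed by
`e₁e₂e₃ = volume`; for a solid axis-aligned cuboid this recovers the
exact edge lengths (without the correction, lengths are biased low by
one voxel-ish at small sizes). Length/width/thickness are e₁/e₂/e₃.

The remaining features use documented surrogates where the original
formulas are proprietary; each preserves the feature's qualitative
meaning, which is all the classifier needs:

| feature | definition |
| --- | --- |
| asymmetry | 1 − √(λ₃/λ₁) |
| border length | exposed-face count × spacing² |
| compactness | volume / oriented (eigen-axis) bounding-box volume |
| elliptical fit | fraction of object voxels inside the equal-volume eigen-aligned ellipsoid |
| rectangular fit | same with the eigen box |
| roundness | inscribed-sphere radius (distance transform) / min enclosing sphere radius (Welzl) |
| shape index | face-counted surface area / (6·volume^{2/3}); 1 for a cube |
| CT stats | mean, SD, Fisher skewness (bias-uncorrected), min, max of the object's HU |
| neighbor count | other skeleton objects with centroid distance ≤ 50 voxels |
| distances | minimum border-to-border Euclidean distance (mm) to the nearest skeleton object and to the shell |

A note on compactness: with the eigen-box edges constrained to multiply
to the object volume, the ratio volume/(e₁e₂e₃) is identically 1, so the
oriented-bounding-box denominator is used instead — it genuinely equals
1 for a solid cuboid and drops for bent or ragged shapes.

## Classification

Features (the 23 plus day of incubation) are standardized to zero mean
and unit SD; zero-variance features standardize with SD 1 under a
warning. The classifier is a one-vs-one soft-margin RBF SVM (SMO
lineage), shipped defaults C = 1.25 and γ = 0.1125 — the grid-search
optimum reported for the original annotated corpus, kept as defaults
because that corpus is not redistributable. `grid_search` re-derives an
optimum for any dataset over C ∈ 2⁻⁵…2⁵, γ ∈ 2⁻⁷…2³ (ties toward
smaller C, then smaller γ) by stratified k-fold accuracy.

Probabilities come from pairwise (one-vs-one) logistic calibration of
the SVM outputs. A one-vs-rest calibration was rejected: with ~50
positives per bone class, per-fold logistic fits see a handful of
positives and collapse the rare classes. Cross-validation uses
stratified folds and scores raw SVM labels; day-transfer evaluation
applies the calibrated model, since that is the model one would apply
to unseen scans.

The anatomical constraint runs per specimen: for any bone class
predicted more than twice, the two highest-probability objects keep the
label and the rest become NOI (ties broken by object id). NOI itself is
unconstrained.

## The phantom: what it emulates, what it does not

`generate_phantom` renders, at the reference geometry (or a scaled
variant — `scaled(2)` gives 128 × 128 × 302 at 0.432064 mm, the size
used throughout the tests and the acceptance script to keep desk runs
in minutes):

* an axially aligned ellipsoidal egg, semi-axes (16, 16, 24) mm, with a
  4-voxel shell at 2200 HU;
* a carbon-fiber bed slab (3.5 × 26 mm cross-section, full scan length)
  tangent to the egg from below, at 60 HU against a 40 HU interior —
  deliberately almost iso-intense, which is the property that forces the
  morphological egg/bed split;
* 14 long-bone rods (two per class: humerus, radius, ulna,
  carpometacarpus, femur, tibiotarsus, tarsometatarsus) with elliptical
  2.2 × 1.8 mm cross-sections, gentle bow, day-dependent lengths
  anchored at literature-plausible day-15 values and per-class
  elongation rates in the 0.5–2.9 mm/day range; bone HU is
  700 + 40·(day − 13), monotone in incubation day as calcification is.
  One humerus points radially and stops two voxels short of the inner
  shell surface — the shell-adjacent hard case. Rods sit on one angular
  slot per class (left/right on opposite sides) with a 3 mm per-class
  z-stagger so they stay disjoint at every day;
* two debris blobs near the egg poles (600 HU) that the bone stage
  correctly segments and a classifier must label NOI;
* Gaussian partial-volume smoothing (σ = 0.5 voxel) and additive
  Gaussian HU noise (SD 25).

Not modeled: X-ray physics (beam hardening, ring artifacts, scatter —
the reference reconstruction corrects these upstream), cartilage (CT has
poor cartilage contrast), anatomically curved bone shapes, soft-tissue
heterogeneity, and egg-to-egg pose variation. Passing the phantom tests
therefore demonstrates the *rule set logic* — thresholds found, borders
respected, loops terminating, geometry measured — not performance on
real eggs, where HU distributions are broader and bones are neither
straight nor isolated.

`generate_feature_table` emulates the annotated training data at the
published class proportions (2951 objects, NOI majority). Classes
occupy Gaussian clusters in a latent 2D shape space — NOI at the origin,
the seven bones on a surrounding ring — so the multiclass problem is not
linearly separable (NOI needs a closed boundary) but separates cleanly
under an RBF kernel. Day-dependent separability mirrors calcification:
the ring radius grows by 0.3/day and the within-class spread contracts
by 9%/day. Carrying most of the day effect in the spread contraction
(not the radius) keeps held-out days inside the training support, which
matters for day-transfer evaluation: a radius-only design makes every
held-out day a covariate shift that the RBF SVM extrapolates poorly on.
The latent coordinates embed into the 20 non-derived feature columns via
a fixed projection on top of realistic baselines; ratio columns and
per-specimen relative volumes are derived afterwards so the exported
schema's invariants hold exactly. With these settings the table yields
~98% 10-fold CV accuracy at the shipped (C, γ) and a day-transfer curve
rising from ~95% (day 13) to ~99% (day 19).

## Numerical choices and degenerate inputs

* Histogram bins for AT: 256; thresholds partition as ≤ t / > t.
* Roundness of a single pixel is 1 by convention; the 2D minimum
  enclosing circle uses pixel centers.
* Welzl's minimum-enclosing-sphere runs on convex-hull vertices; the
  circumsphere solve is anchored to the first boundary point so the
  least-squares solution stays in the points' affine span.
* Objects with < 2 voxels get degenerate eigen boxes (all edges equal
  to the spacing).
* Growth rates use cross-specimen means (left and right bones pool);
  quartiles use linear interpolation; intervals with a missing day are
  skipped with a warning.
* All stochastic components (phantom noise, table sampling, fold
  shuffling, SVM internals) are seeded; fixed seed ⇒ bitwise identical
  outputs.

## Known limitations

* The egg/bed split assumes the bed is tangent from one side and
  axially continuous; a bed wrapping most of the egg would defeat the
  roundness criterion.
* Bones closer than ~2 voxels to the shell lose the voxels inside the
  shell-border layer; bones brighter than the shell AT cut would merge
  into the shell (not reachable with the phantom's HU model).
* The AT homogeneity floor (0.70) is calibrated for roughly Gaussian
  noise; strongly skewed or uniform noise has a higher unimodal η and
  would need a higher floor.
* Touching bones segment as one object by design; the original workflow
  annotates such clots NOI and the constraint handles surplus labels.
* Day-transfer accuracy at the boundary days reflects interpolation
  versus extrapolation of the day feature; the synthetic design keeps
  this mild, real data may not.
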