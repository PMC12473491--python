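# Methods

This note records the models, parameter choices and numerical decisions
behind `sesame3d`, and what the synthetic test bed does and does not
establish about real data.

## Units and calibration

All geometry is computed in the reconstruction's arbitrary units; real
units enter only through the scale factor `r = H_real / H_reconstructed`
(cm per unit) measured on a calibration cube of known 2 cm edge scanned
with the plant. The cube edge in the cloud is the mean of the three
axis-aligned bounding-box extents of the user-supplied cube sub-cloud —
robust to one under-sampled face. Lengths scale with `r`, areas with `r²`.
Automatic cube detection is out of scope; the caller crops the cube.

## Preprocessing cascade

Stages run in a fixed order: density → color → statistical → voxel.

- **Local density** (`k = 20` neighbors, keep the top 95 %): density is the
  reciprocal mean k-NN distance. Duplicated points would be infinitely
  dense and are clamped to the cloud's maximum finite density so they
  survive filtering without propagating infinities. The 95 % keep fraction
  removes sparse reconstruction flotsam without shaving leaf margins.
- **Color** (ExG > 30, strict): vegetation is green; soil and background
  are brown/dark. ExG = 2G − R − B; the normalised variant NExG =
  (2G − R − B)/(R + G + B) is available (NExG at pure black is defined as
  0 so dark background can never pass a green filter). The threshold is
  strict (`>`), so a point at exactly 30 counts as background.
- **Statistical outlier removal** (`n_neighbors = 5`, `std_coeff = 0.8`):
  drop points whose mean distance to their 5 nearest neighbors exceeds the
  global mean plus 0.8 standard deviations. Both values are configurable —
  the two roles are easy to transpose when reading parameter tables, so
  the constructor takes them explicitly by name.
- **Voxel grid** (default edge 0.04 units): one centroid (and mean color)
  per occupied voxel, indices `floor((x − min)/voxel)` with half-open
  cells; output ordered by first occurrence, so the operation is
  deterministic and idempotent once spacing exceeds the voxel diagonal.
  For the synthetic scenes in this repository a smaller voxel
  (0.003–0.004) is used because their absolute scale puts the
  density-clustering operating point at ε = 0.006 (see below); on clouds
  whose units make 0.04 appropriate the downstream ε should be scaled
  accordingly. The two defaults are not mutually consistent on a single
  cloud — a unit-system caveat users must resolve per dataset.

## Semantic segmentation network

The backbone is a set-abstraction (SA) / feature-propagation (FP)
hierarchy with multi-scale grouping: farthest point sampling picks
centers; per scale, a ball query gathers up to S neighbors within the
radius (indices in ascending order, first index repeated to fill, nearest
point as fallback for empty balls — avoiding NaNs on sparse regions); a
shared MLP encodes relative coordinates concatenated with features, and a
max-pool over the neighborhood gives the center's descriptor. FP
interpolates coarse features back with inverse-square-distance weights
over the 3 nearest sources (an exact coordinate hit takes essentially all
weight), concatenates skip features and applies a unit MLP. Input clouds
are centered and scaled to the unit sphere; features are xyz plus RGB/255
(RGB can be disabled).

**Context-anchor attention (CAA).** Inside each SA scale branch, after the
shared MLP, the (centers × samples × channels) map passes through: global
average pool → 1×1 conv channel reduction (reduction 4, floor 4 channels)
→ horizontal depthwise conv → vertical depthwise conv (k = 11 taps,
configurable) → 1×1 fusion conv → sigmoid. The resulting per-channel
weights multiply the feature map. With global pooling the spatial map is
1×1, so the depthwise convolutions reduce to their center taps and the
attention is spatially uniform per channel — consequently the encoder
remains permutation-invariant over neighborhood samples. The depthwise
convolutions are implemented as genuine k-tap convolutions so the block is
faithful for any pooled spatial size.

**Varifocal loss.** Per class with sigmoid confidences and one-vs-rest
targets: `VFL(p, q) = −q log p − (1 − q)^γ log(1 − p)`, averaged over
points and classes; γ defaults to 2.0 (the focal-loss convention). With
hard one-hot targets `(1 − q)^γ ∈ {0, 1}`, so γ is inert and the printed
form coincides with binary cross-entropy — an intrinsic property of this
form, asserted in the tests. An `original-vfl` option keeps γ active for
negatives (`−p^γ log(1 − p)` at q = 0). Disabling VFL switches to softmax
cross-entropy; disabling CAA removes the attention product. Both
ablations reproduce the plain backbone exactly (bit-for-bit identity
checked in tests).

**Training.** Adam (lr 1e-3, weight decay 1e-4 as classic L2-in-gradient,
batch 4, 200 epochs, 10 000 points per cloud, 8:1:1 split) are the
full-scale defaults. Each cloud is subsampled once, seeded, to the point
budget; prediction on larger clouds maps labels back by nearest sampled
neighbor. The epoch history records an end-of-epoch evaluation pass over
the training clouds (train loss/OA) plus the within-epoch running means;
best-validation weights are restored when a validation split exists.

Because the network runs on the package's own numpy reverse-mode autodiff
engine (validated against finite differences), training is CPU-bound and
meant for reduced problem sizes. The reduced configuration used in the
tests and acceptance script (`TOY_SA_CONFIG`) has 2 SA levels (192/48
centers, widths ≤ 64), 512 points per cloud, lr 0.005 with per-cloud
updates, and overfits five synthetic plants to ≥ 0.95 training OA within
50 epochs in a few seconds. Headline accuracies from large-scale GPU
training on real multi-plant datasets are outside what this repository
can reproduce; the tests establish the architecture's correctness
(identities, shapes, gradients) and trainability, not field performance.
The first-five-epoch loss-monotonicity count over five seeded runs is a
stochastic quantity; on the fixed test fixture it is ≥ 4 of 5, across
arbitrary seed sets typically 3–5.

## Leaf instance segmentation

Normals come from the smallest eigenvector of the local k-NN covariance
(k = 30). Because the curvature statistic uses normal *differences*, signs
must be consistent: orientation propagates along a minimum spanning tree
of the k-NN graph (edge cost 1 − |nᵢ·nⱼ|), then each connected component
is flipped to point outward (non-negative mean dot with centroid→point).
Curvature is the mean Euclidean norm of the difference between a point's
normal and its k neighbors' normals — dimensionless, bounded by 2.

Points above the curvature threshold (0.2) are removed as contact regions;
DBSCAN (ε = 0.006 units, MinPts = 10, scikit-learn implementation with
cluster ids renumbered by first member index) clusters the rest. Removed
contact points keep instance −1 by default; an option reassigns them by
majority vote of their nearest clustered neighbors. Clusters with fewer
than 30 points are excluded from the trait report (tiny fragments break
PCA and triangulation) but keep their labels. The defaults 0.2/0.006/10
are the balanced operating point of the parameter study this pipeline
follows: a lower threshold cuts real leaf edges, a higher one leaves
bridges; smaller ε over-segments, larger ε merges leaves; higher MinPts
monotonically grows the noise set.

## Trait extraction

- **Plant frame:** first principal component of the stem cloud = Z axis,
  sign chosen so the end nearest the original minimum height maps to low Z
  (ground at bottom); XY origin on the stem-axis centroid (an early
  version anchored on a stem *surface* point, which offsets the axis by up
  to a stem radius and corrupts petiole orientation); Z origin at the stem
  base.
- **Height:** bounding-box Z extent × r (cm).
- **Stem diameter:** Kåsa algebraic circle fit to the XY projection of the
  slice at 2 cm ± 0.2 cm above ground (slab configurable; the extractor
  retries with a doubled slab if the slice is too sparse). The fitted
  radius is debiased via the Rician moment relations
  `E[d²] = ρ² + 2σ²`, `E[d⁴] = ρ⁴ + 8ρ²σ² + 8σ⁴` solved for ρ — exact on
  clean data, and removing the upward bias that appears when coordinate
  noise is comparable to the stem radius. Reported in mm.
- **Leaf length:** the two mutually farthest leaf points (exact pairwise
  search up to 2000 points, double-sweep heuristic above) anchor a greedy
  walk that repeatedly moves to the in-radius point best aligned with the
  direction to the end, among points strictly closer to it; stalls jump to
  the nearest point strictly closer to the end. The step radius is 8× the
  median nearest-neighbor spacing — wide enough that the best-aligned
  candidate is nearly straight ahead (a 3× radius leaves so few candidates
  the walk zig-zags and overestimates by ~20 %). Accumulated length × r.
- **Leaf width:** extent along the leaf's second principal axis (default),
  so the measure is azimuth-independent; a `global-x` mode measures the
  literal plant-frame X extent for users wanting the bounding-box
  convention.
- **Leaf angle:** arccos of the Z component of the petiole's first
  principal component in the plant frame, oriented away from the stem axis
  by comparing the mean axis distance of the two projection-extreme
  quartiles (single extreme points flip under noise); radially ambiguous
  near-vertical petioles orient upward. Range [0, 180]°.
- **Leaf area:** project to the leaf's two principal components, Delaunay
  triangulate, sum 2D triangle areas × r², dropping triangles whose
  circumradius exceeds 5× the median edge length so the hull does not
  bridge concave margins. Planar projected area, not 3D surface area — an
  underestimate for strongly curled leaves.
- **Noise gate:** leaf length/width/area first pass the cloud through a
  thickness-gated denoiser: if the median local `sqrt(λ₃/λ₂)` of 20-point
  neighborhoods exceeds 0.4 *and* the median local thickness exceeds half
  the point spacing (i.e. the sheet is noise-thickened, not merely curved
  or one-dimensional), every point is replaced by its 30-NN centroid,
  shrinking noise ~√30-fold. Clean clouds pass untouched, so noiseless
  accuracy is unaffected.

Petioles are grouped per leaf by their instance id when present, otherwise
by nearest labelled leaf point; leaves without an associated petiole are
reported as skipped rather than given a fabricated angle.

## Synthetic plants and what they show

The generator builds parametric sesame-like plants: a vertical tapered
stem (default height 2.5 units, base radius 0.012, taper 0.3), petioles as
thin cylinders at specified insertion angles, and lanceolate laminae —
ruled surfaces of half-width `h(t) = (W/2)·sin(πt)^0.8` along a unit-speed
midrib that droops linearly in elevation. Ground truth (height, diameter
at the 2 cm-equivalent slice, per-leaf length/width/angle/area) is
computed by quadrature on the parametric forms, never from the sampled
points, so generator and pipeline share no code path. One unit is 40 cm
(cube edge 0.05 units), putting defaults at ~1 m plants, ~9.6 mm stems,
10 cm × 4.8 cm leaves; the randomized suite spans 0.8–1.2 m, 8–17.6 mm,
7–13 cm, 25–75°.

All plant surfaces share one sampling density (250 000 pts/unit²), chosen
so the DBSCAN operating point ε = 0.006/MinPts = 10 sits in its good
regime (≈ 28 expected points per ε-ball) — and matching the fact that
multi-view stereo densifies all surfaces comparably, which also keeps
statistical filtering from eroding sparser organs. Soil is sparser
(background). Scene colors guarantee the ExG = 30 split by construction:
plant greens stay above it and soil/cube colors below it under the ±10
RGB jitter. Coordinate noise is isotropic Gaussian; the recovery suite
uses σ = 0.5 % of plant height (≈ 5 mm real — pessimistic for close-range
reconstruction).

Adhesion cases weld a leaf pair into an "open book": both laminae share a
straight spine with a 120° dihedral, and points within 0.012 units of the
spine receive cross-surface jitter emulating the interleaved, disordered
points of a real contact area. This makes the pair ε-connected (plain
DBSCAN merges it) while curvature gating removes the contact strip and
separates the leaves.

What passing these tests does **not** show: performance on real
reconstructions with non-Gaussian artifacts (holes, ghost surfaces,
varying exposure), real leaf shapes (serration, strong curl), occlusion
truncation, or field-scale variation. The synthetic suite validates the
geometry and the algorithmic contracts, not biological generality.

## Numerical choices and degenerate inputs

- Collinear inputs: circle fit and leaf area raise; leaf width returns 0
  with a warning.
- DBSCAN border points reachable from two clusters follow the underlying
  implementation's deterministic index-order rule; oracle comparisons
  therefore check core-point partitions exactly and border membership up
  to that documented tie.
- Farthest point sampling breaks ties toward the lowest index; the first
  center is seed-derived.
- VFL confidences are clipped to [1e-7, 1 − 1e-7] before logs.
- Max-pool gradients route to the first maximum on ties.
- All randomness flows from explicit integer seeds (`numpy` Generators);
  fits and predictions are deterministic given seed and weights.

## Problem sizes

Default test-scale conditions: scenes of 45k–90k points, 10-plant recovery
suites (~60 leaves), 30k-point adhesion leaf clouds, training sets of five
~10k-point plants subsampled to 512 points. The full test suite runs in
under two minutes on one CPU; the acceptance script in about one.
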