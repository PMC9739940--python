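# Methods

`mixseedling` reimplements a single-view seedling phenotyping pipeline:
depth-camera point clouds of individual melon-type seedlings are denoised,
segmented into stem and leaves, occluded leaves are completed by a learned
generative decoder, and per-leaf surface area is measured.  This note
documents the models, the synthetic data that stands in for camera scans,
the numerical choices, and the limits of what the desk-scale experiments
show.

## The synthetic scene generator

No public seedling scan set exists for this task, so every experiment runs
on synthetic scenes with exact ground truth.  The generator models what a
top-down depth camera (orthographic along −z) sees of one potted seedling:

- **Leaves.** Each leaf is an ellipse in parameter space (minor/major ratio
  0.6) lifted by the quadratic bowl `z = κ(u² + v²)` and rigidly posed around
  the stem crown.  Sampling is rejection-corrected to be uniform in *surface*
  area, and the exact patch area is computed by Gauss–Legendre quadrature of
  the first fundamental form, giving every leaf an analytic area that the
  phenotyping stage can be tested against.  Defaults: semi-major axis 4 cm,
  κ = 8 m⁻¹ (≈1.3 cm bow), 1–3 leaves with top-view overlap controlled by an
  azimuthal compression factor (default 0.3).
- **Stem.** A 4 mm-radius cylinder leaning 50° from vertical (cucurbit
  seedlings sprawl; a perfectly vertical stem presents no upward-facing
  surface to a top-down camera at all).  Only the strip within 25° of the
  cylinder's most upward-facing line is sampled — the single-view visibility
  model.  This matters for the hover filter: the strip's normals stay within
  ~47° of the viewing axis, below the 60° deletion threshold, which is the
  geometric reason thin stems survive filtering.
- **Background.** A 0.5 m square ground plane at z = 0 and a box-like tray
  whose walls and bottom occupy the 12 cm band below it; background points
  carry the unlabeled sentinel (−1) so preprocessing, not the labels, must
  remove them.
- **Sensor noise.** Gaussian surface jitter (σ = 0.2 mm); *hover points* —
  for a fraction (default 0.3) of silhouette-edge points (points whose
  top-view neighborhood is one-sided), a chain of 6 points is strung at the
  same (x, y) between the organ and the first surface behind it along the
  viewing ray, emulating mixed returns at depth discontinuities; and sparse
  uniform outliers (2% of the cloud) in an inflated bounding box.  The noise
  densities are plausible free parameters, not calibrated against a specific
  camera.

What the generator does **not** emulate: self-occlusion shadows (every organ
surface is sampled even where a leaf above would block the view), RGB
texture, quantization/striping artifacts of time-of-flight sensors,
multi-plant trays, and leaf shapes beyond bent ellipses (no lobes, serration
or folding).  Passing tests therefore demonstrate the pipeline's mechanics
and its behavior under the modeled noise, not camera-grade performance.

## Preprocessing

1. **Crop box**: axis-aligned pass-through filter, 0.5 × 0.5 × 0.7 m about
   the camera axis.
2. **Ground plane**: the modal 1 cm z-bin locates the ground; a
   total-least-squares plane (smallest covariance eigenvector) is fit to the
   points within 1.5 cm of it.  Ground and the tray band extending
   0.11–0.13 m below the plane (default cut 0.12 m) are deleted; a cut
   outside that calibrated band warns rather than fails.
3. **Neighborhood-space-constraint filter**: for every point of the input
   cloud, `D` = mean distance to its N nearest neighbors and `W` = angle
   between the local least-squares plane normal and the viewing axis, folded
   to [0°, 90°] via |n·ẑ| because plane normals are sign-ambiguous.  A point
   is deleted iff `D ≥ d` or `W ≥ c`, with N = 12, d = 3.4 mm, c = 60°
   (d is in meters — sensor frame — consistent with the 0.5 m crop).  All
   D, W are computed before any deletion, so the pass is single-sweep and
   order-independent; hover chains trigger the angle branch (their local
   geometry contains the viewing ray) or the distance branch (chains are
   sparse along the ray), outliers the distance branch.  Measured on ten
   default scenes: ≥99% of injected noise removed, ≤2% of plant points lost.
4. **Normalization**: centroid to the origin, isotropic scale so
   max |coordinate| = 1; the (centroid, scale) record maps areas back to
   physical units (`area × scale²`).
5. **Sampling**: iterative farthest-point sampling (deterministic default
   start: the point farthest from the centroid); and curvature key-point
   sampling — surface variation `s = λ₀/(λ₀+λ₁+λ₂)` over 16-NN covariance
   eigenvalues, greedy highest-s selection under a suppression radius
   (bbox diagonal/√n) with farthest-point fill on exhaustion and a pure
   farthest-point fallback when all variations tie (flat surfaces).  The
   greedy surface-variation scheme is this package's concrete choice for
   "curvature sampling"; the upstream literature does not pin an algorithm.

## The network

A shared encoder with task-specific decoders, built on an in-repo
reverse-mode autodiff over numpy (float64, CPU, bit-reproducible given a
seed).  Writing the engine in-repo keeps the dependency surface to the
scientific Python stack and makes every gradient testable against finite
differences, at the cost of speed — hence the desk-scale defaults below.

- **Neighborhood aggregation** (per encoder stage): curvature-sample the
  stage resolution, group each center with its k nearest input points, and
  aggregate `max-pool_k LBR(concat(F_i − F_ik, repeat(F_i, k)))`, where LBR
  is linear → batch-norm → LeakyReLU(0.01).
- **Point-mixer block**: on the S × D group/channel matrix,
  `Fc = Fs + MLP(LN(Fs))` (channel mixing per group) then
  `Fo = Fc + T(MLP(T(LN(Fc))))` (group mixing per channel through a
  transpose); each MLP is two fully connected layers with a LeakyReLU
  between, hidden width equal to its input width.  Two blocks per stage.
- **Encoder**: resolutions 2048/1024/512/256 with k = 32/16/8/4.  The
  printed stage widths pair as 128/256/512/1024 — width grows as resolution
  shrinks, mirroring the decoder's widths (1024→128) as resolution grows.
  This coarsest-is-widest pairing is a deliberate resolution of the two
  list orders; it is configurable.
- **Completion decoder**: progressive 256→512→1024→2048 generation.  Each
  stage interpolates the running features onto the encoder's
  same-resolution points (inverse-distance 3-NN feature propagation,
  ε = 1e-8 — a simpler, standard up-sampler chosen in place of
  graph-convolution up-sampling; interpolation weights are treated as
  constants, so gradients flow through features only), concatenates the
  encoder skip features, applies an LBR fuse + mixer blocks, and emits
  per-point coordinates through a two-layer MLP; each stage's predicted
  points carry its features to the next stage.
- **Heads**: classification (channel-max pool over the coarsest stage, two
  LBR + dropout-0.5 stages, final linear); semantic segmentation (feature
  propagation back to full resolution with skip fusion, category one-hot
  concatenated, same head stack); instance embedding (pointwise linear +
  LeakyReLU to exactly 5 channels) clustered by flat-kernel mean shift
  (default bandwidth 0.2 = 2× the instance-loss margin, tying the clustering
  scale to the geometry the loss enforces; labels contiguous, ordered by
  cluster size).
- **Inference for completion** returns the final stage merged with the
  partial input (generated points within 1e-3 of an input point are
  dropped): the input region is trusted and only the missing region is
  hallucinated.

## Losses

- Semantic: mean softmax cross-entropy over labeled points (−1 sentinel
  excluded).
- Instance: `L = Ls + Lreg` with
  `Ls = (1/I) Σᵢ (1/Nᵢ) Σⱼ max(0, ‖cᵢ − fⱼ‖ − δs)²` and
  `Lreg = (1/I) Σᵢ ‖cᵢ‖`, margin δs = 0.1 in normalized units.  Note this
  objective has **no inter-instance push term**: a constant embedding is a
  global minimizer, so mean-shift on a converged embedding tends toward one
  cluster.  It is implemented exactly as specified; end-to-end instance
  separation on trained embeddings is therefore not asserted anywhere, and
  practical instance grouping on synthetic data is better served by
  clustering coordinates directly.
- Completion: sum over the four stages of the Chamfer distance
  `CD = ½[mean_x min_y ‖x−y‖ + mean_y min_x ‖x−y‖]` (non-squared norms)
  against farthest-point samples of the complete cloud at N/8, N/4, N/2, N.
  The training gradient treats nearest-neighbor correspondences as
  constants — the standard subgradient.
- EMD (evaluation only): exact Hungarian assignment up to 512 points;
  beyond that, Sinkhorn-regularized transport rounded to a feasible
  assignment (~1–2% tolerance on unit-scale clouds).

## Training

SGD with momentum 0.9 (the optimizer is unstated upstream; momentum-SGD is
the idiom that pairs with a cosine schedule) and cosine learning-rate decay
`lr_e = lr₀ · ½(1 + cos(πe/E))`.  Full-scale reference settings: 250
epochs, batch 32 (segmentation, lr₀ = 0.01) or 16 (completion,
lr₀ = 1e-4), 2048-point clouds.  The tested desk-scale configuration — the
package's own choice of problem size — is 256-point clouds, a
proportionally shrunk architecture (resolutions 256/128/64/32, widths
32/64/96/128), 30 epochs, batch 4, on 20 seedlings (segmentation) or 50
leaf pairs (completion).  At ~150 optimizer steps the full-scale learning
rates are far from convergence, so desk scale uses lr₀ = 0.05
(segmentation) and 0.01 (completion): larger in proportion to the shorter
schedule, same decay shape.  Batches are processed one cloud at a time with
gradient accumulation; batch-norm therefore normalizes over the points of a
cloud.  Measured under these defaults (seed 0): held-out semantic mIoU
≈ 0.93–0.95; held-out 50%-occluded leaf CD drops from ≈0.09 (partial) to
≈0.04 (completed) in normalized units.

## Leaf area

PCA-project the leaf to its best-fit plane, Delaunay-triangulate in 2-D,
lift, and sum triangle areas, with two noise guards chosen after measuring
their failure modes:

- **Height smoothing**: each point's out-of-plane coordinate is replaced by
  the mean over its 8-NN before lifting.  Without it, sensor jitter
  comparable to the sampling pitch crinkles the mesh and biases the area
  upward (and interacts destructively with any edge-based hole guard).
- **Hole guard**: triangles with an edge above 4× the *median triangulation
  edge* are discarded.  Keying the guard to the triangulation's own edge
  scale (rather than nearest-neighbor spacing, which jitter deflates) keeps
  it scale-free; the factor 4 passes a flat disc at 5000 points within 2%
  of π while still rejecting occlusion-sized gaps.  Occlusion produced by
  the viewpoint-nearest cut removes *boundary* regions, which simply fall
  outside the triangulation, so the guard's exact value is not load-bearing
  for the correlation study.

Known bias: ≈ −3 to −6% on the generator's leaves (boundary band loss at
finite sampling plus smoothing of the bow), systematic across a cohort and
therefore nearly invisible to R².  Measured on the 40-leaf occluded cohort
(50% missingness, seed 0): R² ≈ −1.2 before completion, ≈ +0.8 after —
the directional effect the pipeline exists to produce.  A leaf that folds
over its fitted plane would make the projection non-injective and the
estimate invalid; the generator's bow never does this.

## Degenerate inputs and tie-breaks

Collinear neighborhoods in normal estimation are flagged and assigned the
viewing axis; exactly collinear input to plane fitting raises.  Curvature
sampling breaks variation ties by point index and falls back to
farthest-point sampling when all variations agree to 1e-9.  The
nearest-fraction occlusion cut breaks distance ties by input index.
Mean-shift label order is cluster size descending, first-appearance on
ties.  All RNG flows from explicit integer seeds; two runs with the same
seed are bit-identical on CPU.

## Limitations

- Desk-scale results exercise the full architecture but say nothing about
  full-scale (2048-point, 250-epoch) accuracy; the full configuration runs
  (a forward pass takes ~15 s on one CPU core) but is untrained here.
- The instance objective's missing push term (above) limits learned
  instance separation by construction.
- Synthetic-to-real transfer is untested by design: no real scans ship with
  the package.
- The completion decoder's interpolation up-sampler is a stated
  simplification of graph-convolution up-sampling; no claim of equivalence
  is made.
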