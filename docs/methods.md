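# Methods

## The problem and the pipeline decomposition

The package segments individual cells in 3D single-channel membrane images:
volumes where thin bright sheets (labelled plasma membranes) separate dark
cell interiors, with dark background outside the tissue. The pipeline is a
composition `h(f(x))`: `f` is a trainable voxel classifier producing
background / membrane / cell-foreground probabilities, and `h` is a
deterministic clustering that turns the foreground mask into cell
instances. The design premise is that the hard part — neighboring cells
whose foreground masks adhere through membrane gaps ("clumped cells") — is
best attacked on both sides: the loss discourages the classifier from
claiming uncertain voxels near membranes, and the clustering can still cut
residual adhesions because they are thin relative to true cell contacts.

## Semantic stage

### Loss

For one class channel with prediction p, binary mask g, and per-voxel
weights w, the weighted Dice term is `1 − 2Σpgw / (Σp² + Σg²)`; weights
appear in the numerator only. The foreground channel replaces p by
`r = p/(p+α)`. Properties that matter:

* `r` is steeply increasing for p ≪ α·10 and saturates below 1, so the
  per-voxel gradient magnitude is large for low-confidence positives and
  smaller than the plain-Dice gradient near p = 1;
* at a perfect binary prediction the foreground term equals
  `1 − 2r/(r²+1)` with `r = 1/(1+α)` — 0.004525 at the default α = 0.1 — a
  residual penalty that keeps the regularization active throughout
  training;
* as α → 0 the term reduces to plain Dice *on binary predictions* (for
  continuous p the limit of r is the indicator of p > 0, so the identity
  is stated and tested for binary p only).

The "others" component averages (rather than sums) the background and
membrane Dice terms so that the foreground term keeps the same relative
weight regardless of how many non-foreground classes exist. Degenerate
channels (both p and g identically zero, possible under random cropping)
contribute 0, not NaN. Both terms have closed-form per-voxel gradients
(chain rule through r for the foreground); these exact gradients drive
training and are verified against central finite differences in the tests.

Weights come from a reverse distance transform of each class mask: with d
the Euclidean distance of an in-mask voxel to the nearest out-of-mask
voxel (the array border counts as out-of-mask), weights are affinely
rescaled so boundary-adjacent voxels get 1 and the deepest interior gets
`w_min` (default 0.5); out-of-mask voxels get 1 (they never enter the
numerator). This emphasizes exactly the membrane-adjacent voxels whose
misclassification causes adhesions. The affine normalization per volume,
the floor `w_min`, and weights-in-numerator-only are package choices fixed
here; keeping w ≤ 1 bounds every term in [0, 1] and the total in [0, 2].

### Network

A shallow U-Net operating on (Z, Y, X) scalar volumes: 3 resolution levels
(16/32/64 channels), two 3³ convolutions per level, residual strided-
convolution downsampling (3³ stride-2 plus a 1³ stride-2 projection),
nearest-neighbor upsampling followed by convolution in the decoder, skip
concatenations, and a 1³ convolution to 3 channels with softmax. After
each upsampling the feature map is trimmed on the high-index edge to match
the corresponding encoder map, which makes output extent equal input
extent for any cuboid, cubic or not. The default configuration has
~356 000 parameters (≈1.4 MB in float32); a budget check warns above
1.5 M. Exact layer widths are configurable; the defaults were chosen to
stay light-weight while keeping a receptive field of a few cell diameters.

The implementation is pure numpy: im2col convolutions in float32 with
explicit backward passes and a hand-rolled Adam. This keeps the package
dependency-light and single-device deterministic for a fixed seed;
cross-device bit-equality is not promised (BLAS reduction order may
differ). It is CPU-scale by construction — minutes per training run at the
problem sizes below, not the multi-hour GPU regime of full-resolution
microscopy datasets.

### Training and inference

Training samples cuboids with per-axis extents drawn uniformly from
[cuboid_min, cuboid_max] at uniform origins — slightly varying sizes
improve robustness at cuboid interfaces. Package defaults are 56³–64³ with
batch 7 (the configuration appropriate for full-scale data); the test
suite and acceptance script use 22³–30³ cuboids, batch 2, 400–500 Adam
steps at lr 1e-3 — problem sizes chosen so a full cycle runs in minutes on
one CPU core while still reaching ≈99.9 % voxel accuracy on phantoms.
Fine-tuning is supported by warm-starting from a checkpoint; `steps=0`
returns the initial parameters unchanged. A non-finite loss aborts with a
diagnostic.

Both training and inference zero-pad volumes by `context_pad` (default 8)
voxels per side; the pad is cropped from predictions. Zeros represent the
empty space outside the imaged region. This matters: without it, random
cropping teaches the network that dark voxels at an array edge may be cell
interior, while at inference the thin background shell lies exactly at the
real volume edge — the mismatch produced small confident foreground
islands in the background that inflated instance counts. With matched
padding every retained voxel is predicted with the same kind of context it
was trained on.

Large volumes are processed in overlapping tiles whose core regions
exactly partition the volume (core boundaries at overlap midpoints);
only cores are kept, eliminating seams. Per-voxel argmax converts
probabilities to masks, with ties resolved foreground > membrane >
background.

## Instance stage

Foreground voxels are pre-clustered by a watershed on the negated
Euclidean distance transform, seeded at EDT local maxima at least `h_sep`
(default 3) voxels apart. The EDT is Gaussian-smoothed (σ = 1 voxel)
before seeding and flooding: the voxel-quantized EDT has plateaus of
spurious equal-height maxima on thin or flat regions that otherwise
shatter them into slivers whose mutual contacts fall below any sensible
area threshold. Components left without a seed become their own
supervoxels, so every foreground voxel is labeled.

Supervoxel geometry is counted in voxel faces under 6-connectivity: S_u is
the number of exposed faces of supervoxel u (volume-border faces
included), S_uv the number of faces shared between u and v — faces are the
only voxel geometry consistent with an *area* of contact, and they make
`min_area = 30` mean "30 faces". Two rules then assemble cells, in the
order the rules are stated:

1. **Absorption to fixpoint**: any u with a neighbor v such that
   S_uv > S_u/2 merges into v (candidates applied largest S_uv first, ties
   to smaller ids; S, volumes and contacts are recomputed after each
   merge). This removes watershed fragments mostly engulfed by a neighbor.
2. **Thresholded union**: cells are connected components of the graph
   restricted to edges with S_uv ≥ `min_area`. The predicate is symmetric
   in (u, v), so the partition is independent of processing order — tested
   exhaustively against a brute-force transitive closure.

Instances are renumbered 1..K by descending volume; membrane voxels and
any stray foreground are then assigned to the Euclidean-nearest instance
(ties to the smallest id), leaving true background 0. `min_area` is the
single user-facing hyperparameter: sweeping it moves the instance count
monotonically from the merged-component count to the supervoxel count, and
changing it never touches the semantic stage.

## Evaluation

Per-cell scores match each ground-truth cell to the predicted instance
with maximal voxel intersection (ties to the smaller predicted id; no
overlap scores 0). Averages are taken over ground-truth cells, and "cell
count" fractions use strict thresholds (JI or DSC > 0.7, > 0.5). The
adapted Rand error is 1 minus the F-score of distinct-pair-counting
precision and recall from the pred×gt contingency table restricted to
ground-truth foreground (background excluded); the variation of
information is reported as the conditional entropies H(pred|gt) (split
errors) and H(gt|pred) (merge errors) in bits over the same support. All
metrics are invariant to label permutations.

## Phantom generator

The generator emulates the structure of densely packed tissue, not its
optics. Cells are the Voronoi regions of Poisson-disk seed points (dart
throwing with an exclusion radius near the close-packing estimate,
shrinking on failure) inside the volume minus a background margin; this
gives convex-ish space-filling cells akin to plant/epithelial tissue.
Membranes are all voxels within the stated thickness of an inter-label or
label/background interface; intensity is 1.0 on membranes, 0.0 elsewhere,
plus additive Gaussian noise. Membrane holes — chosen interfaces get a
disk of membrane relabeled as foreground — reproduce the adhesion failure
mode at a controlled size, so the clustering stage can be stressed
independently of the network. Randomness uses numpy's PCG64; fixed seeds
give bit-identical phantoms across platforms.

Defaults (the conditions used throughout the tests): 64³ voxels, 20 cells,
membrane thickness 2, noise σ 0.15 relative to unit membrane contrast,
holes on 10 % of interfaces with radius 1.5 voxels, background margin 2.

What the phantom does *not* model: point-spread blur, anisotropic
sampling, intensity gradients, nuclei channels, non-convex cells, and
texture inside cells. Passing tests therefore demonstrate the correctness
and robustness of the algorithmic pipeline under controlled adhesion and
noise, not segmentation accuracy on real microscopy; on real data the
semantic stage would need longer training on annotated volumes at the
full cuboid sizes.

## Numerical and design notes

* Axis order (Z, Y, X), 0-based, everywhere; HDF5 and multi-page TIFF are
  the two I/O dialects, labels stored as the narrowest unsigned dtype.
* Tile cores partition the volume by construction (asserted), and
  stitching is exact copying — no blending.
* The membrane mask derived from labels is symmetric about interfaces, so
  a requested thickness t yields the two flanking voxel layers for t ≤ 2
  and grows by Euclidean distance beyond.
* Empty class masks give all-ones weights; an empty foreground yields an
  empty supervoxel set and an all-zero instance map; assignment with no
  instances warns and leaves voxels unlabeled.
* Known limitations: instance counts on *trained* (as opposed to ground
  truth) masks can include a few small spurious fragments when the
  semantic stage is trained at desk scale; absorption removes only
  fragments that touch a neighbor. The DBSCAN comparison baseline lives in
  the test suite only.
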