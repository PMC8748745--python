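# memseg3d — two-stage 3D cell instance segmentation for membrane microscopy

Densely packed tissue imaged with a membrane marker poses a hard instance
segmentation problem: cells share thin (1–3 voxel) boundaries, and any
misclassified membrane voxel fuses the foreground masks of neighboring
cells into one clump. `memseg3d` implements a two-stage pipeline aimed at
exactly this failure mode, for researchers segmenting 3D confocal stacks of
plant or animal tissue:

1. **Semantic stage** — a light-weight 3D U-Net (~0.36 M parameters) labels
   every voxel *background*, *membrane*, or *cell foreground*. It is
   trained on variable-size cuboids under a confidence-regularized weighted
   Dice loss: for class mask g, weights w from a reverse distance transform
   emphasize voxels near the membranes, and in the foreground term the
   confidence p is replaced by p/(p+α),

   L = L_fg + L_others,
   L_fg = 1 − 2 Σ r g w / (Σ r² + Σ g²),  r = p/(p+α),  α = 0.1,
   L_others = 1 − 2 Σ p g w / (Σ p² + Σ g²)  (mean over the two other classes).

   Because r < 1 even at p = 1, a perfect prediction retains a small
   residual penalty (0.004525 at α = 0.1), and the gradient is steep for
   low-confidence foreground — the network learns to *not* claim uncertain
   voxels near membranes. The closed-form gradients of both terms are
   implemented and power the (pure numpy) training loop.

2. **Instance stage** — operating on the three masks only, a watershed on
   the smoothed Euclidean distance transform pre-clusters the foreground
   into supervoxels; supervoxels form a graph with surface areas S_u and
   touching areas S_uv counted in voxel faces (6-connectivity). Supervoxels
   engulfed by a neighbor (S_uv > S_u/2) are absorbed, then cells are the
   connected components over edges with S_uv ≥ `min_area` — the pipeline's
   **single hyperparameter** (default 30 faces; it is the largest membrane
   hole that will still be cut). Remaining membrane and stray foreground
   voxels join their nearest cell.

A synthetic phantom generator (Voronoi cells, bright membranes, noise,
membrane holes that adhere neighboring cells) provides voxel-perfect ground
truth, so training, clustering and evaluation are all testable without
external data. Evaluation implements per-cell Jaccard/Dice with
max-overlap matching, the adapted Rand error, and the split/merge
variation-of-information decomposition.

## Worked example

```python
import memseg3d as m

# two training phantoms and one held-out phantom, 64^3, 20 cells each
train = [m.generate_phantom(m.PhantomSpec(seed=s)) for s in (11, 12)]
image, truth = m.generate_phantom(m.PhantomSpec(seed=99))

cfg = m.TrainConfig(cuboid_min=(22, 22, 22), cuboid_max=(30, 30, 30),
                    batch_size=2, steps=400)
fit = m.VolumeSegmenter(train, train_config=cfg).fit()
result = fit.segment(image, min_area=30)
report = m.evaluate(result.labels, truth)
print(f"instances: {result.n_instances} (truth 20)")
print(f"Avg JI {report.avg_ji:.3f}  ARE {report.are:.4f}  "
      f"VOI split/merge {report.voi_split:.3f}/{report.voi_merge:.3f}")
```

Output from the run above (seeded; ~6 min on one CPU core):

```
instances: 22 (truth 20)
Avg JI 0.990  ARE 0.0065  VOI split/merge 0.060/0.037
```

22 instances means the 20 true cells were recovered plus two small spurious
fragments; an Avg JI of 0.99 says the matched cells overlap their ground
truth almost voxel-perfectly, and the near-zero ARE/VOI confirm there are
essentially no split or merge errors. The same pipeline is available from
the shell: `memseg3d simulate | train | segment | evaluate` (see
`memseg3d --help`), where `segment --min-area` exposes the one tunable knob
without retraining.

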