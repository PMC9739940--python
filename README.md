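# mixseedling

Point-cloud phenotyping of melon-type seedlings from single top-down
depth-camera views: sensor-noise filtering, stem/leaf semantic and instance
segmentation, occluded-leaf completion with a point-mixer network, and
leaf-area measurement.

Single-view depth scans of seedlings suffer from two problems that corrupt
leaf-area estimates: *hover points* (spurious returns strung along the
viewing ray at leaf edges) and *occlusion* (leaves hiding parts of other
leaves).  This package addresses both.  A neighborhood-space-constraint
filter deletes a point when either the mean distance `D` to its `N` nearest
neighbors reaches `d` or the angle `W` between its local least-squares
surface normal and the viewing axis reaches `c` (defaults `N = 12`,
`d = 3.4 mm`, `c = 60°`) — hover points fail the angle test, outliers the
distance test, while thin stems and leaf surfaces pass both.  A
U-shaped encoder–decoder network whose stages interleave k-NN neighborhood
aggregation with *point-mixer* blocks,

    Fc = Fs + MLP(LayerNorm(Fs))          (mixing within a group)
    Fo = Fc + T(MLP(T(LayerNorm(Fc))))    (mixing across groups)

segments organs (softmax cross-entropy), embeds instances (discriminative
pull loss `Ls = (1/I) Σᵢ (1/Nᵢ) Σⱼ max(0, ‖cᵢ − fⱼ‖ − δs)²` + center
regularization, clustered by mean shift) and completes occluded leaves with
a progressive 256→512→1024→2048 decoder trained on the summed per-stage
Chamfer distance

    CD(S₁,S₂) = ½ [ (1/|S₁|) Σₓ min_y ‖x−y‖ + (1/|S₂|) Σ_y min_x ‖x−y‖ ].

Completion training data is self-supervised: from each intact leaf, the
fraction of points (15/25/50%) nearest one of 14 cube viewpoints (8 corners
+ 6 face centers) is removed, mimicking inter-leaf occlusion.  Completed
leaves are PCA-projected, Delaunay-triangulated and lifted to measure
surface area, which is correlated (R², MSE/RMSE) against ground truth.

Everything runs on synthetic seedling scenes with exact analytic leaf areas
(`mixseedling.synth`), so the whole pipeline is testable end-to-end on one
CPU with no downloads.  The network runs on an in-repo numpy autodiff
engine; all runs are seeded and bit-reproducible.

## Worked example

```python
import numpy as np
from mixseedling import (SeedlingSpec, NoiseSpec, generate_seedling,
                         add_scene_background, add_sensor_noise,
                         passthrough_filter, remove_ground_and_tray,
                         neighborhood_filter, leaf_area)
from mixseedling.preprocess import estimate_ground_plane

spec = SeedlingSpec(n_leaves=2, leaf_radius=0.04, seed=0)
plant = generate_seedling(spec)
scene = add_sensor_noise(add_scene_background(plant, seed=0), NoiseSpec(seed=0))
print(f"scene: {len(scene)} points ({int(scene.noise_mask.sum())} injected noise)")

crop = passthrough_filter(scene)
cut = remove_ground_and_tray(crop, estimate_ground_plane(crop))
kept, removed = neighborhood_filter(cut)
print(f"after filtering: {len(kept)} points "
      f"({int(kept.noise_mask.sum())} noise survivors, "
      f"{(kept.semantic >= 0).sum()}/{(scene.semantic >= 0).sum()} plant points kept)")

leaf = kept.select(kept.instance == 1)
est = leaf_area(leaf)
truth = plant.metadata["leaf_areas"][1]
print(f"leaf 1 area: {est.area * 1e4:.2f} cm^2 estimated "
      f"vs {truth * 1e4:.2f} cm^2 analytic ({100 * (est.area / truth - 1):+.1f}%)")
```

Output:

```
scene: 15291 points (1111 injected noise)
after filtering: 4443 points (0 noise survivors, 4443/4500 plant points kept)
leaf 1 area: 30.92 cm^2 estimated vs 32.16 cm^2 analytic (-3.9%)
```

The scene starts as ~15k points (plant + ground + tray + injected hover
chains and outliers).  Cropping, ground/tray removal and the neighborhood
filter reduce it to plant-only points: here every injected noise point is
gone and 98.7% of true plant points survive.  The triangulated leaf area
lands within 4% of the analytic truth — a small systematic underestimate
from the sampled leaf boundary, which cancels in cohort-level correlations.

Training is equally scriptable — see `mixseedling.train` (`train_semantic`,
`train_completion`, `run_pipeline`) or the CLI:

```bash
mixseedling simulate scenes/ --n-scenes 5 --seed 0
mixseedling preprocess --in scenes/scene_000.ply --out plant.ply
mixseedling train plants/ seg.npz --task semantic --epochs 30
mixseedling infer seg.npz --in plant.ply --out labeled.ply
mixseedling evaluate labeled.ply truth.ply
```

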