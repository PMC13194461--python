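# seedling3d

3D phenotyping of eggplant (*Solanum melongena*) seedlings at the
cotyledon stage from labeled point clouds.

Seedlings grown in trays and reconstructed by multi-view stereo arrive as
dense point clouds in which the cultivation tray contributes more than
75 % of the points. `seedling3d` implements the full analysis chain that
turns such scenes into per-plant traits:

1. **Background purification** — remove every tray point (semantic
   label 0) before any learning, shrinking the data several-fold;
2. **Semantic segmentation** — a hierarchical point-cloud network
   (PointNet++-style set abstraction / feature propagation) labels each
   point stem or leaf, with four toggleable improvements: multi-scale
   residual convolution blocks (kernel sizes 1/3/5 along the sampled point
   sequence), squeeze-and-excitation channel attention, a global context
   module, and an improved feature-propagation layer;
3. **Instance segmentation** — per-class DBSCAN
   (`eps = α·eps_est`, α = 0.8 for stems and 1.2 for leaves,
   `min_samples` = 5) plus stem–leaf assembly separates the individual
   plants;
4. **Trait estimation** on the size-restored cloud, per plant and
   timepoint:
   * plant height `H = z_max − z_min`,
   * stem diameter `D = 2·r̄` from 5 minimum-enclosing-circle fits of the
     stem slab just above the soil (Welzl's algorithm),
   * cotyledon inclination `θ = arccos|n⃗·ẑ|` from RANSAC plane fits
     (the complement `90° − θ` is reported alongside),
   * cotyledon area `A = Σ S_j` from a ball-pivoting mesh (0.2 cm ball)
     summed with Heron's formula.

Because no public dataset of labeled seedling trays exists, the package
ships a first-class synthetic generator: 25 cm × 25 cm trays with a 6 × 6
seedling grid at 41 mm pitch, growth-dependent morphology over 24–120 h,
and known ground truth for every trait — so every stage is testable and
the headline numbers are reproducible from scratch.

The network and its training loop run on a small numpy reverse-mode
autodiff engine included in the package; no GPU or deep-learning framework
is required.

## Worked example

```python
import numpy as np
from seedling3d.synthetic import make_tray_scene
from seedling3d.preprocess import purify_background
from seedling3d.segmenter import PlantClusterer
from seedling3d.phenotype import measure_plant

scene, truths = make_tray_scene(t=72.0, seed=0)   # one tray, 72 h
print(scene.n_points)                              # 226766
print(100 * np.mean(scene.sem_label == 0))         # 85.4  (% tray points)

plants = purify_background(scene)
print(plants.n_points)                             # 33016

clusterer = PlantClusterer()                       # per-class DBSCAN
clusterer.fit(plants)
print(clusterer.n_instances_)                      # 36

plant = clusterer.instances_[0]
idx = plant.point_idx
rec = measure_plant(plants.coords[idx], plants.sem_label[idx],
                    plants.normals[idx], plant_id=1, timepoint_h=72.0)
print(rec.height_cm, rec.stem_diam_cm, rec.incl_deg, rec.area_cm2)
# 2.01 cm   0.125 cm   41.0 deg   1.88 cm2
```

The generator's truth for this plant is H = 2.02 cm, D = 0.101 cm,
θ = 40.9°, A = 1.99 cm². Height, inclination and area recover closely;
the stem diameter is biased high because a minimum enclosing circle is a
max-type fit — surface noise of 0.01 cm inflates a 0.05 cm radius by
roughly one noise standard deviation (see `docs/methods.md`).

Training the segmentation network end-to-end (classes stem/leaf on
purified scenes, 2049 points per scene, Adam with step decay):

```python
from seedling3d.segmenter import PointCloudSegmenter
seg = PointCloudSegmenter(epochs=30, batch_size=8)
seg.fit(train_scenes, val_scenes=val_scenes)
print(seg.evaluate(test_scenes).miou)
```

A command-line pipeline covers the same flow
(`seedling3d synth / preprocess / partition / train / eval / instance /
phenotype / run-all / ablate`), driven by one YAML config and a global
seed.

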