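# dermoscan

Skin-nevus monitoring from ordinary body photographs.

Melanoma frequently develops from changing pigmented nevi (moles), and the
clinical warning signs — **A**symmetry, **B**order irregularity, **C**olor
variegation, **D**iameter > 6 mm, **E**volution — are visible long before a
clinical visit happens. `dermoscan` implements a complete screening
pipeline that takes a photo of a person (for example from a camera mounted
over a mirror), finds candidate skin marks, and classifies each one as
benign or suspicious:

1. **Key-point detection** (`dermoscan.scalespace`) — a SIFT-style
   detector: Gaussian scale space `L(x, y, σ) = G(σ) * I`,
   Difference-of-Gaussian stack `D = L(kσ) − L(σ)`, 26-neighbour extrema,
   sub-pixel Taylor localization, low-contrast rejection
   (`|D(x̂)| < t` on [0,1] intensities) and edge rejection via the spatial
   Hessian ratio test `tr(H)²/det(H) ≥ (r+1)²/r`, orientation histograms
   with the 80 % multi-peak rule, and 128-D gradient descriptors.
2. **Key-point filtering** (`dermoscan.kpfilter`) — removes points that
   match stored empty-room reference photos (position + color), points off
   a configurable skin-tone palette, and points on long thin structures.
3. **Cluster extraction** (`dermoscan.clusterer`) — crops a 15 %w × 15 %h
   window around each survivor, simplifies it (grayscale
   `C = ⌊(R+G+B)/3⌋`, gamma correction `C → 255·(C/255)^γ`, contrast
   stretch `C → F·(C−128)+128` with `F = 259(ω+255)/(255(259−ω))`), grows
   the same-intensity region around the key point by iterative flood
   fill, rejects background-dominated windows, crops to the region's
   bounding box, restores the original colors and resizes to a uniform
   64×64 cluster.
4. **Histogram screening** (`dermoscan.screening`) — compares each
   cluster's gray/R/G/B histograms against a stored nevus database by
   histogram intersection; plain skin is skipped, candidate nevi are
   blurred with the 3×3 binomial kernel (1/16)[1 2 1; 2 4 2; 1 2 1] and
   forwarded.
5. **Classification** (`dermoscan.cnn`) — a from-scratch convolutional
   neural network (valid convolutions, 3×3 max/weighted-color-max pooling,
   fully connected tanh layers `y_k = tanh(Σ_j w_jk x_j)`) trained by
   chain-rule backpropagation on mean-squared error. Exposed as the
   scikit-learn-compatible estimator `CnnClassifier`.

A seeded synthetic generator (`dermoscan.synthgen`) renders skin scenes
with ground-truth nevus masks parameterized by the A–E criteria, so every
stage is verifiable offline, and `dermoscan.pipeline` ties the stages
together, computes the standard confusion-matrix quality measures
(accuracy, precision, sensitivity, specificity, fall-out, FNR, NPV, FDR,
F-measure) and runs train/test experiments. An optional loader ingests the
PH2 dermoscopy dataset layout (200 melanocytic lesion images) when a user
has downloaded it.

## Worked example

```python
import dermoscan as dm

# 1. labeled synthetic clusters: 100 benign + 100 suspicious
dataset = dm.synthgen.make_cluster_dataset(n_per_class=100, seed=0)
x, y = dm.pipeline.dataset_to_arrays(dataset)

# 2. train the CNN (scikit-learn estimator surface)
clf = dm.CnnClassifier(epochs=30, random_state=0).fit(x, y)
print(f"final epoch loss: {clf.loss_history_[-1]:.4f}")

# 3. analyze a scene with one suspicious nevus
scene = dm.synthgen.make_scene(384, 288, n_nevi=1, clutter=3, seed=0,
                               force_label="suspicious")
photos = dm.synthgen.make_background_photos(scene, 2, lighting_jitter=3, seed=0)
ref = dm.kpfilter.build_background_reference(photos)
db = dm.pipeline.default_nevus_database(seed=0)
report = dm.analyze_image(scene.image, clf, ref, db)
print("alert:", report.alert)
print("stages:", report.stage_counts)
```

Output:

```
final epoch loss: 0.0036
alert: True
stages: {'keypoints': 9, 'after_background': 1, 'after_palette': 1,
         'after_elongated': 1, 'clusters': 1, 'forwarded': 1}
```

The loss history shows the network converging on the balanced cluster set;
of the nine key points found in the scene, the background filter removes
the eight belonging to wall clutter, the survivor on the rendered nevus
passes the palette and shape filters, is clustered, forwarded by the
histogram screen, and classified suspicious — which raises the alert.

The same workflow is available from the shell:

```bash
dermoscan simulate --out data --seed 0
dermoscan train --data data/clusters --model model.json
dermoscan detect --image data/scene_000.png --model model.json --report report.json
dermoscan experiment --n-per-class 100 --seed 0
```

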