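# fluorostress

Early detection of heat and water stress in strawberry plants
(*Fragaria × ananassa*) from VNIR fluorescence hyperspectral images.

Heat and drought depress photosynthesis long before visible symptoms
appear, and the damage shows up first in leaf chlorophyll: absorption
weakens at the chlorophyll-a (676 nm) and chlorophyll-b (635 nm) bands
and the red edge — the steep reflectance rise between ~690 and
~750 nm — retreats toward shorter wavelengths. `fluorostress`
implements a three-phase workflow that turns a hyperspectral cube of a
potted plant into a stress-stage call (controlled / stressed /
recovered):

1. **Leaf segmentation** — the NIR band (810 nm) is quantized and a
   binary leaf mask is found by *fast two-dimensional Otsu
   thresholding*: the joint histogram of pixel gray level and local
   window-mean level is searched for the threshold pair `(s, t)`
   maximizing the between-class scatter trace, with summed-area
   recurrences bringing the search to O(L²). The 2D criterion is more
   noise-robust than plain Otsu because isolated bright or dark pixels
   fall in the off-diagonal histogram quadrants and are ignored.
2. **Index extraction** — the mean reflectance spectrum over the leaf
   region of interest feeds eight chlorophyll-fluorescence indices
   (`R_x` = reflectance at the band nearest *x* nm):

   | index | formula |
   |---|---|
   | PSNDa | (R810 − R676) / (R810 + R676) |
   | PSNDb | (R810 − R635) / (R810 + R635) |
   | PSSRa | R810 / R676 |
   | PSSRb | R810 / R635 |
   | CI-RedEdge | R810 / R700 − 1 |
   | NDRE | (R790 − R720) / (R790 + R720) |
   | SR | R810 / R675 |
   | RVSI | (R714 + R752)/2 − R733 |

3. **Modelling** — a seven-classifier harness (RBF and polynomial SVM,
   bagged trees, random forest, AdaBoost, gradient boosting, XGBoost)
   is trained on a stratified 75/25 split, with impurity-based feature
   scoring (Gini decrease weighted by node-reach probability) to rank
   the indices and per-class precision/recall/F1 reports.

Because instrument cubes of this kind are rarely shared, the package
ships a first-class synthetic generator: 128-band cubes on the
397–1003 nm grid with leaf-shaped blobs whose spectra carry
class-conditional chlorophyll dips and red-edge positions. Every stage
of the pipeline is tested against it.

## Worked example

```python
from fluorostress import SceneParams, benchmark, benchmark_frame, make_dataset

table = make_dataset(SceneParams(seed=0))   # 131 samples: 45/43/43
frame = benchmark_frame(benchmark(table, seeds=(0,)))
print(frame.pivot_table(index="classifier", columns="feature_set", values="accuracy"))
```

```
feature_set         all  selected
classifier
adaboost           0.91      0.91
bagged_tree        0.94      0.94
gradient_boosting  0.94      0.94
random_forest      0.97      0.94
svm_poly           0.97      0.94
svm_rbf            1.00      0.97
xg_boosting        0.94      0.94
```

Each cell is the overall accuracy on the held-out 25% (33 samples) for
one classifier, using either all eight indices or the four selective
indicators (RVSI, PSNDb, PSSRb, CI-RedEdge). On this synthetic dataset
the classes are separable enough that most models land in the
0.90–0.97 band; the selected-4 column shows how much of that signal the
reduced feature set retains. `examples/` contains one narrative script
per capability (segmentation, index extraction, feature scoring,
benchmarking, the full pipeline), and the `fluorostress` CLI exposes
the same stages as `synth`, `mask`, `extract`, `score`, `classify` and
`run` subcommands.

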