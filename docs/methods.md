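# Methods

## Scope and data model

The package stages VNIR fluorescence-reflectance cubes of potted
strawberry plants into three classes — controlled (chamber-grown,
watered), stressed (after ~6 days at 35 °C without water) and recovered
(after a ~15-day return to control conditions). A cube is a
`rows × cols × bands` float array with a strictly increasing wavelength
vector in nm; the emulated instrument grid is 128 bands over
397–1003 nm (≈4.77 nm spacing). Values are treated as unitless
reflectance in [0, 1]; whether the physical quantity behind a
fluorescence-filtered sensor is radiance, reflectance or fluorescence
intensity is irrelevant to the method, because seven of the eight
indices are ratios and the eighth (RVSI) only requires a consistent
scale across bands. Integer digital-number cubes are therefore
canonicalised on read (header scale factor if present, else the dtype
maximum), since RVSI is homogeneous of degree one.

## Segmentation

The mask is computed from the band nearest 810 nm: leaves are bright
and the background dark in the NIR, so this projection has maximal
contrast regardless of pigment status. The band is min–max quantized to
L = 256 levels (configurable; a constant band maps to zeros). For each
pixel the mean level of the w × w window (default w = 3, edge
replication, integer arithmetic with round-half-up so the histogram is
exactly reproducible) gives the second coordinate of the classical 2D
Otsu joint histogram p(i, j). The threshold pair maximizes

    tr S_b(s, t) = w0 ‖μ0 − μT‖² + w1 ‖μ1 − μT‖²

where class 0 is the quadrant i ≤ s, j ≤ t, class 1 the quadrant
i > s, j > t, and the off-diagonal quadrants (edge/noise pixels, whose
pixel level and neighbourhood mean disagree) are excluded — this is
what buys noise robustness over 1D Otsu. All quadrant masses and means
come from three summed-area tables, so the full search is O(L²) after
the histogram; an exhaustive O(L⁴) scan is retained as the test oracle
and the equivalence of the two argmaxes on random small-L images is the
module's central correctness property. Ties take the lexicographically
smallest (s, t). A pixel is leaf iff its level > s *and* its window
mean > t (an `invert` flag handles dark-foreground scenes); small-object
removal and hole filling exist but are off by default since the method
itself does not require them.

Open choices resolved here: the projection band (810 nm), window size
(3), and L (256) are all exposed as configuration, since nothing in the
workflow constrains them beyond the NIR-contrast argument.

## Indices

Each requested wavelength resolves to the nearest band centre, ties to
the lower wavelength; a lookup further than 5 nm from its target logs a
warning (the emulated grid is ~4.7 nm). On that grid 675 and 676 nm
resolve to the same band, so SR and PSSRa coincide numerically; both
are kept as distinct features because they are distinct constructs in
the vegetation-index literature. A zero denominator yields NaN and a
logged event rather than an exception, so per-pixel maps never abort;
NaN rows are dropped (with a logged count) when the feature table is
assembled, rather than imputed. The stated ranges follow from the
formulas: normalized differences in [−1, 1], simple ratios in [0, ∞),
CI-RedEdge in [−1, ∞), RVSI in [−1, 1] for unit-range reflectance.

The per-sample feature vector is the index of the ROI-*mean* spectrum,
not the mean of per-pixel indices — one vector per imaged plant, which
is what the classifier stage consumes. The two are not equal for ratio
forms (a two-pixel counterexample is frozen in the tests); per-pixel
index maps are provided for visualization.

## Feature scoring and correlations

The score of feature f is the sum over tree nodes splitting on f of
(n_node / n_total) · ΔGini — the impurity decrease weighted by the
probability of reaching the node — normalised to sum to 1. The impurity
is Gini (the conventional default for classification trees). Because a
single tree's importances are unstable at n ≈ 131, the default score
averages 100 trees fitted on bootstrap resamples drawn from a seeded
generator; a single-tree mode (no bootstrap) is retained because its
value on a six-sample table can be verified by hand, and the traversal
is cross-checked against the tree library's own normalised importances.
Top-k selection is deterministic: ties at the cut break by the
canonical feature order, logged.

Stage-wise correlation matrices use Pearson r with a two-sided p < 0.05
flag from the t transform; no multiple-testing correction is applied,
matching standard exploratory practice for index correlation heat maps.
Constant columns yield NaN entries with a warning.

## Classifier harness

Seven classifiers in three families; hyperparameters are the underlying
libraries' documented defaults, frozen in `DEFAULT_HYPERPARAMS` and
echoed verbatim in every report so a result is reproducible from the
report alone. Two deliberate deviations from bare defaults: SVMs are
wrapped in one-vs-rest with train-fitted z-scoring (kernels are
scale-sensitive; trees are not and get none), and the XGBoost-style
model uses exact split enumeration rather than histogram quantization —
at eight features and ~100 samples the histogram sketch places cuts at
class-edge data values instead of gap midpoints, which degrades
behaviour near class boundaries for no speed benefit at this size.
Without the optional xgboost dependency the kind falls back to
histogram gradient boosting with a logged notice.

The split is a single stratified 75/25 partition seeded for exact
reproducibility (per-class train counts within one sample of the exact
fraction). Metrics are per-class precision, recall and F1 plus overall
accuracy, all recomputed from the confusion matrix, with the 0/0 → 0
convention for precision and F1 of never-predicted classes. Wall time
is recorded on reports but excluded from the CSV outputs so that a
rerun under an identical configuration is bit-identical.

## Synthetic generator

A noise-free leaf spectrum is

    R(λ) = [floor + (plateau − floor) · sigmoid((λ − c)/w)]
           · (1 − d676 · g(λ; 676, 15) − d635 · g(λ; 635, 15))

with g a unit-height Gaussian (σ = 15 nm) and multiplicative N(0,
noise_sd) band noise, clipped to [0, 1]. Class archetypes are ordered
controlled ≥ recovered ≥ stressed in both dip depth and red-edge
position (healthy leaves hold more chlorophyll), and recovered sits
deliberately nearer stressed so those two classes overlap — the regime
in which stress staging is genuinely hard and the one interesting for
the classifiers. The ordering is enforced as a validation rule.
Between-plant variability is Gaussian jitter on each parameter
(committed absolute s.d.s); per-pixel jitter within a leaf blob is 20%
of that. Scenes are 128 × 128 by default (full 502 × 500 available via
`SceneParams.shape`) with elliptical leaf blobs on a flat dark
background (reflectance 0.04), and class counts default to 45/43/43 —
131 samples.

The default effect sizes and jitter were calibrated once, before being
committed, so that all-index random-forest accuracy on the default
dataset lands in the 0.90–0.97 band across seeds — a deliberately
non-saturated operating point where feature selection and classifier
family still matter. Two dials support sensitivity analysis:
`class_params_with_gap(gap)` scales the controlled-vs-stressed contrast
(downstream accuracy must rise monotonically with it), and setting the
recovered archetype equal to the stressed one collapses their margin to
chance — a controllable limit of the stressed/recovered confusability.

Dataset generation has two modes. `pipeline` renders every cube and
runs segmentation → ROI mean → indices (dropping samples whose
segmentation fails, with a logged id). `fast`, the default, draws one
spectrum per sample directly, with band noise shrunk by √400 to emulate
averaging over a ~400-pixel ROI; between-sample parameter jitter, which
does not average out, is unchanged. The fast mode is what the tests and
the acceptance script use for classifier-level questions; the pipeline
mode is exercised at smaller counts.

What the generator does *not* emulate: physically based leaf optics
(no radiative-transfer model), fluorescence emission physics, sensor
smile/striping, illumination gradients, specular highlights, or
temporal stress dynamics. Passing tests on synthetic data therefore
demonstrate that the pipeline machinery is correct and that the
workflow recovers class structure of the assumed spectral form — not
that any particular accuracy will transfer to real plants, whose
spectral effect sizes are unknown here.

## Numerical and problem-size choices

Histogram construction and window means use exact integer arithmetic;
the 2D-Otsu oracle equivalence is asserted exactly, the index
hand-checks at 1e-12. Oracle tests use L ≤ 16 so the O(L⁴) brute force
stays fast. Test and acceptance runs use the default 131-sample fast
datasets (10 independent seeds for accuracy means, 5 for the collapse
and gap checks) and 10 rendered scenes for segmentation scoring —
sizes chosen to estimate the relevant means stably while keeping the
whole suite quick on a single CPU. The determinism check reruns the
pipeline on a reduced configuration (43 samples, two classifiers) and
compares artifact bytes.

## Known limitations

- The "fast" 2D Otsu is the classical diagonal-quadrant criterion with
  integral-image acceleration; published accelerations differ in
  detail, and any algorithm returning the same argmax is equivalent
  here (that equivalence, not a particular recurrence, is tested).
- Ensemble feature scores are permutation-equivariant only up to the
  split-search tie-breaking noise of individual bootstrap trees; the
  single-tree mode is exactly equivariant.
- The ENVI reader supports the common interleaves and dtypes with an
  ASCII header; exotic header features (BIL with header offsets,
  spectral subsetting) are out of scope.
- Index values are only as meaningful as the reflectance calibration of
  the input cube; no radiometric correction is performed.
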