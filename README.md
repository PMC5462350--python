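# leafjdsr

Coarse-to-fine plant species recognition from leaf photographs using the
Jaccard metric on binary edge-orientation images and a Jaccard-distance
weighted sparse representation (JDSR).

Identifying a plant species from a single leaf photograph is a standard task
in ecological monitoring and botany. Sparse-representation classifiers
(SRC) handle it well but scale poorly: every query requires an
ℓ₁-regularized solve over *all* training images. `leafjdsr` implements a
two-stage alternative for botanists and computer-vision researchers working
with registered leaf silhouettes:

1. **Coarse stage.** Every leaf is reduced to a 32×16 binary edge-orientation
   image (grayscale → threshold-30 background segmentation → long-axis
   alignment → crop/resize → Canny edges), flattened to a vector of
   dimension D = 512. For a probe `y`, the average Jaccard coefficient

   J(y, Xᵢ) = (1/nᵢ) Σ_{xⱼ∈Xᵢ} J(y, xⱼ),  J(a,b) = M₁₁ / (M₁₁ + M₀₁ + M₁₀)

   is computed per class, and only the S = ⌊C/2⌋ top-ranked classes survive.

2. **Fine stage.** The surviving training vectors form a dictionary
   G ∈ ℝ^{D×m}, and the probe is approximated by solving the weighted
   ℓ₂–ℓ₁ problem

   min_A ‖GA − y‖₂² + μ‖W′A‖₁,  diag(W′) = [d_J(y,x₁), …, d_J(y,x_m)],

   with d_J = 1 − J the Jaccard distance, so dissimilar atoms are penalized
   more. The probe is assigned to the class whose atoms reconstruct it with
   the smallest ℓ₂ residual eᵢ = ‖y − Σⱼ aᵢⱼxᵢⱼ‖₂.

The solver is cyclic coordinate descent on the substituted standard LASSO
(columns scaled by 1/wⱼ), with a LARS backend as an alternative. A
parametric synthetic-leaf generator (polar silhouettes with lobes,
serration, veins, and controllable noise) makes the full pipeline testable
without any external leaf database.

## Worked example

```python
import numpy as np
import leafjdsr as lj

# two binary vectors
v1 = np.array([1, 0, 0, 1, 0, 0, 1, 1, 0, 0])
v2 = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
c = lj.jaccard_counts(v1, v2)
print(c.m11, c.m01, c.m10)                 # 2 3 2
print(round(lj.jaccard_coefficient(v1, v2), 4))  # 0.2857
print(round(lj.jaccard_distance(v1, v2), 4))     # 0.7143

# a synthetic 6-species benchmark through the full pipeline
ds = lj.make_dataset(C=6, per_class=10, separation=0.5, noise="low", seed=42)
cfg = lj.PreprocessConfig()          # threshold 0.12, background threshold 30
X = np.stack([lj.vectorize(lj.preprocess_image(im, cfg)) for im in ds.images])
y = np.array(ds.labels, dtype=object)

from leafjdsr.pipeline import cross_validate
report = cross_validate(X, y, folds=5, repeats=1, seed=1)
print(round(report.macro_rate, 1))   # 98.3
```

The first block reproduces the textbook Jaccard counts (M₁₁=2, M₀₁=3,
M₁₀=2) and the resulting coefficient 2/7 ≈ 0.2857 and distance 5/7 ≈ 0.7143.
The second runs stratified 5-fold cross-validation of the full coarse-to-fine
classifier on a 6-species synthetic benchmark; the printed number is the
macro-averaged recognition rate in percent (mean of per-class rates).

The classifier is a scikit-learn estimator and composes with sklearn
pipelines:

```python
from sklearn.pipeline import Pipeline
pipe = Pipeline([("orient", lj.OrientationTransformer()),
                 ("jdsr", lj.JDSRClassifier(mu=1e-3))])
pipe.fit(ds.images, y)
pipe.predict(ds.images[:3])
```

A `leafjdsr` CLI wraps the same functionality (`leafjdsr synth`,
`leafjdsr jaccard`, `leafjdsr classify`, `leafjdsr evaluate`).

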