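# Methods

## Model

`leafjdsr` classifies a leaf photograph by comparing binary edge-orientation
images pixel-by-pixel. The representation is deliberately **not**
transformation-invariant: instead of invariant descriptors, every image is
registered into a common frame (long axis vertical, bounding box scaled to
32×16), after which the Jaccard metric on the binary edge maps is meaningful.

**Coarse stage.** For probe `y` and training classes X₁…X_C, the per-class
average Jaccard coefficient J(y, Xᵢ) ranks the classes; only the top
S = ⌊C/2⌋ survive (configurable). The Jaccard coefficient ignores positions
where both images are 0, which matters because edge maps are ~80–90%
background. Exclusion operates on whole classes: every atom of an excluded
class is removed from the fine stage.

**Fine stage.** The shortlisted training vectors are concatenated column-wise
into a dictionary G ∈ ℝ^{512×m} (class blocks in shortlist order, input
order within a class, binary columns used as-is). The weighted problem

    min_A ‖GA − y‖₂² + μ‖W′A‖₁,    W′ = diag(d_J(y, x₁), …, d_J(y, x_m)),

is solved and the probe assigned to argminᵢ ‖y − Σⱼ aᵢⱼ xᵢⱼ‖₂. Unit weights
recover classical SRC; the closed form (GᵀG + μI)⁻¹Gᵀy solves the *ridge*
(ℓ₂-penalized) problem, not the ℓ₁ one, and is shipped only as the
diagnostic `ridge_closed_form`, never in the decision path.

## Solver

The weighted problem reduces to a standard LASSO via B = W′A (column j of G
scaled by 1/wⱼ). The default backend is cyclic coordinate descent on the
Gram matrix K = G̃ᵀG̃ with the correlation vector maintained incrementally,
so a sweep costs O(m²) independent of D; the inner loop is JIT-compiled with
numba when available, with an identical pure-numpy loop as fallback and
correctness reference. A LARS-homotopy backend (`backend="lars"`, via
scikit-learn's `LassoLars` matched to the no-½ objective) provides exact
piecewise-linear-path solutions and serves as a cross-check.

Numerical choices:

- The objective is written without ½ on the quadratic term, so the
  orthonormal-design closed form is αⱼ = soft(gⱼᵀy, μwⱼ/2). All oracles in
  the test suite use this convention.
- **Stopping rule**: iteration ends when the per-sweep objective decrease is
  ≤ tol·max(objective, 1) with tol = 10⁻⁶ — relative for objectives above 1,
  absolute below. A purely relative rule stalls in the overcomplete regime,
  where the optimal objective is nearly 0 and coordinate descent crawls
  along nearly flat ℓ₁-ball faces.
- **Weight floor**: a raw Jaccard distance of 0 (atom identical to the probe)
  would make the substitution singular; weights are floored at 10⁻⁸. The
  unpenalized identical atom dominates the solution regardless.
- μ < 0 is rejected; μ = 0 yields the least-squares limit. Non-convergence
  at `max_iter` (10⁴ sweeps) warns and returns the best iterate.
- Ties in the smallest-residual decision go to the lexicographically
  smallest class label; shortlist ties at the S-th rank are broken by
  (−score, label) stable sort. Both make results platform-independent.

## Preprocessing

Defaults: luminance grayscale (0.2989 R + 0.5870 G + 0.1140 B, unrounded);
background threshold 30 (gray < 30 is background — leaf photographs are
assumed to sit on a simple dark background); Gaussian σ = 1.0; Canny
sensitivity threshold r = 0.12 applied to the max-normalized gradient
magnitude with hysteresis low threshold r/2.5; histogram equalization on;
long-axis alignment on. Alignment rotates about the foreground centroid so
the principal second-moment axis is vertical; the 180° ambiguity is resolved
by placing the mass-heavier half at the bottom, and a nearly isotropic
foreground (moment ratio < 1.05) is left unrotated with a warning.

Size normalization is bounding-box crop + bilinear resample to 32×16 with
hard re-binarization of the mask. A consequence worth knowing: the crop
erases absolute scale *and* aspect ratio, so species can only be separated
by bbox-invariant characters (lobes, margin serration, apex notches, vein
texture). The alternative "fourstep" extractor (Gaussian smoothing →
Roberts-cross gradient → 3×3 dilation → non-maximum suppression → single
threshold) is retained for fidelity to that enumerated procedure; "canny"
is the default.

## Synthetic data

The generator renders silhouettes from a radial polar profile: an ellipse
modulated by sinusoidal lobes (count/depth), an apex notch for cordate
shapes, and high-frequency margin serration; a midrib and chevron lateral
veins are drawn darker than the blade. Background gray is a uniform 14, the
blade ≥ 40, so threshold-30 segmentation is exact at zero noise. Noise
presets: `low` (2° rotation jitter, 2% scale jitter, 0.2% pixel corruption),
`med` (5°, 5%, 10% occlusion probability, 1% corruption, illumination
drift), `high` (15°, 10%, 30%, 3%). Pixel corruption is applied inside the
blade (emulating damaged/diseased leaves) so that stray background specks do
not destabilize the bounding-box crop. Zero-magnitude noise components
consume no randomness, making zero-noise classes byte-identical and every
dataset a pure function of its seed.

`make_dataset(C, per_class, separation, noise, seed)` draws class shapes by
blending distinct species presets toward a common reference ellipse;
`separation=0` collapses all classes onto one shape (accuracy ≈ chance),
`separation=1` uses the full presets. Because of the bbox-normalization
point above, the presets differ chiefly in lobe structure, serration and
vein density rather than aspect ratio.

What the generator does **not** emulate: photographic texture and color
variation, petioles and damage at the margin scale, perspective distortion,
natural vein topology, or inter-species similarity structure of a real
flora. Passing benchmarks on this data therefore demonstrates correctness
and internal consistency of the pipeline, not field accuracy on real leaf
databases.

## Benchmark scales and defaults

The shipped benchmarks are sized for a single CPU: the 6-species evaluation
uses 10 images/class with medium (0.5) separation and low noise under
stratified 5-fold cross-validation (macro rate ≈ 98%); the coarse-recovery
check uses 8 classes with 200 probes; the sparsity comparison uses 20
classes with 55 training images each so the shortlisted dictionary
(10 × 55 = 550 atoms > 512) is genuinely overcomplete, as in large-database
use. Defaults throughout: r = 0.12, μ = 0.001, S = ⌊C/2⌋, 5 folds.

## Known limitations

- **Sparsity of the weighted solution.** Because Jaccard distances lie in
  [0, 1], the weighted penalty μ‖W′A‖₁ is uniformly ≤ μ‖A‖₁. At equal μ the
  weighted problem is therefore a *weaker* regularization, and on the
  synthetic benchmarks its exact solutions are marginally (≲1%) denser by
  exact nonzero count than unweighted SRC — not sparser. What the weighting
  reliably does is concentrate coefficient mass on similar atoms, which is
  what the residual-based decision uses. The acceptance suite states the
  sparser-than-SRC claim as an inequality on exact nonzero counts and is
  expected to fail it; the analysis above is the reason.
- The pixelwise Jaccard metric is sensitive to residual misregistration;
  heavy rotation jitter combined with occlusion (the `high` preset) degrades
  both stages.
- The coarse stage can exclude the true class for atypical probes; the fine
  stage then cannot recover (predictions are always within the shortlist).
- Cross-validation randomness is limited to fold assignment; with the seed
  fixed the entire report is reproducible bit-for-bit.
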