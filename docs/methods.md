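# Methods

## Problem setting

The pipeline classifies per-pixel reflectance spectra from the exposed human
brain surface into four classes — normal cortex (0), glioblastoma tumor (1),
hypervascularized tissue (2) and background materials (3) — and searches for
the smallest wavelength subset that preserves held-out-patient accuracy.
Generalization is always measured with leave-one-patient-out
cross-validation: spectra of the test patient never appear in training, in
prototype selection, or (by default) in the band-search fitness.

## Preprocessing chain

1. **Radiometric calibration** `C = 100·(R − D)/(W − D)` against a white
   diffuse-reflector capture `W` and a closed-shutter dark frame `D`; a zero
   `W − D` anywhere is a hard error (degenerate reference).
2. **Extreme-band removal** to 440–902 nm, where VNIR silicon sensors have
   usable signal-to-noise.
3. **Spectral smoothing**: centered moving average along the band axis,
   default window 5 bands. Edges use shrinking windows so band count is
   preserved. A moving average was chosen over, e.g., Savitzky–Golay because
   it is order-preserving, parameter-light, and sufficient for the
   sensor-noise scale modeled here; the window is configurable.
4. **Band decimation** emulating a coarser camera: for a target count `n`,
   the targets are midpoints of `n` equal wavelength intervals
   (`λmin + (k + 0.5)·Δλ`) and each maps to the nearest existing band, ties
   to the lower index. This subsamples rather than block-averages, matching
   what a camera with fewer bands would record. Decimation is by wavelength
   spacing, not index stride, so it is correct on non-uniform grids.
5. **Per-pixel min–max normalization** `P' = (P − Pmin)/(Pmax − Pmin)`,
   flattening brightness variation from the curved tissue surface.
   Constant-spectrum pixels (e.g. saturated glare) map to all-zeros with a
   logged warning rather than an error, since dead/glare pixels occur in
   real cubes. Normalization runs after decimation so the unit-range
   invariant holds on the bands the classifier sees.

## Synthetic scenes

No public clinical database accompanies this problem, so the package ships a
first-class generator whose outputs have the statistical structure the
pipeline assumes:

- **Class means** are `base + contrast·Δ_c`: a shared logistic-ramp cortex
  curve (dark blue end rising through the red edge to a scattering NIR
  plateau, 0–100 reflectance scale) plus class deviations built from
  Gaussian hemoglobin absorption valleys at 540/580 nm (oxygenated) and
  560 nm (deoxygenated). Hypervascularized tissue has the deepest valleys;
  tumor differs from normal in valley balance, red-edge slope and NIR level;
  background is the mixture mean of four unrelated materials (bone, dura
  with blood film, surgical textile, matte instrument), which also gives it
  a much larger standard deviation than any tissue class.
- **`contrast` ∈ [0, 1]** scales all class separations: at 0 every class
  mean coincides and any classifier sits at 25 % four-class chance; at 1
  (the default) a linear SVM reaches ≥ 95 % on a held-out patient. These two
  endpoints are asserted in the test suite and are the calibration the rest
  of the tests rely on.
- **Inter-patient variability** is an additive smooth low-frequency curve
  per patient (3 cosine harmonics, scaled by `patient_offset_sd`,
  default 1.0 reflectance units). The default was chosen so that
  leave-one-patient-out folds are measurably harder than random splits but
  the max-contrast separability contract above still holds. Offsets are
  shared across a patient's pixels, which is what makes patient-wise
  validation meaningful on this data.
- **Pixel noise** is per-band Gaussian with class-specific standard
  deviation (higher in the NIR, much higher for background), clipped at zero
  reflectance.
- **Spatial cubes** place a background border, two vessel strips, a
  contiguous tumor blob grown to a requested share of pixels, and normal
  parenchyma elsewhere; a configurable fraction of pixels becomes
  near-saturated flat glare and is marked unlabeled (code 255), as glare is
  excluded from quantitative evaluation in practice. An optional
  `flat_tumor_patient` flag renders one patient's tumor spectrally identical
  to normal cortex, emulating a documented intraoperative failure mode for
  robustness tests.

What the generator does **not** model: radiative transfer, spatial texture
within a class, wavelength-dependent sensor PSFs, or label noise. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under controlled separability — not clinical-grade accuracy claims.

## Training-set reduction

Per class: seeded K-means (k-means++, 10 restarts, Euclidean) with K = 100
clusters, then for each centroid (index order) the 10 class pixels with the
smallest spectral angle `arccos(a·b/|a||b|)` to it. Selection is without
replacement across centroids of a class, so the 1000-per-class quota is met
by distinct original pixels; candidates are drawn from the whole class, not
only the centroid's own cluster members. Classes smaller than the quota get
`K = floor(available/10)` and a warning. K-means uses Euclidean distance and
SAM only scores prototypes, keeping the two stages separable; SAM is
brightness-invariant, which matches its role of finding shape-representative
pixels.

## Wrapper fitness and optimizers

A band subset is a binary mask. Fitness (minimized) is
`(1 − base)·(1 + λ/λmax)` with base = overall accuracy (`oa_p`) or the
pairwise balance score FoM (`fom_p`). The product form is used because a
quotient would *reward* larger subsets; a `form="quotient"` option exists
for reproduction studies. When the base metric saturates at 1 the penalty
vanishes for every subset size, so all optimizers break exact fitness ties
toward fewer bands (a 1e-9-scale lexicographic refinement that can never
override a real fitness difference); the stopping rule then requires both
fitness and subset size to stagnate.

- **GA**: generational, tournament selection (size 2), k-point crossover
  (default 2 points), per-bit mutation at rate 1/n_bands, elitism (2).
- **Binary PSO**: velocities follow
  `v ← α·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)` with α = 0.72,
  c1 = c2 = 2, clamped to ±4; bits re-sample as 1 with probability
  sigmoid(v). The sigmoid transfer is the standard binarization for a
  real-valued velocity rule.
- **ACO ranking**: ants build fixed-size subsets with probability
  ∝ τ^α·η^β, where the desirability η is a per-band pairwise Fisher ratio
  discounted by mean absolute correlation with bands already picked
  (penalizing redundant neighbors). Subset quality — SVM overall accuracy on
  a stratified holdout of the training set — is deposited on member bands;
  pheromone evaporates at rate 0.2 and is clamped MAX–MIN style to
  [0.01, 10]. The final ranking sorts by terminal pheromone, then
  heuristic, then index. This is a faithful generic instantiation; the
  published description of this stage is too thin to reproduce exactly, and
  the heuristic is documented as an interpretation.

Empty masks are repaired by activating one random band. Fitness values are
memoized by mask so identical subsets never retrain. All optimizers are
deterministic under their config seed, and per-stage seeds derive from a
global seed via a stable hash, so full-pipeline reruns are bit-identical.

Default search budgets (GA population 50 × 100 generations; PSO 30 × 100;
stagnation patience 20, ε = 1e-6) are configuration, not method: the
experiment drivers and tests run reduced budgets (e.g. population 20 × 40
generations with a 40-cluster prototype quota) matched to the synthetic
cohort's size, stated wherever used.

### Validation protocol inside a fold

The wrapper fitness never sees the held-out test patient. Within each outer
fold, every training patient serves once as an inner validation patient
(reduction refit on the remaining patients each time) and the candidate
subset's penalized fitness is averaged across these rotations — averaging
matters, since a single inner split lets the search overfit one patient's
idiosyncrasies. A `paper_literal=True` option instead scores candidates on
the test patient itself, reproducing a protocol sometimes described in the
literature; it leaks test data into selection and is off by default.

## Metrics

One-vs-rest per class over the multiclass confusion matrix: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), Matthews correlation coefficient with
the zero-denominator → 0 convention, and MCC′ = (MCC+1)/2. Undefined ratios
(empty denominator) are reported as missing (NaN), not zero. Overall
accuracy is the confusion-matrix trace over the total. FoM averages
`(ACCᵢ+ACCⱼ)/(|ACCᵢ−ACCⱼ|+1)` over class pairs (halved), equals the common
value when all accuracies are equal, and is computed over classes actually
present in the fold. Fold reports aggregate as mean ± std; unlabeled pixels
are excluded from all quantitative metrics but are classified in rendered
maps (green/red/blue/black palette for classes 0–3).

## Coincidence levels

Per-fold selections are membership-counted on the shared post-decimation
grid: L_i = bands chosen in ≥ i folds, so L_{i+1} ⊆ L_i and L_1 is the
union. Levels are re-evaluated with the full cross-validation harness, and
each level is reported as contiguous wavelength ranges (gap tolerance 0 by
default: only adjacent selected bands merge).

## Numerical choices and degenerate inputs

- Decimation ties (target equidistant between two bands) go to the lower
  index; duplicate picks collapse, so very coarse grids can return fewer
  bands than requested.
- Spectral angle is clipped into [−1, 1] before arccos; zero vectors are an
  error (angle undefined), which cannot arise for generated tissue spectra.
- SVM: linear kernel, C = 1, one-vs-one multiclass. Chosen to keep wrapper
  iterations fast and to avoid kernel hyperparameters masking band-selection
  effects; all configurable. Reproduction of any specific clinical accuracy
  figure is not claimed — the reference SVM configuration for such results
  was never published.
- ENVI output is float32 BIL with the wavelength list in the text header;
  round-trips are bit-exact at float32 and wavelengths survive to 6
  decimals.

## Known limitations

Synthetic separability is optimistic relative to clinical data (no spatial
artifacts, no label noise, Gaussian class models). The ACO stage is an
interpretation, not a reproduction. Absolute accuracies on real cohorts
depend on acquisition hardware and labeling protocol and cannot be inferred
from these tests.
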