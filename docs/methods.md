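# Methods

This note records the modelling conventions, numerical choices and open
design decisions behind `periradiomics`, in the spirit of the model
documentation shipped with simulation and statistics packages. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Regions

The peritumoral region is produced by per-slice (2D) morphological
dilation of the tumor mask with a Euclidean disk of radius 5 pixels
(center included), minus the tumor. Two choices deserve justification:

* **Fixed 5-pixel radius.** The clinically quoted peritumoral margin for
  this application is 2.5–5 mm "depending on pixel size"; across the
  cohort's 0.5–1.0 mm in-plane spacings a single 5-pixel rule reproduces
  exactly that physical range. Spacings outside (0, 2] mm trigger a
  warning rather than an error.
* **2D, not 3D.** Slice thickness (0.9–3 mm) is strongly anisotropic
  relative to pixel spacing, and all analysis windows are 5×5 in-plane;
  a 3D dilation would mix very different physical distances. A
  consequence is that no ring voxel appears on a slice without tumor.

No breast/air or chest-wall exclusion is applied: ring voxels are kept
wherever the image grid allows. Real cohorts would clip the ring to breast
tissue; phantoms have no such boundary.

## Texture bank

All descriptors are computed per 2D slice with mirror padding.

**Laws (25).** Convolution with the 5×5 outer products of L5 = [1,4,6,4,1],
E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1], W5 = [−1,2,0,−2,1],
R5 = [1,−4,6,−4,1], ordered row-kernel-major.

**Gabor (48).** Complex kernels with isotropic Gaussian envelope,
frequency-major then orientation order. The frequency index f ∈
{0, 2, 4, 8, 16, 32} is read as cycles per 64-pixel reference window
(so f = 32 is Nyquist), with a one-octave bandwidth tying σ = 0.5622/f₀.
Two conventions are deliberate:

* *f = 0* has no meaning as a wave frequency; it is implemented as the
  low-pass limit — the unit-sum Gaussian envelope alone (σ of the smallest
  nonzero frequency), replicated across the 8 orientation slots so the
  printed 6 × 8 = 48 bank shape is preserved.
* The orientation grid defaults to the uniform 22.5° ladder ending at
  157.5°; the variant ending at 167.5° (as sometimes printed) is available
  via `GABOR_THETAS_PRINTED`. Kernels with f > 0 are DC-corrected so that
  constant images produce zero magnitude.

**Haralick (13).** Per pixel, a symmetric gray-level co-occurrence matrix
is accumulated over unit offsets in 4 directions (0°, 45°, 90°, 135°)
between pixel pairs lying fully inside the 5×5 window, normalized to sum
1, and summarized by the 13 classical statistics (natural-log entropies).
Gray levels: 64 bins by min–max scaling over the tumor + ring union of the
slice (the common GLCM default; the count is configurable). Degenerate
conventions: correlation = 0 when a marginal variance vanishes; the
information-measure denominator 0 maps to 0. Note that HXY1 and HXY2
collapse algebraically to HX + HY, so IMC1 = −MI/max(HX,HY) and
IMC2 = √(1 − e^(−2·MI)); the test oracle computes the literal double sums.

**CoLlAGe (13).** Gradients by central differences on a mirror-padded
slice; each pixel's dominant orientation is the principal singular
direction of the gradient vectors stacked over its 5×5 window (computed in
closed form from the 2×2 scatter matrix, θ = ½·atan2(2S_xy, S_xx − S_yy)
mapped to [0, π)). Orientations are quantized into 64 uniform bins
(configurable) and passed through the same windowed co-occurrence
machinery. Windows with identically zero gradients take orientation 0.

For efficiency the windowed families accept an evaluation mask; the
pipeline computes them only at tumor + ring voxels (other pixels are NaN).

## Pharmacokinetics

Standard Tofts model, C_t(t) = K^Trans ∫₀ᵗ C_p(τ)e^(−k_ep(t−τ))dτ, with a
population Weinmann bi-exponential AIF (a = 3.99, 4.78 kg/L; m = 0.144,
0.0111 min⁻¹; dose 0.1 mmol/kg) — no measured AIF exists for a
retrospective cohort. Signal is converted to a concentration proxy by
relative enhancement (S − S₀)/S₀ because no T1 maps are available;
absolute parameter values are therefore in proxy units and only the
pipeline structure (not PK magnitudes) is comparable across datasets.
V_e is the extravascular-extracellular volume fraction K^Trans/k_ep (the
standard Tofts definition).

Numerics: the generic forward model integrates by trapezoid on a 2000-point
grid (≲10⁻⁶ relative error vs an ODE oracle); for the bi-exponential AIF a
closed form is used in fitting. `fit_tofts` seeds bounded least squares
([0, 5] min⁻¹) from a 64-point geometric k_ep grid with the K^Trans
profile solved linearly; `fit_tofts_grid` vectorizes the same idea over
voxels (400-point grid + parabolic refinement on log k_ep, discretization
error ≪ 1%). Flat zero curves return (0, 0, 0) flagged; voxels with zero
precontrast signal are masked with a warning.

## Feature table

* Phases: exactly two are summarized — *initial* (first postcontrast,
  t = 2 min) and *peak* (argmax of mean tumor intensity over postcontrast
  phases) — because 1980 = 99 × 5 × 2 regions × 2 phases fixes the count.
* Statistics are pooled over all region voxels across slices (not
  per-slice-then-averaged, which is the main alternative reading); SD uses
  n−1; skewness/kurtosis are biased moment estimators with non-excess
  kurtosis (Gaussian → 3); constant regions return 0 for both, flagged.
* The 15 PK features are the five statistics of the three parameter maps
  over the intratumoral region.
* Normalization maps each column affinely so the *reference* (training)
  min/max go to ∓1; non-reference rows are clipped to [−1, 1] and constant
  reference columns map to 0. The reference is always the training cohort,
  frozen before the holdout is touched.

## Feature discovery

mRMR uses the MID (relevance − mean redundancy) criterion with mutual
information estimated on 10-bin quantile-discretized features — the
toolbox-standard variant; quantile binning makes the ranking invariant to
monotone feature transforms. Stage-1 frequencies pool over all
iterations × folds (600 fold-runs at the default 200 × 3); "eliminate the
bottom 90%" is read as retaining the top ⌈10%⌉ by frequency, with ties
broken by mean within-run mRMR score and then lexical feature id (ties are
inevitable at 600 runs). Redundancy pruning drops a feature when
|Pearson r| ≥ 0.90 (configurable) against any higher-ranked keeper.
Majority-class downsampling (used for the 10/60 hormone-receptor-positive
group, to 20 per iteration) happens per iteration before folding. Folds
are stratified by class — with 10 minority patients plain folds could go
single-class.

## Consensus clustering

Each of 1000 iterations subsamples ⌊0.8·n⌋ patients without replacement,
clusters them hierarchically (average linkage, both for the inner runs and
the final cut, matching the usual consensus-clustering default) under
1 − Pearson correlation between patient vectors, and cuts at k = 2.
Consensus_ij = co-clusterings / co-samplings with 0/0 → 0; the final
assignment cuts a hierarchical tree of 1 − consensus. Patient vectors with
zero variance have undefined correlation; their distances are set to 1
with a warning. Clustering uses normalized feature values. A property
worth knowing: the Pearson patient-distance is invariant to uniform
per-patient shifts, so classes must differ in their feature *pattern* to
form clusters (the phantom classes do; the uniform-shift planted tables do
not, and `generate_patterned_groups` exists for clustering tests).
Cluster-vs-label accuracy maps each true class to the cluster holding most
of its members and reports that fraction, invariant to cluster relabeling.

## Classifiers

LDA, QDA and Gaussian naive Bayes are scikit-learn estimators; DLDA
(pooled *diagonal* covariance discriminant) is implemented here since
scikit-learn has none; the SVM is linear with C = 1 (kernel and C are not
otherwise determined at ≤10 features) and scored by signed margin, the
discriminants by posterior probability. Class priors are empirical.
Accuracy/sensitivity/specificity threshold at posterior 0.5 (margin 0);
AUC is the rank statistic with half credit for ties. If a QDA class
covariance is rank-deficient (possible in small folds), a
shrinkage-regularized QDA ((1−α)S + α·tr(S)/p·I, α = 0.1) is substituted
with a warning — scikit-learn's own regularizer refuses rank-deficient
classes outright. CV is stratified 3-fold × 50 repetitions with
out-of-fold scores pooled *within* each repetition, metrics computed per
repetition, and mean ± SD across repetitions.

A statistical caveat encoded in the tests: for one finite ~100-patient
null dataset the CV AUC sits at 0.5 only in expectation *across datasets*
(chance feature–label correlation contributes ±0.08 per dataset), so
chance-level checks average over independent null cohorts or label
permutations.

## Synthetic phantoms

The generator emulates the study conditions, not breast anatomy. An
ellipsoidal tumor (default radius 6 mm, optional lobulation) sits in a
uniform background on a (5, 48, 48) grid at 0.75 mm pixels and 1.5 mm
slices; one precontrast plus five postcontrast phases at t = 2, 3.5, 5,
6.5, 8 min. Tumor voxels follow S(t) = S₀(1 + C_t(t)) with C_t from the
Tofts forward model, so PK recovery tests are self-consistent by
construction; ring-adjacent tissue enhances at 30% of the tumor kinetics.

Class-linked contrasts are planted explicitly:

* **Peritumoral speckle** — multiplicative high-frequency noise in the
  ring (floored at 5% signal so intensities stay physical); class means
  0.05 (pCR) vs 0.25 (non-pCR), per-patient SD 0.10.
* **Gradient disorder** — the spatial modulation of voxel-wise K^Trans is
  a mix (1−d)·radial ramp + d·smooth random field; d means 0.2 vs 0.8,
  SD 0.30, clipped to [0, 1].
* **Enhancement heterogeneity** — the amplitude of that modulation;
  means 0.25 vs 0.45, SD 0.15.
* **Kinetics** — class-mean (K^Trans, k_ep) = (0.30, 0.65) vs (0.40, 0.85)
  min⁻¹ with per-patient SDs (0.10, 0.20): strongly overlapping, since
  contrast kinetics are weak response discriminators in this setting.

The per-patient jitter is the package's realism choice: without it the
classes separate perfectly and every downstream metric saturates at 1.0,
which no clinical cohort does. No quantitative class-contrast magnitudes
exist to copy, so these values were fixed once as plausible and are
configuration, not fitted constants. Additive acquisition noise defaults
to SD 2 (≈1% of baseline). All randomness derives from a single
per-phantom seed with a fixed draw order, so identical configurations are
bit-identical and cohorts use seeds `spec.seed + i`.

What phantoms do **not** model: breast anatomy and fat saturation, scanner
and field-strength effects, radiologist-annotated region boundaries,
non-mass enhancement. Passing tests demonstrate that the *pipeline*
recovers planted structure under the stated conditions — not that the
planted magnitudes match clinical effect sizes, so absolute AUCs on
phantoms do not transfer to patients.

## Experiments and problem sizes

Experiment 1 generates 24 + 54 training and 12 + 27 holdout patients;
discovery, normalization and model fitting see only training patients (an
audit object records the patient ids each stage touched and asserts the
holdout is untouched). Consensus clustering runs on the training cohort
with four feature sets: combined top-10, intratumoral-only top-10,
peritumoral-only top-10, and the 15 PK features. Experiment 2 runs
group-restricted discovery and 50 × 3 CV in the 10/60 and 26/21 receptor
groups (downsampling to 20 in the former); as in the study protocol,
discovery and evaluation share the patient pool there, which is optimistic
and is recorded in the bundle note.

`scripts/acceptance.py` uses the full cohort sizes and consensus
iterations but 50 discovery iterations and 25 CV repetitions for the
experiment-level section, and 10 seeds for discovery recovery — sizes
chosen so a complete run stays within a few minutes on one CPU while every
reported quantity remains a run-time computation. The unit/acceptance test
suite uses smaller grids (documented in `tests/conftest.py`) for the same
reason.

## Known limitations

* The ring is not clipped to anatomy (no supplementary mask procedure is
  reproducible), so peritumoral statistics include whatever the grid holds.
* PK values are proxy-scaled (relative enhancement, population AIF);
  only orderings and pipeline behavior are meaningful.
* The exact CoLlAGe/Haralick discretizations and the Gabor f = 0 reading
  used historically are unknowable from the printed description; the
  conventions above are documented choices exposed in configuration.
* Phantom effect magnitudes are free parameters; headline AUCs computed on
  phantoms characterize the pipeline, not the clinical task.
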