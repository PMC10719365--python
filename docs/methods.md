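# Methods

This note documents the models and procedures implemented in
`chromascope`, the parameters that matter, the numerical choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Image model and preprocessing

Acquisitions are 4-D arrays indexed `(channel, z, y, x)` with voxel
geometry carried alongside (defaults 0.09 × 0.09 µm lateral, 0.5 µm
axial). Pixel coordinates are 0-based; bounding boxes half-open.
Intensities are carried as floats; integer TIFF data is converted on read.

Range normalization is min–max per image per channel, mapping each image
onto [0, 1] to absorb the variable explored intensity range of individual
acquisitions; a constant image maps to all zeros rather than dividing by
zero. Normalization is applied per stack, not per z-plane — per-plane
scaling would re-weight axial intensity structure that the 3-D
segmentation relies on. The median denoise filter uses a 3×3
cross (diamond radius 1) footprint with reflective edges; the footprint
size is a free choice (only "a median filter" is pinned down by the
protocol) and radius 1 removes single-pixel shot noise without eroding the
nuclear boundary at the 30–80 px nucleus diameters this pipeline targets.

## Segmentation

2-D candidates: max-z projection → median filter → gamma adjustment
(γ = 0.7, boosting dim mid-tones before thresholding) → Otsu threshold →
8-connected components → area gate 800–5000 px (6.48–40.5 µm²) → removal
of border-touching objects. The upper area cap is deliberately the sole
mechanism that removes touching/merged nuclei: merged blobs exceed it, and
no separate adjacency test exists. Candidates are therefore pairwise
disjoint single components by construction.

Crops: each candidate's bounding box is padded by 12 px (~1 µm, so that
peripheral signals like Lamin A/C and surface markers are retained) and
clipped to the field; clipping is flagged on the record rather than
discarding the nucleus. Background is zeroed outside the convex hull of
the candidate mask dilated 12× with a 3×3 cross — an approximate
whole-cell region. The DAPI channel is additionally re-cleared against a
crop-local 2-D mask (median → max-z → Otsu → hole filling) applied at
every z, which erases DAPI signal of neighbouring nuclei that fall inside
the padded box but outside the hull.

3-D refinement uses the morphological Chan-Vese level set (the n-D
morphological variant of the Chan-Vese energy; the classical
finite-difference implementation available to us is 2-D only) on the
range-normalized DAPI crop with (λ₁, λ₂) = (1, 2), checkerboard
initialization, smoothing 1, and a hard cap of 300 iterations. The solver
runs in 10-iteration chunks and stops early once the level set is
unchanged across a chunk — in practice convergence occurs well before the
cap. Checkerboard initialization makes the inside/outside labelling
arbitrary, so the side with the higher mean intensity is taken as the
nucleus. The largest connected component is kept (one nucleus per crop by
construction), then QC requires ≥ 400 voxels (1.62 µm³) and a z-height —
counted as occupied z-slices × dz, inclusive bounds — within 2.5–10 µm.
Failing records carry their rejection reason (`size`, `height`,
`no object`).

Cell masks are box dilations of the nuclear mask by 12 px laterally and
2 planes axially (~1 µm each way, exploiting the near-spherical PBMC
shape), implemented as separable 1-D dilations; the nuclear mask is always
contained.

## Chrometric features

~45 named features in five categories, deterministic order, exported with
units in a JSON dictionary:

- **morphology** — volume (voxels × voxel volume), projected area, height,
  2-D and 3-D concavity (1 − object/convex-hull ratio; the 3-D variant is
  undefined for single-plane masks and reported as NaN), and
  principal-axis aspect ratio / elongation computed on physically scaled
  coordinates (z multiplied by dz/dx) so axial anisotropy does not
  masquerade as shape.
- **boundary** — the longest closed iso-contour of the projected mask is
  resampled to 128 equal arc-length points (stable finite differences at
  30–80 px diameters), smoothed with a periodic Gaussian of σ = 2 samples
  (suppresses pixel-staircase noise; shrinks a circle's radius by < 1%),
  and signed curvature κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2} is evaluated by
  periodic central differences. Reported: mean |κ|, SD of κ (the boundary
  "variability"), max |κ|, in 1/µm. On a rasterized circle of radius 30 px
  the mean recovers 1/r within ~1%.
- **intensity** — in-mask mean, SD, skewness, excess kurtosis, the nine
  deciles, and the Shannon entropy (bits) of a 64-bin histogram over the
  in-mask range.
- **moments** — central image moments to order 3 and the seven Hu
  rotation invariants of the masked projected DNA intensity.
- **hc_ec** — heterochromatin/euchromatin partition by a two-class Otsu
  threshold *within* the nuclear mask (parameter-free and consistent with
  the pipeline's other thresholding); reported as HC volume, HC volume
  fraction, HC/EC ratio and HC intensity share. The partition conserves
  volume exactly; an untextured (constant) nucleus has no defined
  partition and reports NaN.

Marker expression is the in-mask intensity sum on the max-z projection,
plus the area-normalized form (sum / projected mask area) used for gating.
The nuclear mask is used for all markers, including the perinuclear
Lamin A/C — the 12-px crop pad keeps the rim inside the crop, but rim
signal outside the projected nuclear mask is not counted; this convention
is uniform across markers and is the main sensitivity caveat for Lamin
quantification.

## γH2AX foci

Per nucleus: the marker crop and 3-D mask are max-z projected, the
projection range-normalized, and pixels at least 2.5 SD above the mean
become candidates; components < 4 px are removed; a watershed seeded at
local intensity maxima (maximum filter with 2-px minimum separation,
plateaus merged to a single seed, 8-connectivity, deterministic seed
order) splits touching foci; the size filter is applied once more. Mean
and SD are computed over the pixels of the projected nuclear mask — a
whole-crop statistic would be dragged down by the zeroed background and
inflate counts. A flat in-mask signal (SD = 0) yields zero foci by
definition. Because normalization precedes thresholding, counts are
invariant under affine intensity rescaling.

## Cell typing

Per sample and marker, the area-normalized intensities of all cells
(minimum 20) are fit with a two-component univariate Gaussian mixture
(k-means++ initialization, 10 restarts, EM tolerance 1e-6, fixed seed; the
covariance floor scales with the data variance so fits are
scale-equivariant). The gate threshold is the equal-posterior crossing
point between the component means — not the midpoint, so unequal variances
and weights are honoured — with a variance-weighted midpoint fallback for
pathological weight configurations. The higher-mean component is positive;
values strictly above the threshold are positive and a value exactly at
the threshold is negative (deterministic tie rule). Gates that fail to
converge or whose component separation |µ₂ − µ₁|/max(σ) falls below 0.5
are refused and the sample excluded from typing. Note the separation
diagnostic is a heuristic: a unimodal sample can still yield a formally
well-separated two-component fit; it reliably rejects near-coincident
modes, which is its job here. CD4/CD8 booleans define the four subset
labels; CD3 status is carried separately; CD16 and other markers are
supported as generic channels without dedicated subset logic.

## Cohort analyses

**Pruning.** Features correlated with any other at |Pearson r| > 0.8
(strict) are removed greedily in fixed column order, keeping the earlier
feature of an offending pair — deterministic, since no rule for which
member to drop is otherwise implied. Constant columns (undefined
correlation) are removed first with a warning.

**Balancing.** Random subsets with equal counts per balancing level
(patient, or condition group), allocated as equally as possible across the
patient × timepoint sub-units inside each level; levels that cannot supply
the quota are excluded ("sufficient cells" rule). Reproducible under seed.

**LOPO-CV.** One fold per patient; the forest (500 trees by default,
√(n_features) candidate features per split, no depth cap, per-fold seeds
drawn from one generator) trains on all other patients' cells and is
scored by balanced accuracy on the held-out patient's cells. Since a
held-out patient carries one class, its fold score is that class's recall;
the average over folds is the cohort estimate. Confusion matrices are
row-normalized per fold and averaged over folds where the row has test
support. "Stratification" is realized entirely through the upstream
per-patient balancing; no additional within-fold reweighting is applied.
A patient carrying more than one label raises a leakage error — except in
permutation runs, where mixed labels are the point.

**Permutation null.** Labels of the whole table are permuted (not within
patient — permuting the table is what destroys the feature–label
association) and the full LOPO protocol re-runs; 10 permutations by
default. The real per-fold accuracies are compared against the pooled null
folds with a two-sided Wilcoxon rank-sum test. For balanced k-class
synthetic cohorts the null mean sits at 1/k within Monte-Carlo error.

**Ablations.** Patients: for each k, each fold's training set is reduced
to a random k patients per class (all, when k covers the class), repeated
10 times; at full k the procedure is exactly standard LOPO. Cells: per
training patient, max(1, ⌊p·n⌋) cells are kept, p ∈ {10%, …, 100%}.

**Biomarkers.** Gini (mean-decrease-in-impurity) importances are averaged
over the LOPO folds and ranked; the Welch screen runs two-sided Welch
t-tests per feature (pairwise for > 2 groups) with Benjamini-Hochberg
adjustment across the entire screen and significance at adjusted p < 0.05.
Star coding: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.
Control-normalized comparisons divide all values by the control-group mean
(control normalized mean is exactly 1) with Welch tests against control.

**QC embedding.** t-SNE (PCA initialization, perplexity min(30, n/10),
fixed seed) or class-supervised LDA, returned with metadata for coloring
by patient/condition; used only for visual batch-effect assessment.

**Majority vote.** Each patient receives its modal predicted class; exact
ties break to the first class in sorted order and are flagged ambiguous.

## Synthetic data

The image generator renders what the pipeline assumes: ellipsoidal nuclei
(lateral semi-axis 2.8 ± 0.25 µm, axial 2.0 ± 0.15 µm — projected area
~25 µm², height ~4 µm, comfortably inside the QC windows) voxelized on the
anisotropic grid, with low-order Fourier perturbation of the lateral
radius (boundary irregularity), DAPI texture from a low-pass Gaussian
random field thresholded so the brightest quantile forms discrete HC blobs
(default HC fraction 0.25), Poisson-count Gaussian foci (default rate 3,
amplitude 0.9 over a 0.15 base), a rim-weighted Lamin channel, and
surface-marker channels at bimodal log-normal levels with PBMC-typical
positivity (CD3 0.70, CD4 0.45, CD8 0.25). Condition effects are
multiplicative dials on volume, HC fraction, foci rate and boundary
irregularity; patient effects are multiplicative log-normal with SD 0.05;
additive Gaussian noise (SD 0.02) and a 0.05 background follow truth
recording, so truth/image consistency is exact pre-noise. Default field:
150 × 150 px × 21 planes at 0.09/0.5 µm voxels (a ~13.5 µm lateral field
per nucleus).

A table-level twin, `simulate_feature_cohort`, samples per-cell feature
vectors (volume, HC fraction, foci count, curvature SD, plus pure-noise
columns) from the same hierarchy — condition effect × patient effect ×
log-normal cell noise (CV 0.12), Poisson foci. The cohort-level statistics
operate on tables, so their calibration and recovery suites use this
generator at realistic sizes (hundreds of cells, 6–10 patients) while the
image-level generator exercises segmentation, features and foci on small
fields; this split keeps the default test run in the minutes range on one
CPU and is a deliberate scale choice, not a change of model.

What the generator does **not** emulate: optical PSF blur and axial
smearing, photobleaching, chromatic shifts, spectral spillover between
channels, true chromatin texture statistics, touching-nuclei clusters,
debris and imaging artifacts, and staining-batch drift beyond a scalar
per-sample marker shift. Passing recovery tests therefore demonstrates
the internal correctness and calibration of the algorithms under the
stated generative model, not performance on real microscope data.

## Calibration caveat: patient effects vs cell-level tests

The Welch screen treats cells as independent samples. Under patient-level
random effects, cells are correlated within patients and a cell-level test
across conditions is anticonservative (pseudoreplication): with the
default 5% patient effect, zero-effect cohorts frequently show spurious
BH-significant features. The screen's null calibration is therefore
stated — and tested — for exchangeable cells (no patient effects); on real
cohorts the LOPO + permutation machinery, which respects the patient
hierarchy, is the trustworthy guard, and the screen should be read as a
ranking aid rather than an inferential test. This mirrors how such screens
are used alongside the classifier in practice.

## Determinism and degenerate inputs

Every stochastic procedure takes an explicit seed; per-fold and
per-permutation seeds derive from a single generator. Degenerate inputs
have decided behaviours rather than errors where a value is recoverable:
constant images normalize to zero, flat foci signals count zero, constant
nuclei flag their HC partition and entropy as NaN/0, single-plane masks
flag 3-D concavity, and exact gate-threshold values are negative.
Otsu on a constant image and gates on constant intensities raise, since no
meaningful output exists.

## Limitations

- No splitting of touching nuclei (they are excluded by the area cap) and
  no deep-learning segmentation backend.
- Foci are called in 2-D projection; overlapping foci along z merge.
- The feature catalog covers the quantities the analyses consume; it is
  not a parity implementation of any external texture-feature library.
- Published patient-level accuracies from real cohorts depend on the
  deposited imaging data and are out of scope here; the synthetic suites
  validate the machinery, not clinical effect sizes.
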