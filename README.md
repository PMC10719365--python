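# chromascope

Chromatin imaging profiles of PBMC nuclei, from raw confocal z-stacks to
patient-level classification.

Peripheral blood mononuclear cells (PBMCs) respond to systemic signals —
a tumor's secretome, radiation exposure during therapy — by reorganizing
their nuclear chromatin. `chromascope` quantifies that reorganization from
3-D multi-channel fluorescence images (DAPI plus functional and cell-type
markers such as γH2AX, Lamin A/C, CD3/CD4/CD8) and asks whether it carries
enough signal to tell patient groups apart. It is written for imaging and
computational-biology groups who have (or simulate) single-cell nuclear
image stacks and want a transparent, fully testable pipeline rather than a
black box.

## What it computes

**Per nucleus.** DAPI stacks are range-normalized; 2-D nucleus candidates
come from a max-z projection (median filter → γ = 0.7 contrast adjustment →
Otsu threshold → connected components, keeping areas of 800–5000 px =
6.48–40.5 µm² at 0.09 µm pixels and dropping border-touching objects).
Each candidate yields a background-cleared multi-channel 3-D crop, refined
into a 3-D nuclear mask by a Chan-Vese level set with (λ₁, λ₂) = (1, 2)
and at most 300 iterations, quality-controlled at ≥ 400 voxels (1.62 µm³)
and a 2.5–10 µm z-height. From the mask and crop the package extracts a
"chrometric" profile: morphology (volume, projected area, height,
concavity, principal-axis shape), boundary curvature statistics,
DNA-intensity descriptors, image-moment invariants, and the
heterochromatin/euchromatin partition. γH2AX foci are counted on the
projected crop by thresholding at mean + 2.5 SD of the in-mask intensity,
a 4-px (0.032 µm²) size filter, and a watershed split of touching spots.
Surface-marker expression is the in-mask intensity sum normalized by
projected area, gated per sample with a two-component Gaussian mixture to
call CD4/CD8 subsets and CD3 status.

**Per cohort.** Feature tables are pruned of correlated features
(|Pearson r| > 0.8), subsampled to equal per-patient cell counts, and
classified with a random forest under leave-one-patient-out
cross-validation (LOPO-CV): for each fold the forest never sees cells of
the evaluation patient, so the balanced accuracy

  BA = (1/K) Σ_k recall_k

estimates how well an *unseen* patient's condition is predicted. Chance is
estimated empirically by re-running the identical protocol on
label-permuted tables; patients are diagnosed by majority vote over their
cells; ablation curves vary the number of training patients (k) or the
per-patient cell fraction (p); biomarkers are screened both by Gini
importance of the fitted forests and by per-feature Welch t-tests with
Benjamini-Hochberg correction; a t-SNE/LDA embedding supports visual
batch-effect QC.

**Synthetic ground truth.** A generator renders ellipsoidal, textured
nuclei on the anisotropic voxel grid with planted foci, rim-weighted Lamin,
bimodal marker intensities, condition effects (volume, HC fraction, foci
rate, boundary irregularity) and patient-level random effects — so every
stage of the pipeline is testable against known truth without any
microscope data. A table-level twin (`simulate_feature_cohort`) samples
feature cohorts from the same hierarchical model for fast statistical
experiments.

## Worked example

```sh
python examples/04_cohort_classification.py
```

simulates a 10-patient control-vs-tumor cohort in which tumor nuclei are
1.3× larger, carry 1.2× the heterochromatin fraction and 1.5× the foci
rate, and prints:

```
cohort: 800 cells, 10 patients; 0 correlated features removed
balanced accuracy (cell level): 0.815 +/- 0.097
patient-level majority-vote accuracy: 1.00
permutation null: 0.497 (Wilcoxon p = 2e-07)

top-5 Gini importances:
           feature  importance  importance_sd
        volume_um3      0.2839         0.0269
hc_volume_fraction      0.1890         0.0191
        foci_count      0.0527         0.0084
      curvature_sd      0.0287         0.0039
          noise_12      0.0260         0.0027

Welch/BH-significant features: ['volume_um3', 'hc_volume_fraction', 'foci_count']
```

Cells of held-out patients are classified correctly 81.5% of the time
(chance ≈ 0.5 by the permutation null), every patient is diagnosed
correctly by majority vote, and both biomarker strategies converge on
exactly the three planted-effect features. The other examples walk through
segmentation (`01`), single-nucleus profiling and foci counting (`02`) and
mixture-model gating (`03`).

A thin CLI wraps the same stages for shell use:

```sh
chromascope simulate --out cohort/ --patients 3
chromascope extract --config config.yaml
chromascope analyze --config config.yaml
chromascope report --out-dir results/
```

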