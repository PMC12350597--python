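# hfmap — tile-shifted homology-profile maps for fibrotic lung CT

`hfmap` quantifies fibrotic texture on axial lung CT slices with a
topological statistic and classifies slices as fibrotic vs non-fibrotic (or
fibrotic vs lung cancer) from it. It is aimed at quantitative-imaging
researchers who want a transparent, parameter-light alternative to
learned radiomics pipelines, and it ships a synthetic thorax phantom so the
whole method runs and is testable without any clinical data.

## The method

For a binary image, the Betti numbers **b0** and **b1** count connected
foreground components and holes (enclosed background regions). Sweeping the
binarization threshold *t* over the fibrosis-relevant attenuation band
(−700…−400 HU, 1 HU steps; foreground = pixels ≥ *t*) turns a grayscale tile
into a **homology profile** — the sequence (b0(t), b1(t)).

Fibrotic patterns (reticulation, honeycombing) consist of thin septa whose
local attenuation varies, so inside the sweep band a fibrotic tile shatters
into many components: its b0 profile peaks high. Aerated lung with a few
vessel cross-sections stays low.

The **HF map** makes this local statistic an image again:

1. slide a 32×32 px tile across the slice with an 8 px stride;
2. skip tiles with strictly more than 95 % of pixels outside the lung mask;
3. take max<sub>t</sub> b0(t) for each remaining tile, divide by the pixel
   area (mm²) so values are comparable across scanners;
4. add the standardized value to every pixel of the tile footprint
   (overlaps sum).

The slice-level feature is the HF-map maximum. Classification is slice-wise:
patients are randomly split 2/3–1/3 into tuning and testing sets; a ROC
analysis of the tuning features yields the cutoff maximizing the Youden
index J = sensitivity + specificity − 1; the rule *feature ≥ cutoff ⇒
fibrosis* is scored on the testing slices (accuracy, sensitivity,
specificity, precision); the whole protocol is repeated 5 times and
averaged.

Betti numbers use dual 8/4 adjacency for foreground/background, and the whole
sweep profile of a tile is computed in one incremental union-find pass per
phase (numba-accelerated), which is what makes 1 HU steps practical.

## Worked example

```python
from hfmap import (CohortSpec, ExperimentParams, cohort_features,
                   generate_cohort, repeated_experiment)

# 10 fibrosis + 10 normal phantom patients, 2 slices each
manifest, samples = generate_cohort(CohortSpec(base_seed=0))

# full pipeline: lung segmentation -> b0 HF map -> slice feature
features = cohort_features(samples)
print(features.groupby("label").feature.describe()[["mean", "min", "max"]].round(1))

result = repeated_experiment(features, ExperimentParams(n_repeats=5, seed=0))
for key in ("cutoff_mean", "cutoff_sd", "auroc_mean", "accuracy_mean",
            "sensitivity_mean", "specificity_mean", "precision_mean"):
    print(f"{key:18s} {result['summary'][key]:.3f}")
```

prints

```
               mean    min    max
label
fibrosis      484.5  436.7  530.6
non_fibrosis   86.1   67.3  114.3
cutoff_mean        273.469
cutoff_sd          2.499
auroc_mean         1.000
accuracy_mean      1.000
sensitivity_mean   1.000
specificity_mean   1.000
precision_mean     1.000
```

The fibrotic honeycomb drives the slice feature roughly 5× above normal
lung, so every repeated patient-wise split separates perfectly (AUROC and
all four test-set metrics 1.0); the tuned cutoff sits mid-gap and varies
slightly with the split (SD ≈ 2.5).

The estimators also compose with scikit-learn:

```python
from sklearn.pipeline import Pipeline
from hfmap import HFMapTransformer, YoudenThresholdClassifier

pipe = Pipeline([("hf", HFMapTransformer()),
                 ("clf", YoudenThresholdClassifier(positive_label="fibrosis"))])
pipe.fit(samples, [s.label for s in samples])
```

## Command line

```bash
hfmap phantom --out-dir cohort --n-per-class 10 --seed 0   # synthetic cohort
hfmap segment --input slice.nii --out-mask mask.nii        # lung-field mask
hfmap run --input slice.nii --mask mask.nii --out map.nii  # HF map + feature
hfmap experiment --features features.csv --repeats 5       # ROC/Youden protocol
hfmap sweep --out sweep.csv --tile 16 --tile 32            # tile/shift validation
```

CT input may be DICOM (HU via rescale slope/intercept), NIfTI, or PNG with a
JSON spacing sidecar.

## Scope

2D slices only (no volumetric homology), no persistence diagrams, no
learned segmentation. The phantom emulates HU statistics relevant to the
method, not CT physics; see `docs/methods.md` for what that does and does
not validate.
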