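# bsamap

Voxel-wise **BOLD signal amplitude (BSA)** brain-activity mapping from
resting-state fMRI.

## The problem

Resting-state fMRI measures spontaneous low-frequency (< 0.1 Hz) BOLD
fluctuations without a task. Most analyses turn these fluctuations into
*connectivity* (correlations between regions). `bsamap` instead computes a
per-voxel *activity* magnitude, intended as an MR-only counterpart to
FDG-PET glucose-metabolism imaging — useful, for example, when comparing
healthy elderly controls against patients with Alzheimer disease, whose
neuronal activity and metabolism are reduced.

## The metric

Let S_i(t) be the preprocessed BOLD time series of voxel *i* and let spatial
ICA decompose the masked 4D data into *n* components, each a spatial map
paired with a unit-variance time course W_j(t). A subset of *k* components is
identified as *neuronal* by template matching against canonical resting-state
networks (goodness of fit = mean map value inside the template minus mean
over the rest of the brain) plus a high-frequency power screen on the time
course. For each neuronal component *j*:

    BSA_ij(t) = S_i(t) ∘ W_j(t)                (Hadamard product)

and the activity of voxel *i* is

    activity_i = Σ_{j=1..k}  SD( BSA_ij ) · NC_ij

where SD is the temporal standard deviation and NC_ij is component *j*'s
z-scored spatial map value at voxel *i*. A square-root variant
(Σ sqrt(SD)·NC, `aggregation="sum_sqrt_sd"`) is also provided. Activity maps
can be summarized over a ROI atlas, correlated voxel-by-voxel with FDG-PET
SUVR images (normalized to a cerebellar reference), compared between groups
(ANOVA + Bonferroni-corrected Welch follow-ups), and fed to a leave-one-out
linear-SVM classifier.

Because real cohort data of this kind sit behind data-use agreements, the
package ships a phantom generator (`bsamap.phantom`) producing synthetic
subjects with planted sources, structured noise, group effects, and a
PET-like surrogate with a designed correlation to the true activity — every
pipeline stage is testable with known ground truth.

## Worked example

```python
from bsamap import (PhantomSpec, generate_subject, preprocess, PreprocConfig,
                    decompose, label_components, activity_map, ActivityConfig,
                    whole_brain_activity, voxelwise_correlation)
from bsamap.phantom import truth_templates

series, truth = generate_subject(PhantomSpec(), seed=42)
pre = preprocess(series, PreprocConfig())          # 6 mm FWHM, 0.01-0.1 Hz
dec = decompose(pre, n_components=8, seed=1)       # spatial ICA
labels = label_components(dec, truth_templates(truth),
                          tr_seconds=series.tr_seconds)
amap = activity_map(pre, dec, labels, ActivityConfig())
res = voxelwise_correlation(amap.values, truth.true_activity.values, truth.mask)
print(f"neuronal components k = {labels.k}")
print(f"whole-brain activity  = {whole_brain_activity(amap):.4f}")
print(f"correlation with truth r = {res.r:.3f} over n = {res.n} voxels")
```

prints

```
neuronal components k = 5
whole-brain activity  = 0.3479
correlation with truth r = 0.983 over n = 2000 voxels
```

All five planted sources were labeled neuronal (k = 5); the whole-brain
activity is the voxel mean of the map over the brain mask (arbitrary BOLD
units); and the recovered map correlates at r = 0.98 with the noiseless
ground-truth activity.

The same pipeline is scriptable from the shell:

```sh
bsamap simulate --out sim --seed 42
bsamap run --config config.yaml --out results_run
bsamap classify --cohort cohort.tsv --features whole_brain,roi_source0
```

`bsamap run` writes `maps/`, `tables/`, and a `manifest.json` recording the
config hash and every seed, so a rerun with the same config is byte-identical.

## Layout

| module | role |
| --- | --- |
| `bsamap.io` | NIfTI/TSV I/O, grids, masks, atlases, ROI volume fractions |
| `bsamap.preprocess` | Gaussian smoothing, detrend, zero-phase band-pass |
| `bsamap.ica` | seeded spatial ICA (`SpatialICA` estimator), component matching |
| `bsamap.labeling` | GoF template matching, spectral screen, neuronal count k |
| `bsamap.activity` | the BSA activity metric, ROI summaries |
| `bsamap.pet` | SUVR normalization, voxel-wise Pearson correlation |
| `bsamap.groupstats` | group comparison, associations, LOOCV linear SVM |
| `bsamap.phantom` | synthetic subjects/cohorts with ground truth |
| `bsamap.pipeline`, `bsamap.cli` | orchestration, manifest, `bsamap` CLI |

See `docs/methods.md` for the model, parameter choices, and limitations.
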