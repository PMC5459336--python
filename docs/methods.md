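# Methods

## Model and procedure

The package computes a per-voxel neuronal-activity magnitude from
resting-state BOLD data in five stages.

**Preprocessing.** Each time point is smoothed with an isotropic Gaussian
kernel (default FWHM 6 mm, converted to voxels per axis from the grid's voxel
sizes), each voxel's time course is linearly detrended, then band-pass
filtered to 0.01–0.1 Hz with an order-2 Butterworth applied forward-backward
(zero phase). Detrending guarantees exact DC removal — a constant series maps
to zero — and the forward-backward pass leaves band-limited signals without
group delay. Smoothing uses half-sample-symmetric (reflect) boundary
handling, which preserves the spatial mean of every time point to machine
precision; edge-replication boundaries do not, which is why reflection was
chosen. Smoothing is applied to the full field and the brain mask re-applied
afterwards, so edge voxels borrow intensity from just outside the mask.

**Spatial ICA.** The masked data matrix (voxels × time) is whitened by PCA to
the requested model order (default 30; the phantom studies use 8) and
decomposed by FastICA with symmetric (parallel) updates, logcosh contrast,
tolerance 1e-4, and at most 500 iterations, with sources independent over
*voxels* — each component is a spatial map paired with a time course. Scale
and sign are fixed by convention: time courses unit variance, amplitude
folded into the maps, and each component oriented so its spatial map has
positive skewness (the blob-like supra-threshold structure of a network map
is positive). The z-scored maps are what downstream stages consume; the raw
amplitude-carrying maps are kept for reconstruction. Runs are deterministic
per seed. When FastICA hits the iteration cap the fit is retried with up to
three derived seeds; if none converges the first fit is kept and a warning
logged. This is deliberate: when the model order exceeds the number of
non-Gaussian sources, the leftover whitened dimensions are isotropic Gaussian
noise on which the fixed-point update cannot settle — the convergence
criterion fails globally even though the structured components are estimated
as well as in converged runs (verified on phantom data: planted sources
recovered at |r| ≈ 0.99 in non-converged fits).

**Neuronal identification.** Each component's z-scored map is scored against
every resting-state-network template mask with a goodness-of-fit statistic:
mean map value inside the template minus mean over the brain mask outside it.
Each template is assigned to its highest-scoring component (ties to the
lowest index; several templates may share a component, which then counts once
toward k). A component is *neuronal* when it wins at least one template with
GoF ≥ 0 (configurable) and the fraction of its time-course spectral power
above 0.1 Hz is ≤ 0.5; a component failing the spectral screen is
*non-neuronal*; everything else is *undefined* and excluded from k. The
spectral screen is a deterministic stand-in for a trained per-component
classifier, which no public model exists for; externally produced labels can
be plugged in as a TSV override.

**Activity metric.** For voxel *i* and neuronal component *j*, BSA_ij(t) =
S_i(t)·W_j(t), and activity_i = Σ_j SD(BSA_ij)·NC_ij with NC the z-scored
map value. The default aggregation is the plain SD sum (`sum_sd`); the
square-root variant (`sum_sqrt_sd`) compresses the dynamic range and is kept
as a first-class option because both forms appear in descriptions of this
family of metrics. SD uses the sample (n−1) denominator by default;
configurable. NC values are signed and unthresholded; `clip_negative_nc`
zeroes negative weights for users who want a nonnegative map. Whole-brain
activity is the voxel *mean* over the brain mask (not the sum), so the
summary does not change with grid resolution.

**Downstream statistics.** PET images are normalized to the mean SUV of a
reference region (cerebellum by convention) to give SUVR; activity–SUVR
agreement is the Pearson r over a supplied (gray-matter) mask, with slope,
intercept, and the t-transform p-value (n−2 df). Group comparisons use an
omnibus one-way ANOVA over the stacked subject × feature observations with
group as the factor — one reading of an "ANOVA across regions" design, and a
flagged modelling choice — followed by per-feature Welch t-tests with
Bonferroni adjustment (factor = number of features, capped at 1).
Classification is a linear SVM (C = 1.0) under leave-one-out
cross-validation; features are standardized per fold with training-fold
statistics only, so no information leaks from the held-out subject; patient
is the positive class, and sensitivity/specificity carry Wilson 95%
intervals.

## The phantom

The generator emulates a down-scaled resting-state acquisition: 20×20×12
voxels at 3 mm isotropic, 150 volumes at TR 3 s, with an ellipsoidal brain
mask (~2000 voxels). Five Gaussian-blob sources (σ = 4.5 mm, truncated at
3σ, amplitude 1.0) carry band-limited time courses — sums of three
random-phase sinusoids drawn in 0.01–0.08 Hz, unit variance before amplitude
scaling. Noise comprises white Gaussian noise (SD 0.2, i.e. amplitude SNR 5
at a source center), a linear drift (0.001 per second), and whole-volume
spikes (2% of volumes, amplitude 2) that model scanner transients. Artifact
sources with white-noise time courses can be planted to give the spectral
screen true negatives. Patient subjects scale all neuronal amplitudes
(default 0.6) and lose sources at random (default 1 of 5), mimicking fewer
and weaker neuronal components. A PET-like surrogate is built by mixing the
standardized true activity with standardized independent noise at a chosen
correlation and mapping the result affinely into a positive range, so the
designed correlation is exact in the population sense.

Ground-truth activity is computed by running the noiseless sources through
the *same* activity code path (truth time courses normalized to unit
variance, truth maps z-scored), so the generator and the metric cannot drift
apart; an independent brute-force per-voxel loop in the test suite provides
the external check on that path.

What the phantom does **not** model: hemodynamic response shape, motion,
physiological (cardiac/respiratory) noise structure, spatial autocorrelation
of noise, EPI distortion, or partial-volume effects. Passing tests therefore
demonstrate the correctness and statistical behavior of the *algorithms*,
not performance on real clinical cohort data, whose headline numbers additionally
depend on acquisition and registration quality.

## Numerical choices and degenerate inputs

- Grids must match exactly (affine tolerance 1e-4); no resampling is ever
  performed — registration is an upstream responsibility.
- Band edges must satisfy 0 ≤ low < high < Nyquist; a zero low cut degrades
  to a low-pass with explicit mean removal. Series shorter than the
  filter's padding requirement are rejected rather than zero-padded.
- GoF requires the template to be a nonempty strict subset of the brain
  mask; constant maps score 0 by construction.
- k = 0 (no neuronal components) yields an all-zero activity map and a
  logged warning rather than an error.
- SUVR requires a strictly positive reference mean; zero or negative means
  signal wrong units and are rejected.
- Correlation requires ≥ 3 masked voxels and non-constant fields.
- LOOCV raises on any single-class training fold instead of silently
  skipping it.
- All stochastic stages take explicit integer seeds; derived seeds are
  produced with `numpy.random.SeedSequence` and kept below 2^31.

## Problem sizes used in the tests

The suite and the reproduction script run entirely on the 20×20×12×150
phantom (the cross-modal correlation check uses a 28×28×16 grid to exceed
5000 masked voxels). Replicate counts: 10 seeded runs for ICA recovery, 20
for neuronal-labeling recovery, 10 for the end-to-end map-recovery property,
15+15 subjects per classification cohort with a 100-permutation null in the
test suite (50 in the reproduction script). These sizes were chosen so the
whole suite completes in minutes on a single core while keeping the binomial
bounds of the ≥ 90/95% success criteria meaningful.

## Known limitations

- Single-subject spatial ICA only; group ICA with back-reconstruction (as
  used with multi-subject toolboxes) is out of scope, so component spaces
  differ between subjects and are aligned only through template matching.
- The spectral screen cannot reject artifacts whose power lies inside the
  pass band (e.g. slow drifts surviving detrend); such components fall to
  the template-matching stage.
- The GoF statistic uses signed map values by default; a network expressing
  as a deactivation would score negatively (an absolute-value variant is
  provided via `absolute_gof`).
- Signed NC weights can make activity negative in voxels anti-correlated
  with a network; interpretation of negative activity is left to the user
  (or suppressed with `clip_negative_nc`).
- The omnibus ANOVA layout stacks features of potentially different scales;
  for heterogeneous feature sets the per-feature Welch follow-ups are the
  interpretable quantities.
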