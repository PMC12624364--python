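# Methods

## Signal model and assumptions

The resting-state rCVR estimator assumes that the whole-brain mean BOLD
signal, band-limited to 0.02–0.04 Hz, is a usable surrogate for arterial CO2
fluctuation during natural breathing, and that a voxel's BOLD response to
that fluctuation is proportional to its vasodilatory capacity. Because the
surrogate has arbitrary units, only *relative* CVR is identified: voxel
slopes are normalized to the mean slope over white matter, which is far less
vascularized than gray matter and therefore a stable within-subject
reference (a whole-brain reference is available as `normalization_mode =
"global"`). Consequences of the model worth keeping in mind:

* rCVR is a ratio; any per-run intensity scaling cancels exactly.
* Anything that contaminates the 0.02–0.04 Hz band — neuronal fluctuations,
  cardiac/autonomic dynamics — biases β. The synthetic studies quantify this
  (see below); in real data it is an irreducible limitation of gas-free CVR.
* The voxel regression needs a meaningful temporal mean for the inverse-tSNR
  exclusion, so nuisance regression returns residuals *plus the voxel mean*.

## Pipeline parameters

| parameter | default | units | why |
|---|---|---|---|
| `band_cvr_hz` | (0.02, 0.04) | Hz | respiratory-volume frequency at rest |
| `band_fc_hz` | (0.008, 0.1) | Hz | conventional resting-state FC band |
| `fd_threshold_mm` | 0.25 | mm | censoring threshold (strict >) |
| `max_censored_fraction` | 0.25 | — | participant inclusion rule |
| `min_remaining_minutes` | 4 | min | participant inclusion rule |
| `smoothing_fwhm_mm` | 8 | mm | spatial smoothing kernel |
| `itsnr_percentile` | 98 | — | vessel/CSF voxel exclusion |
| `normalization_mode` | white_matter | — | rCVR reference tissue |
| `head_radius_mm` | 50 | mm | rotation→displacement conversion in FD |

FD uses the sum-of-absolute-backward-differences convention (translations in
mm plus 50 mm-scaled rotations); the first frame has FD = 0. "18 motion
parameters" is read as the 6 rigid-body parameters, their backward
differences, and their squares — the only reading that yields 18 columns.
Frames with FD strictly above 0.25 mm are censored by one-hot spike
regression, which at the kept frames is algebraically identical to deleting
the frames (verified by test). The mean-FD covariate used by the group
models is computed over *all* frames, pre-censoring, since it indexes
overall subject motion. Motion regressors enter as-is (no demeaning before
squaring); the intercept absorbs offsets, and the squared columns then also
carry linear leakage — harmless for nuisance removal, and noted here because
the alternative (demeaning first) is equally defensible.

Order of operations: nuisance regression (trend + motion + spikes) →
smoothing → surrogate extraction from the fully preprocessed data →
voxel-wise β → inverse-tSNR exclusion → normalization → regional averaging.
The surrogate is deliberately computed *after* cleaning so motion spikes
cannot leak into it. For FC, the nuisance design additionally carries mean
WM and CSF series over one-voxel-eroded masks (to limit gray-matter
partial-volume leakage); regression precedes the band-pass, with the
0.008–0.1 Hz zero-phase Butterworth applied voxel-wise afterwards.

Percentile convention for the inverse-tSNR exclusion: NumPy's
linear-interpolation percentile over in-mask voxels, exclusion strictly
above it, so an all-tied map excludes nothing and ~2 % of voxels are removed
on continuous data.

## Harmonization

ComBat is implemented in full (parametric empirical Bayes): site indicators
and biological covariates (diagnosis, sex as ±1 codes, mean-centered age)
are fit jointly; features are standardized by the covariate-predicted mean
and pooled residual SD; per-site location/scale estimates are shrunk toward
normal / inverse-gamma priors with method-of-moments hyperparameters,
iterating the conditional posterior means to 1e-4. Two deliberate choices:

* **ddof = 0 variances** throughout the standardization, which makes a
  single-site fit an exact identity transform (the reference R
  implementation uses ddof = 1 and is *not* an identity in that case; the
  test suite cross-checks against `sva::ComBat` at the tolerance this
  convention gap implies, ~1–2 % of the feature SD, with correlation
  > 0.999).
* **One model per feature family**: regional rCVR and seed-FC tables are
  harmonized separately; the API takes one table at a time.
* The diagnosis-by-sex interaction is *not* among the protected covariates
  by default (`include_interaction=True` adds it).

A property the parametric EB machinery cannot provide is exact idempotence:
re-harmonizing already-harmonized data re-estimates small residual site
effects (of order the shrinkage factor times the sampling noise of the
per-site means) and adjusts them again. The measured second-pass change is
~4e-3 relative under the validation scenario — small, but far from machine
precision. Exact idempotence would require disabling the EB shrinkage
entirely.

## Group statistics

OLS with classical standard errors, implemented directly (normal-equations
and statsmodels oracles in the tests). Effect coding: diagnosis ASD = −1 /
NA = +1, sex M = −1 / F = +1, interaction = product, so with balanced
noiseless cells the interaction coefficient equals
(μ_MA + μ_FN − μ_FA − μ_MN)/4 exactly. Age is re-centered within whatever
sample enters each model (full cohort or stratum); mean FD enters in raw mm.
All betas are reported signed, all p-values two-sided. The 91-region rCVR
scan reports uncorrected p-values (an exploratory characterization);
Benjamini–Hochberg FDR is applied only within each declared FC target
family. Post-hoc within-sex (or within-diagnosis) models use
outcome ~ predictor + age_centered + mean_fd. In the rCVR–FC association
models, FC is the response and seed rCVR the predictor.

## The synthetic cohort generator

Voxel signal: `B·(1 + g_v·s(t) + a_n·n_r(t)) + artifact + ε`, with baseline
B = 1000, thermal noise SD 20 (tSNR 50), the unit-variance CO2 surrogate
`s` built by brick-wall band-passing white noise to 0.02–0.04 Hz, and
unit-variance regional neuronal signals `n_r` band-limited to 0.008–0.1 Hz.
Geometry is a concentric-sphere phantom (WM core, GM shell parcellated into
compact angular sectors, CSF rim) on a 20³ grid of 4 mm voxels, 150 frames
at TR 2.5 s. Defaults and their rationale:

* **GM:WM gain ratio 3.5** (WM gain 0.004, i.e. 0.4 % signal change per
  surrogate SD; GM mean 1.4 %): white matter has roughly 70–75 % less
  vasculature than gray matter.
* **CSF gain 0.05**: CSF pulsation produces the largest resting
  fluctuations, which is precisely what the inverse-tSNR exclusion is meant
  to remove; with this default the excluded 2 % are CSF/vessel-like voxels
  and atlas (GM) regions are never emptied.
* **Neuronal amplitude 0.005** (0.5 % of baseline): a modest resting
  neuronal fluctuation. Its band overlaps the CO2 band, so it contaminates
  regional rCVR by ~0.17 rCVR units regardless of region size — the
  dominant error term at default settings, and a deliberate feature: the
  generator reproduces the main physical confound of gas-free CVR. The
  gain-recovery study isolates measurement noise by setting it to zero.
* **Subject-level regional noise SD 0.5 rCVR units**: calibrated so that,
  at the study's cell sizes (79/16/125/74 over 8 sites), coefficients of
  ~0.1–0.2 rCVR units land at the significance levels such designs report
  (the interaction-coefficient SE is ≈ 0.078·σ at those cell sizes).
* **Site effects** are injected on regional *summary features* (additive
  N(0, 0.2), multiplicative log-normal σ = 0.1, per site × region), after
  image-level generation — exactly the level harmonization operates on.
* **Motion**: per-subject drift |N(0, 0.01)| mm/frame and Poisson(1.5)
  spikes of 0.3–1.0 mm; spike frames additionally receive a spatial image
  artifact of SD 0.2·FD·B, which one-hot spike regression removes exactly.
* Inter-regional neuronal correlations are imposed *exactly* (band-limited
  white rows are orthonormalized, then mixed through the Cholesky factor of
  the target matrix), which requires the band to carry at least as many
  degrees of freedom as regions; the 91-region default uses independent
  signals, and correlation-recovery studies use smaller networks or
  generated pairs with a true population correlation.

What the generator does **not** emulate: k-space/susceptibility artifacts,
slice timing, registration error, spatially structured (non-spherical)
anatomy, hemodynamic delay between the surrogate and the voxel response,
heavy-tailed noise, or site differences at the image level. Passing tests
therefore validate the estimators and their algebra under the stated signal
model, not robustness to every artifact of real acquisitions.

## Problem sizes and numerical choices

Validation studies run at phantom scale: 20³ voxels for single-subject
studies, 16³ with 150 frames for the 294-subject × 25-replicate end-to-end
study (a few minutes on one CPU). At this scale the brain is ~5× smaller
than a real head, so the 8 mm kernel — appropriate at acquisition scale and
kept as the pipeline default — would span entire parcels; the phantom
analyses therefore run with smoothing disabled. Filtering uses zero-phase
`sosfiltfilt`; series shorter than the filter padding are rejected rather
than silently truncated. Correlations are clipped to 1 − 1e-12 before the
Fisher transform. Ties in the exclusion percentile resolve to "keep"
(strict inequality). Every simulation is a pure function of (inputs, seed),
and the pipeline writes a config-hash-keyed manifest with every run.

## Known limitations

* rCVR is relative: no %BOLD/mmHg units, no absolute comparison across
  normalization modes.
* The in-band neuronal contamination of β described above bounds per-subject
  regional accuracy at realistic amplitudes.
* Parametric EB harmonization is not exactly idempotent (see above) and
  leaves residual per-feature site differences of order the shrunk sampling
  noise.
* A motion-QC null check at the conventional α = 0.05 is expected to flag
  ~5 % of null cohorts; counts near that rate in small replicate sets are
  sampling noise, not association.
* The 91-region default parcellation is synthetic (angular sectors); real
  analyses should supply their own co-registered label volume and lookup.
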