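# restcvr

Relative cerebrovascular reactivity (rCVR) mapping from standard resting-state
BOLD fMRI — no gas challenge, no CO2 recording — together with the downstream
analyses such a study needs: seed-based functional connectivity, multi-site
(ComBat) harmonization of regional features, and region-wise group GLMs. A
synthetic multi-site cohort generator with a complete ground-truth manifest
makes every stage testable end to end.

## Who this is for

Neuroimaging researchers who want a cerebrovascular readout from rs-fMRI data
that was never acquired with CVR in mind (large repositories, pediatric or
clinical cohorts where hypercapnia protocols are impractical), and who need
to harmonize the resulting regional measures across acquisition sites before
group statistics.

## The method

Cerebrovascular reactivity is vasodilation per unit vasoactive stimulus.
During natural breathing, arterial CO2 fluctuates at the frequency of
respiratory-volume variation, 0.02–0.04 Hz, and that fluctuation is visible
in the global BOLD signal. The pipeline therefore:

1. **Preprocesses** each run: 18 motion regressors (6 rigid-body parameters,
   their temporal derivatives, their squares), a linear trend, and one spike
   regressor per frame with framewise displacement FD > 0.25 mm
   (FD = Σ|Δtranslation| + 50 mm · Σ|Δrotation|); then smooths with an 8 mm
   FWHM Gaussian kernel. Participants keep their data only if < 25 % of
   frames are censored and ≥ 4 minutes survive.
2. **Extracts the CO2 surrogate**: the whole-brain mean signal, band-passed
   to 0.02–0.04 Hz (zero-phase 4th-order Butterworth).
3. **Maps CVR**: per voxel, the OLS slope β of the BOLD series on the
   surrogate. Voxels whose inverse temporal SNR (temporal SD / temporal
   mean) exceeds the 98th percentile are excluded (vessels, CSF, artifact).
4. **Normalizes**: rCVR = β / mean β over white matter (which is much less
   vascularized than gray matter; a global-reference variant is available),
   then averages rCVR within gray-matter atlas regions (91 by default).
5. **Functional connectivity**: with additional WM/CSF nuisance regression
   and a 0.008–0.1 Hz band-pass, region-to-region FC is the Fisher
   z-transformed Pearson correlation of regional mean series.
6. **Harmonizes** regional rCVR and FC tables across sites with
   empirical-Bayes ComBat (location and scale), protecting diagnosis, sex
   and mean-centered age — one model per feature family.
7. **Group GLMs**: per region, outcome ~ diagnosis + sex + diagnosis×sex +
   mean-centered age + mean FD under ±1 effect coding (ASD = −1/NA = +1,
   M = −1/F = +1), with within-sex post-hoc models and rCVR–FC association
   models (BH-FDR over each connectivity target family).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate one subject with known regional gains and recover them:

```python
import numpy as np
from restcvr.synth import (AcquisitionConfig, SubjectTruth, default_geometry,
                           make_co2_surrogate, make_subject)
from restcvr.pipeline import PipelineConfig, process_subject

acq = AcquisitionConfig()                      # 150 frames, TR 2.5 s, tSNR 50
masks, atlas = default_geometry(acq.grid_shape, n_regions=91)
rng = np.random.default_rng(0)
true_ratio = np.clip(rng.normal(3.5, 0.5, 91), 1.5, None)   # true rCVR per region
truth = SubjectTruth(regional_cvr_gain=true_ratio * 0.004,
                     wm_cvr_gain=0.004, network_corr=np.eye(91))
surrogate = make_co2_surrogate(acq.n_frames, acq.tr_s, seed=1)
subject = make_subject(truth, acq, surrogate, seed=1, masks=masks, atlas=atlas)

cfg = PipelineConfig(smoothing_fwhm_mm=0.0)    # phantom-scale analysis
result = process_subject(subject.bold, masks, atlas, subject.motion, cfg)
print(f"GM mean rCVR: {result.gm_mean_rcvr:.2f} (true {true_ratio.mean():.2f})")
print(f"recovery r vs truth: {np.corrcoef(result.regional_rcvr, true_ratio)[0, 1]:.3f}")
```

prints

```
GM mean rCVR: 3.44 (true 3.55)
recovery r vs truth: 0.940
```

The gray-matter mean rCVR of ~3.5 reflects the injected gray:white gain
ratio; the per-region correlation of 0.94 is what thermal noise plus
band-overlapping neuronal fluctuations allow at this tSNR (it rises to
> 0.98 without the neuronal component, and recovery is exact to machine
precision on noiseless data — see the tests).

The same flow is available from the shell:

```bash
restcvr simulate --out data/ --seed 1            # NIfTI + motion + phenotypes
restcvr run-all --paper-mirror --out run/ --seed 1
```

`run-all` writes QC, regional rCVR tables (raw and harmonized), ComBat model
JSON, region-wise GLM tables and a run manifest keyed by the config hash.

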