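"""Synthetic-data generator: spectra, motion, signal model, cohort manifest."""

import numpy as np
import pytest
from scipy.signal import periodogram

from restcvr.preprocess import compute_fd
from restcvr.pipeline import PipelineConfig, process_subject
from restcvr.synth import (
    AcquisitionConfig,
    CohortConfig,
    CohortTruth,
    MotionSpec,
    SubjectTruth,
    apply_site_effects,
    default_geometry,
    make_co2_surrogate,
    make_cohort,
    make_feature_cohort,
    make_motion_trace,
    make_neuronal_signals,
    make_subject,
    plan_cohort,
)


class TestCo2Surrogate:
    @pytest.mark.parametrize("n,tr", [(150, 2.5), (200, 2.0), (120, 3.0)])
    def test_power_confined_to_band(self, n, tr):
        s = make_co2_surrogate(n, tr, (0.02, 0.04), seed=7)
        f, p = periodogram(s, fs=1 / tr)
        inband = p[(f >= 0.02) & (f <= 0.04)].sum() / p.sum()
        assert inband >= 0.95

    def test_standardized(self):
        s = make_co2_surrogate(150, 2.5, seed=3)
        assert abs(s.mean()) < 1e-6 and abs(s.std() - 1.0) < 1e-6

    def test_deterministic(self):
        a = make_co2_surrogate(150, 2.5, seed=11)
        b = make_co2_surrogate(150, 2.5, seed=11)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, make_co2_surrogate(150, 2.5, seed=12))

    @pytest.mark.parametrize("band", [(0.0, 0.04), (0.02, 0.3), (0.04, 0.02)])
    def test_invalid_band_rejected(self, band):
        with pytest.raises(ValueError):
            make_co2_surrogate(150, 2.5, band, seed=0)


class TestMotionTrace:
    def test_no_spikes_no_drift_gives_zero_fd(self):
        fd = compute_fd(make_motion_trace(100))
        assert (fd == 0).all()

    def test_spike_produces_fd_at_frame(self):
        trace = make_motion_trace(100, spike_frames=(10,), spike_amp_mm=0.5)
        fd = compute_fd(trace)
        assert fd[10] >= 0.495
        assert (np.delete(fd, 10) < 0.25).all()

    def test_drift_gives_constant_fd(self):
        fd = compute_fd(make_motion_trace(50, drift_mm_per_frame=0.02))
        np.testing.assert_allclose(fd[1:], 0.02, atol=1e-12)

    def test_spike_at_frame_zero_rejected(self):
        with pytest.raises(ValueError, match="spike frame 0"):
            make_motion_trace(100, spike_frames=(0,))


class TestNeuronalSignals:
    def test_exact_correlation_and_band(self):
        corr = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1.0]])
        sig = make_neuronal_signals(3, 150, 2.5, corr=corr, seed=2)
        np.testing.assert_allclose(np.corrcoef(sig), corr, atol=1e-10)
        f, p = periodogram(sig[0], fs=1 / 2.5)
        inband = p[(f >= 0.008) & (f <= 0.1)].sum() / p.sum()
        assert inband >= 0.99

    def test_insufficient_bandwidth_raises(self):
        with pytest.raises(ValueError, match="degrees"):
            make_neuronal_signals(91, 150, 2.5, corr=np.eye(91) * 0.5 + 0.5, seed=0)


class TestMakeSubject:
    def test_uniform_double_gain_recovers_rcvr_two(self, geometry_91):
        masks, atlas = geometry_91
        acq = AcquisitionConfig(noise_sd=0.0)
        truth = SubjectTruth(regional_cvr_gain=np.full(91, 0.008),
                             wm_cvr_gain=0.004, network_corr=np.eye(91))
        surr = make_co2_surrogate(acq.n_frames, acq.tr_s, seed=1)
        subj = make_subject(truth, acq, surr, seed=0, masks=masks, atlas=atlas,
                            neuronal_amp=0.0, motion_artifact_per_mm=0.0)
        res = process_subject(subj.bold, masks, atlas, subj.motion,
                              PipelineConfig(smoothing_fwhm_mm=0.0))
        np.testing.assert_allclose(res.regional_rcvr.to_numpy(), 2.0, atol=1e-6)

    def test_zero_surrogate_gives_constant_baseline(self, small_geometry):
        masks, atlas = small_geometry
        acq = AcquisitionConfig(noise_sd=0.0, grid_shape=(16, 16, 16))
        truth = SubjectTruth(regional_cvr_gain=np.full(20, 0.01),
                             wm_cvr_gain=0.004, network_corr=np.eye(20))
        subj = make_subject(truth, acq, np.zeros(acq.n_frames), seed=0,
                            masks=masks, atlas=atlas, neuronal_amp=0.0,
                            motion_artifact_per_mm=0.0)
        assert (subj.bold.data[masks.brain] == acq.baseline_intensity).all()

    def test_same_seed_identical(self, small_geometry):
        masks, atlas = small_geometry
        acq = AcquisitionConfig(grid_shape=(16, 16, 16))
        truth = SubjectTruth(regional_cvr_gain=np.full(20, 0.01),
                             wm_cvr_gain=0.004, network_corr=np.eye(20),
                             motion_spec=MotionSpec(spike_frames=(9,)))
        surr = make_co2_surrogate(acq.n_frames, acq.tr_s, seed=4)
        a = make_subject(truth, acq, surr, seed=5, masks=masks, atlas=atlas)
        b = make_subject(truth, acq, surr, seed=5, masks=masks, atlas=atlas)
        np.testing.assert_array_equal(a.bold.data, b.bold.data)

    def test_grid_mismatch_rejected(self, small_geometry):
        masks, atlas = small_geometry
        acq = AcquisitionConfig(grid_shape=(20, 20, 20))
        truth = SubjectTruth(regional_cvr_gain=np.full(20, 0.01),
                             wm_cvr_gain=0.004, network_corr=np.eye(20))
        with pytest.raises(ValueError, match="grid"):
            make_subject(truth, acq, np.zeros(acq.n_frames), masks=masks, atlas=atlas)


class TestGeometry:
    def test_masks_disjoint_and_labels_in_gm(self, geometry_91):
        masks, atlas = geometry_91
        assert not (masks.gm & masks.wm).any()
        assert not (masks.gm & masks.csf).any()
        assert (atlas.labels[~masks.gm] == 0).all()
        sizes = np.bincount(atlas.labels[masks.gm])[1:]
        assert sizes.min() >= 1 and len(sizes) == 91


class TestCohort:
    def test_paper_mirror_composition(self):
        cc = CohortConfig.paper_mirror(n_regions=5)
        truth = plan_cohort(cc, seed=0)
        pheno = truth.phenotype
        assert len(pheno) == 294
        cells = pheno.groupby(["diagnosis", "sex"]).size()
        assert cells[("NA", "F")] == 74 and cells[("ASD", "F")] == 16
        assert cells[("ASD", "M")] == 79 and cells[("NA", "M")] == 125
        assert pheno["site"].nunique() == 8

    def test_null_cohort_has_no_group_differences(self):
        cc = CohortConfig(
            cells={("ASD", "M"): 200, ("ASD", "F"): 200,
                   ("NA", "M"): 200, ("NA", "F"): 200},
            n_sites=1, n_regions=4, site_additive_sd=0.0,
            site_multiplicative_logsd=0.0,
        )
        feats, pheno, _ = make_feature_cohort(cc, seed=1)
        asd = (pheno["diagnosis"] == "ASD").to_numpy()
        gap = feats[asd].mean() - feats[~asd].mean()
        # between-group difference is 0 up to subject noise (SE ~ 0.5/sqrt(200))
        assert np.abs(gap).max() < 4 * 0.5 * np.sqrt(2 / 400)

    def test_interaction_contrast_matches_injected_coefficient(self):
        """With noiseless subject gains and balanced cells, the cell-mean
        contrast (mu_MA + mu_FN - mu_FA - mu_MN)/4 equals the injected
        interaction coefficient under the +/-1 coding."""
        g = 0.25
        cc = CohortConfig(
            cells={("ASD", "M"): 3, ("ASD", "F"): 3, ("NA", "M"): 3, ("NA", "F"): 3},
            n_sites=1, n_regions=3, subject_sd=0.0, site_additive_sd=0.0,
            site_multiplicative_logsd=0.0,
            effects={"diagnosis_x_sex": {"region_002": g}},
        )
        feats, pheno, _ = make_feature_cohort(cc, seed=3)
        mu = feats.groupby(
            [pheno["diagnosis"].to_numpy(), pheno["sex"].to_numpy()]
        ).mean()["region_002"]
        contrast = (mu[("ASD", "M")] + mu[("NA", "F")]
                    - mu[("ASD", "F")] - mu[("NA", "M")]) / 4
        assert contrast == pytest.approx(g, abs=1e-12)

    def test_unknown_effect_region_rejected(self):
        cc = CohortConfig(effects={"diagnosis": {"region_999": 0.1}})
        with pytest.raises(ValueError, match="unknown region"):
            plan_cohort(cc, seed=0)

    def test_truth_manifest_roundtrip(self):
        cc = CohortConfig(
            cells={("ASD", "M"): 2, ("ASD", "F"): 2, ("NA", "M"): 2, ("NA", "F"): 2},
            n_sites=2, n_regions=6, effects={"sex": {"region_001": 0.2}},
        )
        truth = plan_cohort(cc, seed=9)
        back = CohortTruth.from_json(truth.to_json())
        np.testing.assert_array_equal(back.base_ratio, truth.base_ratio)
        np.testing.assert_array_equal(
            back.site_additive.to_numpy(), truth.site_additive.to_numpy()
        )
        np.testing.assert_array_equal(
            back.subjects[3].regional_cvr_gain, truth.subjects[3].regional_cvr_gain
        )
        assert back.subjects[3].motion_spec == truth.subjects[3].motion_spec
        np.testing.assert_array_equal(
            back.group_effects["sex"], truth.group_effects["sex"]
        )
        assert back.phenotype.equals(truth.phenotype)

    def test_site_effects_applied_as_recorded(self):
        cc = CohortConfig(
            cells={("ASD", "M"): 2, ("ASD", "F"): 2, ("NA", "M"): 2, ("NA", "F"): 2},
            n_sites=2, n_regions=3,
        )
        truth = plan_cohort(cc, seed=4)
        feats = truth.true_features
        shifted = apply_site_effects(feats, truth.phenotype["site"].to_numpy(), truth)
        s = truth.phenotype["site"].iloc[0]
        expected = (feats.iloc[0] * truth.site_multiplicative.loc[s]
                    + truth.site_additive.loc[s])
        np.testing.assert_allclose(shifted.iloc[0].to_numpy(), expected.to_numpy())

    def test_make_cohort_deterministic(self):
        cc = CohortConfig(
            cells={("ASD", "M"): 1, ("ASD", "F"): 1, ("NA", "M"): 1, ("NA", "F"): 1},
            n_sites=1, n_regions=4, acq=AcquisitionConfig(grid_shape=(12, 12, 12),
                                                          n_frames=60),
        )
        subj_a, _ = make_cohort(cc, seed=6)
        subj_b, _ = make_cohort(cc, seed=6)
        for a, b in zip(subj_a, subj_b):
            np.testing.assert_array_equal(a.bold.data, b.bold.data)
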