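"""Group GLMs: coding, OLS against oracles, subgroup models, BH FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from restcvr.stats import (
    bh_fdr,
    build_design,
    cvr_fc_association,
    fit_glm,
    region_effects,
    relation_string,
    subgroup_effects,
)
from restcvr.synth import CohortConfig, make_feature_cohort


def _pheno(rows):
    df = pd.DataFrame(rows, columns=["diagnosis", "sex", "age_years", "mean_fd"])
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    df["site"] = "site01"
    return df


class TestBuildDesign:
    def test_autistic_female_codes(self):
        pheno = _pheno([("ASD", "F", 10.0, 0.1), ("NA", "M", 11.0, 0.2),
                        ("NA", "F", 9.5, 0.15), ("ASD", "M", 10.5, 0.12)])
        X, coding = build_design(pheno)
        row = X.iloc[0]
        assert (row["diagnosis"], row["sex"], row["diagnosis_x_sex"]) == (-1, 1, -1)
        assert coding["diagnosis"] == {"ASD": -1.0, "NA": 1.0}

    def test_age_centered_within_sample(self):
        pheno = _pheno([("ASD", "F", 9.0, 0.1), ("NA", "M", 12.0, 0.1),
                        ("NA", "F", 10.0, 0.1)])
        X, _ = build_design(pheno)
        assert abs(X["age_centered"].mean()) < 1e-12

    def test_constant_factor_rejected(self):
        pheno = _pheno([("ASD", "M", 10.0, 0.1), ("NA", "M", 11.0, 0.1),
                        ("ASD", "M", 9.5, 0.2)])
        with pytest.raises(ValueError, match="constant"):
            build_design(pheno)

    def test_unknown_level_rejected(self):
        pheno = _pheno([("autism", "F", 10.0, 0.1), ("NA", "M", 11.0, 0.1)])
        with pytest.raises(ValueError, match="autism"):
            build_design(pheno)

    def test_unknown_term_rejected(self):
        pheno = _pheno([("ASD", "F", 10.0, 0.1)])
        with pytest.raises(ValueError, match="unknown design terms"):
            build_design(pheno, terms=("intercept", "iq"))


class TestFitGlm:
    def test_zero_outcome_zero_coefficients(self, rng):
        X = pd.DataFrame({"intercept": np.ones(20), "x": rng.normal(size=20)})
        fit = fit_glm(np.zeros(20), X)
        np.testing.assert_allclose(fit.params.to_numpy(), 0.0, atol=1e-14)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(15, 50)), int(rng.integers(2, 5))
            A = rng.standard_normal((n, k))
            A[:, 0] = 1
            y = rng.standard_normal(n)
            X = pd.DataFrame(A, columns=[f"c{j}" for j in range(k)])
            mine = fit_glm(y, X)
            ref = sm.OLS(y, A).fit()
            np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-8)
            np.testing.assert_allclose(mine.bse.to_numpy(), ref.bse, atol=1e-8)
            np.testing.assert_allclose(mine.pvalues.to_numpy(), ref.pvalues, atol=1e-8)
            assert mine.df_resid == ref.df_resid

    def test_cell_mean_contrast_closed_form(self):
        """Noiseless balanced cells mu_FA=1.2, mu_MA=1.0, mu_FN=0.9,
        mu_MN=1.0 give interaction = (mu_MA+mu_FN-mu_FA-mu_MN)/4 = -0.075."""
        cells = {("ASD", "F"): 1.2, ("ASD", "M"): 1.0,
                 ("NA", "F"): 0.9, ("NA", "M"): 1.0}
        rows, y = [], []
        for (dx, sex), mu in cells.items():
            for i in range(5):
                rows.append((dx, sex, 10.0 + 0.1 * i, 0.1))
                y.append(mu)
        pheno = _pheno(rows)
        X, coding = build_design(pheno, ("intercept", "diagnosis", "sex",
                                         "diagnosis_x_sex"))
        fit = fit_glm(np.array(y), X, coding)
        assert fit.params["diagnosis_x_sex"] == pytest.approx(-0.075, abs=1e-12)
        assert fit.params["diagnosis"] == pytest.approx(
            (1.0 + 0.9 - 1.2 - 1.0) / 4, abs=1e-12
        )

    def test_rank_deficiency_rejected(self, rng):
        A = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_glm(rng.normal(size=10), pd.DataFrame(A, columns=list("abc")))

    def test_underdetermined_rejected(self, rng):
        A = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="more observations"):
            fit_glm(rng.normal(size=3), pd.DataFrame(A, columns=list("abcd")))


class TestRegionEffects:
    def _cohort(self, **kw):
        cc = CohortConfig.paper_mirror(n_regions=6, n_sites=1, site_additive_sd=0.0,
                                       site_multiplicative_logsd=0.0, **kw)
        return make_feature_cohort(cc, seed=3)

    def test_one_row_per_region_and_term(self):
        feats, pheno, _ = self._cohort()
        tab = region_effects(feats, pheno)
        assert len(tab) == 6 * 3
        assert set(tab["term"]) == {"diagnosis", "sex", "diagnosis_x_sex"}

    def test_mostly_missing_region_skipped(self, caplog):
        feats, pheno, _ = self._cohort()
        feats.iloc[: int(0.3 * len(feats)), 0] = np.nan
        tab = region_effects(feats, pheno)
        assert "region_001" not in set(tab["region"])
        assert len(tab) == 5 * 3

    def test_betas_signed(self):
        feats, pheno, _ = self._cohort(
            effects={"diagnosis": {"region_002": 0.4, "region_003": -0.4}}
        )
        tab = region_effects(feats, pheno).set_index(["region", "term"])
        assert tab.loc[("region_002", "diagnosis"), "beta"] > 0
        assert tab.loc[("region_003", "diagnosis"), "beta"] < 0


class TestSubgroupEffects:
    def test_female_specific_effect_isolated(self):
        """A diagnosis effect injected only through the interaction+main
        combination (female effect, zero male effect) shows up in the female
        stratum and not the male one."""
        g = 0.6
        cc = CohortConfig(
            cells={("ASD", "M"): 80, ("ASD", "F"): 80,
                   ("NA", "M"): 80, ("NA", "F"): 80},
            n_sites=1, n_regions=3, subject_sd=0.1, site_additive_sd=0.0,
            site_multiplicative_logsd=0.0,
            effects={"diagnosis": {"region_001": -g / 4},
                     "diagnosis_x_sex": {"region_001": -g / 4}},
        )
        feats, pheno, _ = make_feature_cohort(cc, seed=8)
        tab = subgroup_effects(feats, pheno, split="sex", term="diagnosis",
                               regions=["region_001"]).set_index("stratum")
        # female diagnosis coefficient = -(ASD-NA difference)/2 = -g/2
        assert tab.loc["sex=F", "beta"] == pytest.approx(-g / 2, abs=0.05)
        assert abs(tab.loc["sex=M", "beta"]) < 0.05

    def test_small_stratum_warns(self):
        cc = CohortConfig(cells={("ASD", "M"): 20, ("ASD", "F"): 3,
                                 ("NA", "M"): 20, ("NA", "F"): 4},
                          n_sites=1, n_regions=2)
        feats, pheno, _ = make_feature_cohort(cc, seed=2)
        with pytest.warns(UserWarning, match="only"):
            subgroup_effects(feats, pheno, split="sex", term="diagnosis")

    def test_deterministic(self):
        cc = CohortConfig(n_sites=1, n_regions=2)
        feats, pheno, _ = make_feature_cohort(cc, seed=4)
        a = subgroup_effects(feats, pheno, split="sex", term="diagnosis")
        b = subgroup_effects(feats, pheno, split="sex", term="diagnosis")
        pd.testing.assert_frame_equal(a, b)


class TestCvrFcAssociation:
    def _data(self, n_targets=10, slope=0.4, seed=0):
        rng = np.random.default_rng(seed)
        cc = CohortConfig.paper_mirror(n_regions=2, n_sites=1, site_additive_sd=0.0,
                                       site_multiplicative_logsd=0.0)
        feats, pheno, _ = make_feature_cohort(cc, seed=seed)
        rcvr = feats["region_001"]
        fc = pd.DataFrame(
            {f"t{i}": rng.normal(0, 0.2, len(pheno)) for i in range(n_targets)},
            index=feats.index,
        )
        fc["t0"] = slope * rcvr + rng.normal(0, 0.1, len(pheno))
        return rcvr, fc, pheno, slope

    def test_slope_recovered_within_two_se(self):
        rcvr, fc, pheno, slope = self._data()
        tab = cvr_fc_association(rcvr, fc, pheno, "females").set_index("target")
        assert abs(tab.loc["t0", "beta"] - slope) < 2 * tab.loc["t0", "se"]

    def test_unrelated_targets_controlled_by_fdr(self):
        rcvr, fc, pheno, _ = self._data(n_targets=20)
        tab = cvr_fc_association(rcvr, fc, pheno, "males").set_index("target")
        others = tab.drop(index="t0")
        assert (others["p_fdr"] > 0.05).mean() >= 0.9

    def test_family_size_excludes_seed(self):
        rcvr, fc, pheno, _ = self._data(n_targets=90)
        tab = cvr_fc_association(rcvr, fc, pheno, "females")
        assert len(tab) == 90 and "p_fdr" in tab.columns

    def test_constant_rcvr_rejected(self):
        rcvr, fc, pheno, _ = self._data()
        with pytest.raises(ValueError, match="zero variance"):
            cvr_fc_association(pd.Series(np.ones(len(pheno)), index=rcvr.index),
                               fc, pheno, "females")


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr(np.ones(5)), np.ones(5))

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(2, 120)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_monotone_and_order_invariant(self, p_list):
        p = np.asarray(p_list)
        adj = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm], atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


def test_relation_string_reflects_injected_pattern():
    cc = CohortConfig(
        cells={("ASD", "M"): 60, ("ASD", "F"): 60, ("NA", "M"): 60, ("NA", "F"): 60},
        n_sites=1, n_regions=2, subject_sd=0.1, site_additive_sd=0.0,
        site_multiplicative_logsd=0.0,
        effects={"diagnosis": {"region_001": -0.2},
                 "diagnosis_x_sex": {"region_001": -0.2}},
    )
    feats, pheno, _ = make_feature_cohort(cc, seed=1)
    rel = relation_string(feats, pheno, "region_001")
    assert "Females: ASD>NA" in rel
    assert "Males: ASD~NA" in rel
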