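"""Voxel-wise mixed-effects engine: oracle equivalence, calibration, effect sizes."""

import numpy as np
import pytest

from lnsim.lme import (VoxelLME, direct_fc_longitudinal, effect_size_eta2,
                       predicted_connectivity_at_adl, simulate_lme_responses)

from conftest import LME_NAMES, lme_design


class TestFitAccuracy:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        exog, groups = lme_design(rng)
        beta = np.array([0.5, -0.005, 0.0, 0.0, 0.0])
        endog = np.tile((exog @ beta)[:, None], (1, 3))
        res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
        assert np.max(np.abs(res.coef("adl") + 0.005)) <= 1e-8

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        exog, groups = lme_design(rng)
        endog = simulate_lme_responses(exog, groups,
                                       [0.9, -0.005, 0.001, 0.02, -0.05],
                                       re_sd=0.08, resid_sd=0.1, n_voxels=5, rng=rng)
        res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
        for v in range(5):
            ref = sm.MixedLM(endog[:, v], exog, groups=groups).fit(reml=True)
            assert res.params[1, v] == pytest.approx(ref.params[1], abs=2e-5)
            assert res.bse[1, v] == pytest.approx(ref.bse[1], rel=2e-2)

    def test_mean_estimate_within_two_se_of_truth(self):
        rng = np.random.default_rng(2)
        true_b = -0.005
        est, ses = [], []
        for _ in range(200):
            exog, groups = lme_design(rng)
            endog = simulate_lme_responses(exog, groups,
                                           [0.9, true_b, 0.0, 0.0, 0.0],
                                           0.08, 0.1, 1, rng)
            res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
            est.append(res.coef("adl")[0])
            ses.append(res.bse[1, 0])
        mean_se = np.mean(ses) / np.sqrt(200)
        assert abs(np.mean(est) - true_b) <= 2 * mean_se

    def test_between_within_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        exog, groups = lme_design(rng, n_subjects=17)
        endog = simulate_lme_responses(exog, groups, [0.5, 0, 0, 0, 0],
                                       0.1, 0.1, 2, rng)
        res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
        inner = ~res.boundary
        assert np.all(res.df[inner] == 51 - 5 - 17 + 1)


class TestEffectSize:
    def test_zero_t_gives_zero_eta2(self):
        rng = np.random.default_rng(4)
        exog, groups = lme_design(rng)
        endog = simulate_lme_responses(exog, groups, [0.5, 0, 0, 0, 0],
                                       0.05, 0.1, 4, rng)
        res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
        res.tvalues[1, :] = 0.0
        assert np.all(effect_size_eta2(res, "adl") == 0.0)

    def test_t_squared_equal_df_gives_half(self):
        rng = np.random.default_rng(5)
        exog, groups = lme_design(rng)
        endog = simulate_lme_responses(exog, groups, [0.5, 0, 0, 0, 0],
                                       0.05, 0.1, 1, rng)
        res = VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()
        res.tvalues[1, 0] = np.sqrt(res.df[0])
        assert effect_size_eta2(res, "adl")[0] == pytest.approx(0.5)

    def test_matches_sums_of_squares_oracle_without_random_effects(self):
        """Fixed-effects-only data: partial eta^2 equals SS_eff/(SS_eff+SS_res)."""
        rng = np.random.default_rng(6)
        exog, groups = lme_design(rng)
        # no subject effect at all: the fit lands on the OLS boundary
        endog = exog @ np.array([0.5, -0.004, 0.001, 0.02, -0.01]) \
            + 0.05 * rng.standard_normal(exog.shape[0])
        res = VoxelLME(endog[:, None], exog, groups, exog_names=LME_NAMES).fit()
        if not res.boundary[0]:
            pytest.skip("random-effect variance not on the boundary for this draw")
        # oracle: residual SS of full vs ADL-deleted OLS models
        beta_full, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        rss_full = np.sum((endog - exog @ beta_full) ** 2)
        x_red = np.delete(exog, 1, axis=1)
        beta_red, *_ = np.linalg.lstsq(x_red, endog, rcond=None)
        rss_red = np.sum((endog - x_red @ beta_red) ** 2)
        ss_eff = rss_red - rss_full
        oracle = ss_eff / (ss_eff + rss_full)
        assert effect_size_eta2(res, "adl")[0] == pytest.approx(oracle, abs=1e-6)


class TestTypeIAndCoverage:
    def test_null_rejection_rate_and_ci_coverage(self):
        rng = np.random.default_rng(7)
        rej, cover, est = [], [], []
        true_b = -0.005
        for _ in range(200):
            exog, groups = lme_design(rng)
            null = simulate_lme_responses(exog, groups, [0.5, 0, 0, 0, 0],
                                          0.08, 0.1, 40, rng)
            res = VoxelLME(null, exog, groups, exog_names=LME_NAMES).fit()
            rej.append((res.pvalue("adl") < 0.05).mean())

            alt = simulate_lme_responses(exog, groups, [0.9, true_b, 0, 0, 0],
                                         0.08, 0.1, 5, rng)
            res_a = VoxelLME(alt, exog, groups, exog_names=LME_NAMES).fit()
            ci = res_a.conf_int("adl")
            cover.append(((ci[0] <= true_b) & (true_b <= ci[1])).mean())
            est.append(res_a.coef("adl").mean())
        assert abs(np.mean(rej) - 0.05) <= 0.02
        assert 0.92 <= np.mean(cover) <= 0.98
        assert abs(np.mean(est) - true_b) <= 0.05 * abs(true_b)


class TestPredictedMaps:
    def _fit(self, beta, rng):
        exog, groups = lme_design(rng)
        endog = simulate_lme_responses(exog, groups, beta, 0.05, 0.08, 6, rng)
        return VoxelLME(endog, exog, groups, exog_names=LME_NAMES).fit()

    def test_zero_adl_effect_gives_identical_maps(self):
        res = self._fit([0.5, 0.0, 0.001, 0.02, -0.01], np.random.default_rng(8))
        res.params[1, :] = 0.0  # exact null for the prediction identity
        maps = predicted_connectivity_at_adl(res, levels=(47.0, 65.0, 83.0))
        assert np.allclose(maps[47.0], maps[65.0])
        assert np.allclose(maps[65.0], maps[83.0])

    def test_midpoint_level_is_voxelwise_average(self):
        res = self._fit([0.5, -0.004, 0.001, 0.02, -0.01], np.random.default_rng(9))
        maps = predicted_connectivity_at_adl(res, levels=(47.0, 65.0, 83.0))
        assert len(maps) == 3
        assert np.max(np.abs(maps[65.0] - (maps[47.0] + maps[83.0]) / 2.0)) <= 1e-10

    def test_extrapolation_warns(self):
        res = self._fit([0.5, -0.004, 0.0, 0.0, 0.0], np.random.default_rng(10))
        with pytest.warns(UserWarning, match="outside the observed range"):
            predicted_connectivity_at_adl(res, levels=(150.0,))


class TestDirectFcLongitudinal:
    @staticmethod
    def _setup(seed, lesion_activity=(0.0, 0.0, 0.0)):
        from lnsim.cohort import simulate_cohort
        from lnsim.lesion_network import build_fc_stack, derive_ln_template, threshold_ln
        from conftest import clean, small_cohort_config

        cfg = small_cohort_config(n_patients=5, pool_local=4, pool_remote=11,
                                  lesion_activity_by_visit=lesion_activity)
        cohort = simulate_cohort(cfg, seed)
        cleans = {c.subject_id: clean(cohort, c.subject_id, 1)
                  for c in cohort.controls[:8]}
        records = {c.subject_id: c for c in cohort.controls}
        tpl = derive_ln_template(build_fc_stack(cleans, records, cohort.patients,
                                                cohort.lesion_masks))
        core = threshold_ln(tpl, p_voxel=1e-5, min_cluster_mm3=108.0)
        patient_cleans = [clean(cohort, p.subject_id, v) for p in cohort.patients
                          for v in (1, 2, 3)]
        return cohort, core, patient_cleans

    def test_summary_has_three_rows_per_region(self):
        cohort, core, cleans = self._setup(40)
        assert len(core) >= 1
        summary, tests = direct_fc_longitudinal(cleans, cohort.lesion_masks, core)
        for _, grp in summary.groupby("region_id"):
            assert sorted(grp["visit"]) == [1, 2, 3]
        assert set(tests.columns) == {"region_id", "visit_coef", "visit_t", "visit_p"}

    def test_constant_coupling_rarely_significant(self):
        hits = total = 0
        for seed in range(50, 55):
            cohort, core, cleans = self._setup(seed)
            if not len(core):
                continue
            _, tests = direct_fc_longitudinal(cleans, cohort.lesion_masks, core)
            hits += int((tests["visit_p"] < 0.05).sum())
            total += len(tests)
        assert total >= 5
        assert hits / total <= 0.10

    def test_increasing_coupling_detected_in_network_regions(self):
        """Rising lesion coupling is detected in core regions that genuinely
        overlap the planted network (other core blobs are noise and stay flat)."""
        import numpy as np

        detected = total = 0
        for seed in range(60, 65):
            cohort, core, cleans = self._setup(seed, lesion_activity=(0.0, 0.75, 1.5))
            if not len(core):
                continue
            net = cohort.network
            network_mask = np.zeros(cohort.config.grid.shape, bool)
            for i in range(net.n_nodes):
                if i not in net.compensation_nodes:
                    network_mask |= net.node_mask(i)
            _, tests = direct_fc_longitudinal(cleans, cohort.lesion_masks, core)
            for row in core.itertuples():
                vox = np.asarray(row.voxels)
                if not network_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any():
                    continue
                p = float(tests.loc[tests["region_id"] == row.cluster_id,
                                    "visit_p"].iloc[0])
                detected += p < 0.05
                total += 1
        assert total >= 4
        assert detected / total >= 0.8

    def test_empty_core_regions_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="core region"):
            direct_fc_longitudinal([], {}, pd.DataFrame())
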