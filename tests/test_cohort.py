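"""Synthetic cohort generator: determinism, planted structure, geometry."""

import numpy as np
import pytest

from lnsim.cohort import (CohortConfig, VisitRecord, SubjectRecord,
                          generate_network_spec, simulate_bold_run,
                          simulate_cohort)
from lnsim.errors import MatchingInfeasibleError, PlacementError
from lnsim.grid import GridSpec, load_nifti, save_nifti

from conftest import small_cohort_config


def _control(sid="C0001", motion=0.4):
    return SubjectRecord(sid, "control", 60.0, "male", "local",
                         [VisitRecord(1, None, None, motion)])


class TestNetworkSpec:
    def test_deterministic_for_fixed_seed(self):
        g = GridSpec((16, 18, 16))
        a = generate_network_spec(g, 6, seed=5)
        b = generate_network_spec(g, 6, seed=5)
        assert np.array_equal(a.weights, b.weights)
        for ra, rb in zip(a.node_regions, b.node_regions):
            assert np.array_equal(ra, rb)

    def test_regions_disjoint_and_inside_brain_mask(self):
        # brute-force voxel membership scan on the default-sized grid
        g = GridSpec((24, 28, 24))
        spec = generate_network_spec(g, 10, seed=3)
        mask = g.brain_mask()
        seen = set()
        for reg in spec.node_regions:
            for v in map(tuple, reg):
                assert v not in seen, "regions overlap"
                seen.add(v)
                assert mask[v], "region voxel outside the brain mask"
        assert len(spec.node_regions) == 10

    def test_grid_too_small_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_network_spec(GridSpec((8, 8, 8)), 40, seed=0)

    def test_compensation_weights_orthogonal_to_lesion(self):
        spec = generate_network_spec(GridSpec((16, 18, 16)), 6, seed=2,
                                     n_compensation=2)
        for i in spec.compensation_nodes:
            assert abs(spec.weights[0] @ spec.weights[i]) < 1e-12

    def test_network_nodes_overlap_lesion_weights(self):
        spec = generate_network_spec(GridSpec((16, 18, 16)), 8, seed=2,
                                     n_compensation=2,
                                     lesion_overlap_range=(0.35, 0.8))
        for i in range(3, spec.n_nodes):
            rho = spec.weights[0] @ spec.weights[i]
            assert 0.35 - 1e-12 <= rho <= 0.8 + 1e-12


class TestSimulateBoldRun:
    def test_full_similarity_gives_unit_signal_correlation(self):
        # s = 1, no noise: compensation node signal equals the lesion mixture
        spec = generate_network_spec(GridSpec((14, 16, 14)), 5, seed=1)
        kw = dict(n_timepoints=80, noise_sd=0.0, signal_sd=1.0, seed=9)
        run = simulate_bold_run(spec, _control(), 1, similarity=1.0,
                                lesion_activity=1.0, **kw)
        lesion_sig = run.data[tuple(spec.node_regions[0][0])]
        comp_sig = run.data[tuple(spec.node_regions[1][0])]
        assert np.corrcoef(lesion_sig, comp_sig)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_similarity_signal_uncorrelated_in_expectation(self):
        spec = generate_network_spec(GridSpec((14, 16, 14)), 5, seed=1)
        run = simulate_bold_run(spec, _control(), 1, similarity=0.0,
                                lesion_activity=1.0, n_timepoints=130,
                                noise_sd=0.0, signal_sd=1.0, seed=9)
        lesion_sig = run.data[tuple(spec.node_regions[0][0])]
        comp_sig = run.data[tuple(spec.node_regions[1][0])]
        # orthogonal mixing weights: only sampling correlation remains
        assert abs(np.corrcoef(lesion_sig, comp_sig)[0, 1]) < 0.35

    def test_noiseless_same_node_voxels_identical(self):
        spec = generate_network_spec(GridSpec((14, 16, 14)), 5, seed=1)
        run = simulate_bold_run(spec, _control(), 1, noise_sd=0.0, seed=4,
                                n_timepoints=60, lesion_activity=1.0)
        reg = spec.node_regions[3]
        assert np.allclose(run.data[tuple(reg[0])], run.data[tuple(reg[1])])

    def test_patient_lesion_node_emits_pure_noise(self):
        spec = generate_network_spec(GridSpec((14, 16, 14)), 5, seed=1)
        patient = SubjectRecord("P001", "patient", 60.0, "male", "local",
                                [VisitRecord(v, 2.0, 50.0, 0.4) for v in (1, 2, 3)])
        run = simulate_bold_run(spec, patient, 1, seed=4, noise_sd=0.0,
                                n_timepoints=60)
        assert np.allclose(run.data[tuple(spec.node_regions[0][0])], 0.0)

    def test_invalid_visit_rejected(self):
        spec = generate_network_spec(GridSpec((14, 16, 14)), 5, seed=1)
        with pytest.raises(ValueError, match="visit"):
            simulate_bold_run(spec, _control(), 2, seed=0)


class TestSimulateCohort:
    def test_default_config_counts(self):
        cfg = CohortConfig()
        assert cfg.n_patients == 17
        assert cfg.n_patients * 3 == 51  # patient runs
        assert cfg.adl_means == (32.2, 75.3, 88.4)
        assert cfg.pool_size >= 3 * cfg.n_patients

    def test_cohort_is_deterministic(self):
        cfg = small_cohort_config()
        a = simulate_cohort(cfg, 21)
        b = simulate_cohort(cfg, 21)
        assert a.covariate_table().equals(b.covariate_table())
        ra = a.run("P001", 2)
        rb = b.run("P001", 2)
        assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(ra.motion_trace, rb.motion_trace)

    def test_adl_rises_and_matches_trajectory(self):
        cohort = simulate_cohort(small_cohort_config(n_patients=17,
                                                     pool_local=6, pool_remote=45), 3)
        adls = np.array([[v.adl for v in p.visits] for p in cohort.patients])
        assert np.all(np.diff(adls, axis=1) >= 0)
        assert np.all((adls >= 0) & (adls <= 100))
        means = adls.mean(axis=0)
        for got, want, sd in zip(means, (32.2, 75.3, 88.4), (6.3, 18.2, 16.8)):
            assert abs(got - want) < 3 * sd / np.sqrt(17) + 1.0

    def test_constant_decay_schedule_has_zero_planted_effect(self):
        cohort = simulate_cohort(small_cohort_config(constant_similarity=True), 5)
        assert cohort.truth.planted_adl_effect_is_zero
        s_vals = [cohort.truth.similarity[(p.subject_id, v)]
                  for p in cohort.patients for v in (1, 2, 3)]
        assert len(set(np.round(s_vals, 12))) == 1

    def test_planted_similarity_decreases_with_visits(self):
        cohort = simulate_cohort(small_cohort_config(), 7)
        for p in cohort.patients:
            s = [cohort.truth.similarity[(p.subject_id, v)] for v in (1, 2, 3)]
            assert s[0] >= s[1] >= s[2]

    def test_lesion_and_compensation_masks_disjoint(self, small_cohort):
        truth = small_cohort.truth
        for m in truth.compensation_masks:
            assert not (truth.lesion_mask & m).any()

    def test_empirical_signal_correlation_tracks_planted_decay(self):
        """Noiseless compensation/lesion signal correlation falls across visits."""
        cfg = small_cohort_config(noise_sd=0.0)
        cohort = simulate_cohort(cfg, 13)
        spec = cohort.network
        comp_vox = tuple(spec.node_regions[spec.compensation_nodes[0]][0])
        pat = cohort.patients[0]
        corrs = []
        for v in (1, 2, 3):
            s = cohort.truth.similarity[(pat.subject_id, v)]
            run = simulate_bold_run(spec, pat, v, cohort.seed, similarity=s,
                                    lesion_activity=1.0, noise_sd=0.0,
                                    n_timepoints=cfg.n_timepoints)
            lesion_sig = run.data[tuple(spec.node_regions[0][0])]
            corrs.append(np.corrcoef(run.data[comp_vox], lesion_sig)[0, 1])
        assert corrs[0] > corrs[1] > corrs[2]

    def test_pool_too_small_raises(self):
        with pytest.raises(MatchingInfeasibleError):
            simulate_cohort(small_cohort_config(pool_local=2, pool_remote=2), 0)


def test_nifti_round_trip(tmp_path, small_grid):
    rng = np.random.default_rng(0)
    data = rng.standard_normal(small_grid.shape)
    save_nifti(data, small_grid, tmp_path / "x.nii.gz")
    loaded, grid = load_nifti(tmp_path / "x.nii.gz")
    assert grid == small_grid
    assert np.array_equal(loaded, data)


def test_cohort_write_outputs(tmp_path, small_cohort):
    small_cohort.write(tmp_path, runs=True, subjects=["P001"])
    assert (tmp_path / "covariates.tsv").exists()
    assert (tmp_path / "truth.json").exists()
    data, grid = load_nifti(tmp_path / "P001_visit1_bold.nii.gz")
    assert data.shape == grid.shape + (small_cohort.config.n_timepoints,)
    assert np.array_equal(data, small_cohort.run("P001", 1).data)
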