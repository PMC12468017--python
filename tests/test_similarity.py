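"""Voxel connectivity profiles and lesion-network-similarity maps."""

import numpy as np
import pytest

from lnsim.cohort import simulate_cohort
from lnsim.errors import DegenerateTemplateError
from lnsim.grid import GridSpec
from lnsim.lesion_network import LNTemplate, fisher_z
from lnsim.qc import CleanRun
from lnsim.similarity import similarity_map, voxel_fc_profile

from conftest import clean, small_cohort_config

GRID = GridSpec((10, 10, 10))
MASK = np.ones(GRID.shape, dtype=bool)


def make_clean(data):
    t = data.shape[-1]
    return CleanRun(data=data, kept_index=np.arange(t), band=(0.009, 0.08),
                    smoothing_fwhm_mm=None, tr_seconds=3.0, grid=GRID,
                    brain_mask=MASK, subject_id="X", visit=1)


def make_template(values):
    return LNTemplate(intercept=values, t_map=np.zeros(GRID.shape),
                      p_map=np.ones(GRID.shape), residuals=np.zeros((2, MASK.sum())),
                      mask=MASK, grid=GRID, n_maps=2, df_resid=1)


class TestVoxelFcProfile:
    def test_profile_excludes_the_seed_voxel(self):
        data = np.random.default_rng(0).standard_normal(GRID.shape + (30,))
        prof = voxel_fc_profile(make_clean(data), (4, 4, 4), MASK)
        assert prof.shape == (MASK.sum() - 1,)

    def test_matches_brute_force_pairwise_correlations(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal(GRID.shape + (40,))
        vox = (3, 7, 2)
        prof = voxel_fc_profile(make_clean(data), vox, MASK)
        coords = np.argwhere(MASK)
        seed_idx = int(np.flatnonzero((coords == np.array(vox)).all(1))[0])
        brute = [np.corrcoef(data[vox], data[tuple(c)])[0, 1]
                 for i, c in enumerate(coords) if i != seed_idx]
        assert np.max(np.abs(prof - fisher_z(np.array(brute)))) <= 1e-10

    def test_outside_mask_rejected(self):
        data = np.random.default_rng(2).standard_normal(GRID.shape + (30,))
        mask = MASK.copy()
        mask[0, 0, 0] = False
        clean_ = make_clean(data)
        clean_.brain_mask = mask
        with pytest.raises(ValueError, match="outside"):
            voxel_fc_profile(clean_, (0, 0, 0), mask)


class TestSimilarityMap:
    def test_invariant_to_positive_affine_template_rescaling(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal(GRID.shape + (40,))
        tvals = rng.standard_normal(GRID.shape)
        a = similarity_map(make_clean(data), make_template(tvals), MASK)
        b = similarity_map(make_clean(data), make_template(3.0 * tvals + 1.5), MASK)
        assert np.nanmax(np.abs(a.values - b.values)) <= 1e-10

    def test_template_equal_to_own_profile_hits_clip(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal(GRID.shape + (40,))
        run = make_clean(data)
        vox = (5, 5, 5)
        prof = voxel_fc_profile(run, vox, MASK)
        tvals = np.zeros(GRID.shape)
        coords = np.argwhere(MASK)
        seed_idx = int(np.flatnonzero((coords == np.array(vox)).all(1))[0])
        full = np.insert(prof, seed_idx, 0.0)
        tvals[MASK] = full
        sm = similarity_map(run, make_template(tvals), MASK)
        assert sm.values[vox] == pytest.approx(np.arctanh(0.999))

    def test_constant_template_raises(self):
        data = np.random.default_rng(5).standard_normal(GRID.shape + (30,))
        with pytest.raises(DegenerateTemplateError):
            similarity_map(make_clean(data), make_template(np.ones(GRID.shape)), MASK)

    def test_subset_voxels_match_full_map(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal(GRID.shape + (40,))
        tvals = rng.standard_normal(GRID.shape)
        full = similarity_map(make_clean(data), make_template(tvals), MASK)
        subset = np.array([[1, 2, 3], [4, 5, 6], [9, 9, 9]])
        part = similarity_map(make_clean(data), make_template(tvals), MASK,
                              voxels=subset)
        for v in map(tuple, subset):
            assert part.values[v] == pytest.approx(full.values[v], abs=1e-12)
        assert np.isnan(part.values[0, 0, 0])

    def test_blockwise_equals_voxel_at_a_time(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal(GRID.shape + (40,))
        tvals = rng.standard_normal(GRID.shape)
        a = similarity_map(make_clean(data), make_template(tvals), MASK,
                           block_size=7)
        b = similarity_map(make_clean(data), make_template(tvals), MASK,
                           block_size=100000)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_r_scale_is_tanh_of_z(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal(GRID.shape + (40,))
        tvals = rng.standard_normal(GRID.shape)
        sm = similarity_map(make_clean(data), make_template(tvals), MASK)
        assert np.allclose(sm.r_values, np.tanh(sm.values), equal_nan=True)


class TestPlantedCompensation:
    def test_full_similarity_low_noise_tops_non_network_voxels(self):
        """At s = 1 and low noise the compensation voxel's profile reproduces
        the lesion node's connectivity fingerprint, so it scores above every
        voxel outside the planted lesion network (whose own member voxels
        legitimately resemble the LN as well) and in the map's top tail."""
        cfg = small_cohort_config(n_patients=4, pool_local=4, pool_remote=8,
                                  constant_similarity=True,
                                  similarity_anchors=(1.0, 1.0),
                                  noise_sd=0.3, compensation_radius_mm=2.0,
                                  n_nodes=8, n_compensation=1)
        cohort = simulate_cohort(cfg, 19)
        from lnsim.lesion_network import build_fc_stack, derive_ln_template

        cleans = {c.subject_id: clean(cohort, c.subject_id, 1, fwhm=None)
                  for c in cohort.controls[:8]}
        records = {c.subject_id: c for c in cohort.controls}
        tpl = derive_ln_template(build_fc_stack(cleans, records, cohort.patients,
                                                cohort.lesion_masks))
        sm = similarity_map(clean(cohort, "P001", 1, fwhm=None), tpl,
                            cohort.config.grid.brain_mask())
        comp = cohort.truth.compensation_masks[0]
        net = cohort.network
        network = net.node_mask(net.lesion_node)
        for i in range(net.n_nodes):
            if i != net.lesion_node and i not in net.compensation_nodes:
                network |= net.node_mask(i)
        comp_mean = np.nanmean(sm.values[comp])
        assert comp_mean > np.nanmax(sm.values[sm.mask & ~network & ~comp])
        assert comp_mean > np.nanpercentile(sm.values[sm.mask], 97)

    def test_compensation_similarity_declines_across_visits(self):
        """Mean similarity in planted masks falls visit 1 -> 3 (sign test)."""
        n_rep, wins = 8, 0
        for seed in range(30, 30 + n_rep):
            cohort = simulate_cohort(small_cohort_config(n_patients=4,
                                                         pool_local=4,
                                                         pool_remote=8), seed)
            from lnsim.lesion_network import build_fc_stack, derive_ln_template

            cleans = {c.subject_id: clean(cohort, c.subject_id, 1)
                      for c in cohort.controls[:8]}
            records = {c.subject_id: c for c in cohort.controls}
            tpl = derive_ln_template(build_fc_stack(cleans, records,
                                                    cohort.patients,
                                                    cohort.lesion_masks))
            comp = np.zeros(cohort.config.grid.shape, bool)
            for m in cohort.truth.compensation_masks:
                comp |= m
            vox = np.argwhere(comp)
            means = []
            for visit in (1, 3):
                vals = []
                for p in cohort.patients:
                    sm = similarity_map(clean(cohort, p.subject_id, visit), tpl,
                                        cohort.config.grid.brain_mask(), voxels=vox)
                    vals.append(np.nanmean(sm.values[comp]))
                means.append(np.mean(vals))
            wins += means[0] > means[1]
        # one-sided sign test: 7+/8 rejects p = 0.5 at p < 0.05
        assert wins >= 7
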