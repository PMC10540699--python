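"""ERP statistics: contrast algebra, smoothing, F-map and cluster oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from duplescales import erp_stats
from duplescales.cluster_stats import (cluster_test_1samp, find_clusters,
                                       one_sample_t, rm_anova_2way)
from duplescales.erp_stats import (anova_map, build_condition_erps,
                                   congruence_contrast_maps,
                                   mismatch_contrast_maps, posthoc_pairwise,
                                   smooth_topo_time, subject_indices)
from duplescales.montage import gaussian_channel_smoother


class TestConditionERPs:
    def test_nine_cells_right_shape(self, epochs_mid):
        erp = build_condition_erps(epochs_mid, robust=False)
        assert erp.waveforms.shape == (3, 3, 64, 90)
        assert erp.standards_by_position.shape == (2, 3, 64, 90)

    def test_empty_cell_raises_named_error(self, epochs_mid):
        broken = epochs_mid.select(content=["standard", "deviant_BD"])
        with pytest.raises(ValueError, match="deviant_ID"):
            build_condition_erps(broken, robust=False)

    def test_mismatch_kernel_peaks_in_window(self, schedule_mid):
        from duplescales import synth
        p = synth.SynthEEGParams(noise_scale=0.01)
        ep = synth.synth_epochs(schedule_mid, p, seed=1)
        erp = build_condition_erps(ep, robust=False)
        diff = np.stack([erp.waveforms[1], erp.waveforms[2]]).mean(axis=(0, 1)) \
            - erp.waveforms[0].mean(axis=0)
        peak_t = erp.times[np.argmax(np.abs(diff).max(axis=0))]
        assert 0.173 <= peak_t <= 0.223


class TestContrasts:
    @given(st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_congruence_zero_under_additive_cells(self, seed):
        # any main effects without interaction must give exactly zero
        rng = np.random.default_rng(seed)
        n, ch, t = 4, 5, 6
        content = rng.standard_normal((n, 2, 1, ch, t))
        timing = rng.standard_normal((n, 1, 2, ch, t))
        subject = rng.standard_normal((n, 1, 1, ch, t))
        cells = content + timing + subject
        maps = congruence_contrast_maps(cells)
        assert np.allclose(maps, 0.0, atol=1e-10)

    def test_swapping_deviant_labels_flips_sign(self, rng):
        cells = rng.standard_normal((6, 2, 2, 4, 5))
        maps = congruence_contrast_maps(cells)
        swapped = congruence_contrast_maps(cells[:, ::-1])
        assert np.allclose(maps, -swapped)

    def test_mismatch_zero_when_deviants_equal_standards(self, rng):
        base = rng.standard_normal((5, 1, 3, 4, 6))
        cells = np.repeat(base, 3, axis=1)
        assert np.allclose(mismatch_contrast_maps(cells), 0.0)


class TestSmoothing:
    def test_mass_conserved_and_constant_fixed(self, pos2d, rng):
        w = gaussian_channel_smoother(pos2d, 5.0)
        delta = np.zeros(64)
        delta[10] = 1.0
        out = w @ delta
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert (w @ np.full(64, 3.3)) == pytest.approx(3.3, abs=1e-6)

    def test_zero_fwhm_is_identity(self, pos2d):
        assert np.allclose(gaussian_channel_smoother(pos2d, 0.0), np.eye(64))

    def test_spreads_to_neighbors_only_spatially(self, pos2d):
        maps = np.zeros((1, 64, 10))
        maps[0, 20, 3] = 1.0
        out = smooth_topo_time(maps, pos2d, 5.0)
        assert (out[0, :, 3] > 1e-6).sum() > 1     # spatial spread
        assert np.allclose(out[0, :, [0, 1, 2, 4]], 0.0)  # no temporal spread


class TestANOVAMaps:
    def test_f_invariant_to_subject_offsets(self, rng, pos2d):
        cells = rng.standard_normal((6, 3, 3, 8, 4))
        shifted = cells + rng.standard_normal((6, 1, 1, 1, 1)) * 5
        a = anova_map(cells, pos2d[:8], fwhm_mm=0.0)
        b = anova_map(shifted, pos2d[:8], fwhm_mm=0.0)
        for key in ("contents", "time", "interaction"):
            assert np.allclose(a[key][0], b[key][0], atol=1e-8)

    def test_two_cell_f_equals_paired_t_squared(self, rng):
        # F(1, n-1) = t^2 identity as the oracle
        from duplescales.cluster_stats import rm_anova_1way
        x = rng.standard_normal((8, 2))
        x[:, 1] += 0.7
        f, (df1, df2) = rm_anova_1way(x[:, :, None])
        t, _ = stats.ttest_rel(x[:, 1], x[:, 0])
        assert (df1, df2) == (1, 7)
        assert f[0] == pytest.approx(t ** 2, rel=1e-9)

    def test_matches_pingouin_two_way(self, rng):
        import pandas as pd
        import pingouin as pg
        x = rng.standard_normal((10, 3, 3))
        x += np.arange(3)[None, :, None] * 0.3          # contents effect
        x += (np.arange(3)[None, None, :] ** 2) * 0.2   # time effect
        res = rm_anova_2way(x[..., None])
        long = pd.DataFrame({
            "y": x.ravel(),
            "s": np.repeat(np.arange(10), 9),
            "a": np.tile(np.repeat(np.arange(3), 3), 10),
            "b": np.tile(np.arange(3), 30),
        })
        oracle = pg.rm_anova(data=long, dv="y", within=["a", "b"],
                             subject="s", detailed=True)
        for name, key in (("a", "A"), ("b", "B"), ("a * b", "AxB")):
            f_oracle = oracle.loc[oracle["Source"] == name, "F"].iloc[0]
            assert res[key][0][0] == pytest.approx(f_oracle, rel=1e-6)


class TestClusterInference:
    def test_threshold_above_max_gives_empty(self, rng, adjacency):
        stat = rng.uniform(0, 1, (64, 20))
        assert find_clusters(stat, 2.0, adjacency) == []

    def test_contiguity_respected(self, adjacency):
        stat = np.zeros((64, 10))
        stat[5, 2:5] = 10.0        # one channel, contiguous in time
        stat[40, 8] = 10.0         # detached island
        clusters = find_clusters(stat, 5.0, adjacency)
        assert len(clusters) == 2
        assert clusters[0].mass == pytest.approx(30.0)

    def test_strong_effect_detected_weak_not(self, rng, pos2d, adjacency):
        n = 12
        maps = rng.standard_normal((n, 64, 30))
        bump = np.zeros((64, 30))
        bump[adjacency[30], 10:20] = 3.0
        bump[30, 10:20] = 3.0
        t_obs, res = cluster_test_1samp(maps + bump, adjacency, n_perm=200,
                                        seed=0)
        assert res.significant()
        _, res_null = cluster_test_1samp(maps, adjacency, n_perm=200, seed=0)
        assert not res_null.significant()

    def test_needs_enough_permutations(self, rng, adjacency):
        with pytest.raises(ValueError):
            cluster_test_1samp(rng.standard_normal((5, 64, 4)), adjacency,
                               n_perm=50)


class TestPosthocAndIndices:
    def test_identical_cells_give_zero_t(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = posthoc_pairwise(x, [(0, 1), (0, 2)])
        assert all(abs(r["t"]) < 1e-9 or np.isnan(r["t"]) for r in res)

    def test_bonferroni_multiplies_and_caps(self, rng):
        x = rng.standard_normal((10, 2))
        x[:, 1] += 0.5
        res = posthoc_pairwise(x, [(0, 1)], n_comparisons=3)
        assert res[0]["p_bonferroni"] == pytest.approx(
            min(1.0, res[0]["p"] * 3))

    def test_subject_indices_linearity(self, rng):
        from duplescales.cluster_stats import Cluster
        cells = rng.standard_normal((5, 3, 3, 6, 8))
        mask = Cluster(channels=np.array([1, 2]),
                       time_indices=np.array([3, 4]), mass=1.0)
        base = subject_indices(cells, mask, mask)
        shifted = cells.copy()
        # shift both congruent deviant cells by -c
        c = 0.7
        shifted[:, 1, 1] -= c      # deviant_ID x interval
        shifted[:, 2, 2] -= c      # deviant_BD x beat
        out = subject_indices(shifted, mask, mask)
        assert np.allclose(out["congruence_index"],
                           base["congruence_index"] - c)

    def test_deviants_equal_standards_zero_mismatch_index(self, rng):
        from duplescales.cluster_stats import Cluster
        base = rng.standard_normal((4, 1, 3, 6, 8))
        cells = np.repeat(base, 3, axis=1)
        mask = Cluster(channels=np.arange(6), time_indices=np.arange(8),
                       mass=1.0)
        out = subject_indices(cells, mask, mask)
        assert np.allclose(out["mismatch_index"], 0.0, atol=1e-12)


class TestStandardsControl:
    def test_deviant_only_kernel_spares_standards(self, schedule_mid, pos2d,
                                                  adjacency):
        from duplescales import synth
        cohort = synth.synth_cohort(8, seed=21)
        erps = []
        for sim in cohort:
            ep = synth.synth_epochs(schedule_mid, sim.eeg, seed=sim.seed)
            erps.append(build_condition_erps(ep, robust=False))
        _, res = erp_stats.standards_control(erps, pos2d, adjacency,
                                             n_perm=150, seed=0)
        assert not res.significant()
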