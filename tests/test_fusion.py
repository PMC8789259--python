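"""LGE thresholding, T1 classification and personalized-threshold transfer."""
import numpy as np
import pytest

from virtuheart import fusion, synthetic
from virtuheart.fusion import (LABEL_DENSE, LABEL_DIFFUSE, LABEL_NORMAL,
                               PersonalizedThresholds, RemoteStats, T1Map,
                               TissueLabelMap)


def _bimodal_slice(rng, n=40, frac_bright=0.3, lo=(100.0, 10.0), hi=(200.0, 15.0)):
    vals = np.where(rng.random((n, n)) < frac_bright,
                    rng.normal(hi[0], hi[1], (n, n)),
                    rng.normal(lo[0], lo[1], (n, n)))
    return vals, np.ones((n, n), dtype=bool)


class TestRemoteStats:
    def test_recovers_remote_component(self, rng):
        img, mask = _bimodal_slice(rng)
        st = fusion.estimate_remote_stats(img, mask)
        assert st.mean == pytest.approx(100.0, abs=4.0)
        assert st.sd == pytest.approx(10.0, abs=3.0)

    def test_small_bright_blob_ignored(self, rng):
        img = rng.normal(100.0, 10.0, (40, 40))
        img[:4, :20] = rng.normal(300.0, 5.0, (4, 20))   # 5% bright blob
        st = fusion.estimate_remote_stats(img, np.ones_like(img, dtype=bool))
        assert st.mean == pytest.approx(100.0, abs=4.0)
        assert st.sd == pytest.approx(10.0, abs=3.0)

    def test_constant_slice_rejected(self):
        img = np.full((20, 20), 7.0)
        with pytest.raises(ValueError):
            fusion.estimate_remote_stats(img, np.ones_like(img, dtype=bool))

    def test_too_few_voxels_rejected(self, rng):
        img = rng.normal(size=(8, 8))
        with pytest.raises(ValueError):
            fusion.estimate_remote_stats(img, np.ones_like(img, dtype=bool))


class TestClassifyLge:
    def test_threshold_boundaries(self):
        # voxels at mean, mean+4sd, mean+6sd with thresholds (3, 5)
        inten = np.array([[100.0, 140.0, 160.0]])
        stack = fusion.LGEStack(np.repeat(inten[..., None], 1, axis=2),
                                np.ones((1, 3, 1), dtype=bool), (2.0, 8.0),
                                np.array([0.0]))
        labels = fusion.classify_lge(stack, RemoteStats(100.0, 10.0),
                                     PersonalizedThresholds(3.0, 5.0))
        assert labels.labels[0, 0, 0] == LABEL_NORMAL   # at the mean
        assert labels.labels[0, 1, 0] == LABEL_DIFFUSE  # mean + 4 SD
        assert labels.labels[0, 2, 0] == LABEL_DENSE    # mean + 6 SD

    def test_fractions_equal_brute_force_count(self, rng):
        vals = rng.normal(100.0, 10.0, (30, 30, 4)) + \
            rng.exponential(20.0, (30, 30, 4))
        mask = rng.random((30, 30, 4)) < 0.8
        mask[:, :, 2] |= True
        stack = fusion.LGEStack(vals, mask, (2.0, 8.0), np.arange(4) * 8.0)
        st = RemoteStats(100.0, 10.0)
        thr = PersonalizedThresholds(1.5, 4.0)
        labels = fusion.classify_lge(stack, st, thr)
        exp_dense = np.sum(mask & (vals > 100.0 + 4.0 * 10.0))
        exp_diff = np.sum(mask & (vals > 115.0) & (vals <= 140.0))
        assert np.sum(labels.labels == LABEL_DENSE) == exp_dense
        assert np.sum(labels.labels == LABEL_DIFFUSE) == exp_diff


class TestClassifyT1:
    @pytest.mark.parametrize("time_ms,expected", [
        (349.0, LABEL_DENSE), (350.0, LABEL_DIFFUSE), (450.0, LABEL_DIFFUSE),
        (451.0, LABEL_NORMAL), (500.0, LABEL_NORMAL),
    ])
    def test_band_boundaries(self, time_ms, expected):
        t1 = T1Map(np.full((12, 12), time_ms), np.ones((12, 12), bool),
                   (1.5, 8.0), 40.0)
        assert fusion.classify_t1(t1)[5, 5] == expected

    def test_band_areas_match_construction(self, default_pair):
        _, t1, _ = default_pair
        labels = fusion.classify_t1(t1)
        sel = t1.lv_mask
        assert (labels[sel] > 0).all()
        # cohort-mean conditions: diffuse ~40% of the stack; the single mid
        # slice fluctuates around it, and its dense burden (3.8% stack-wide)
        # may be absent from any one slice
        assert np.mean(labels[sel] == LABEL_DIFFUSE) == pytest.approx(0.40, abs=0.12)
        assert np.mean(labels[sel] == LABEL_DENSE) <= 0.15

    def test_nonpositive_time_rejected(self):
        t1 = T1Map(np.full((12, 12), 400.0), np.ones((12, 12), bool),
                   (1.5, 8.0), 40.0)
        t1.times_ms[3, 3] = -1.0
        with pytest.raises(ValueError):
            fusion.classify_t1(t1)


class TestMatchSlice:
    def _stack(self, n=11):
        return fusion.LGEStack(np.zeros((4, 4, n)) + 100.0,
                               np.ones((4, 4, n), bool), (2.0, 8.0),
                               np.arange(n) * 8.0)

    def _t1(self, z):
        return T1Map(np.full((6, 6), 500.0), np.ones((6, 6), bool), (1.5, 8.0), z)

    def test_nearest(self):
        assert fusion.match_slice(self._stack(), self._t1(40.0)) == 5

    def test_tie_breaks_low(self):
        assert fusion.match_slice(self._stack(), self._t1(36.0)) == 4

    def test_perturbation_stable(self):
        for dz in (-1.0, -0.5, 0.5, 1.0):
            assert fusion.match_slice(self._stack(), self._t1(40.0 + dz)) == 5

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fusion.match_slice(self._stack(), self._t1(-5.0))


class TestThresholdTransfer:
    def test_self_consistency_returns_reference_thresholds(self, rng):
        """A T1 map whose bands equal the slice's own 3/5-SD sets gives
        thresholds (3, 5) back (within quantile interpolation)."""
        n = 60
        vals = rng.normal(100.0, 10.0, (n, n)) + rng.exponential(15.0, (n, n))
        mask = np.ones((n, n), bool)
        sl = fusion.LGESlice(vals, mask, (1.5, 8.0), 40.0)
        st = RemoteStats(100.0, 10.0)
        # T1 map on the same grid encoding the (3,5)-SD classification
        t1_times = np.full((n, n), 500.0)
        t1_times[vals > 130.0] = 400.0
        t1_times[vals > 150.0] = 300.0
        t1 = T1Map(t1_times, mask, (1.5, 8.0), 40.0)
        thr = fusion.derive_personalized_thresholds(sl, st, t1)
        assert thr.t_diffuse == pytest.approx(3.0, abs=0.05)
        assert thr.t_dense == pytest.approx(5.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_within_one_voxel(self, seed):
        """Applying derived thresholds to the matching slice reproduces the
        T1-derived area fractions within one voxel's area fraction."""
        spec = synthetic.SyntheticCohortSpec(seed=seed)
        stack, t1, _ = synthetic.generate_lge_t1_pair(spec)
        k = fusion.match_slice(stack, t1)
        sl = stack.get_slice(k)
        st = fusion.estimate_remote_stats(sl.intensities, sl.lv_mask)
        thr = fusion.derive_personalized_thresholds(sl, st, t1)
        res = fusion.resample_t1_labels(t1, sl)
        sel = sl.lv_mask & (res > 0)
        f_dense = np.mean(res[sel] == LABEL_DENSE)
        f_diff = np.mean(res[sel] == LABEL_DIFFUSE)
        lab = fusion._classify_array(sl.intensities, sl.lv_mask, st, thr)
        n = sl.lv_mask.sum()
        tol = 1.0 / n + 1e-12
        assert abs(np.sum(lab == LABEL_DENSE) / n - f_dense) <= tol
        assert abs(np.sum(lab == LABEL_DIFFUSE) / n - f_diff) <= tol

    def test_empty_fibrotic_classes(self):
        rng = np.random.default_rng(0)
        n = 40
        sl = fusion.LGESlice(rng.normal(100, 10, (n, n)), np.ones((n, n), bool),
                             (1.5, 8.0), 40.0)
        t1 = T1Map(np.full((n, n), 600.0), np.ones((n, n), bool), (1.5, 8.0), 40.0)
        thr = fusion.derive_personalized_thresholds(sl, RemoteStats(100, 10), t1)
        lab = fusion._classify_array(sl.intensities, sl.lv_mask,
                                     RemoteStats(100, 10), thr)
        assert np.sum(lab == LABEL_DENSE) == 0
        assert np.sum(lab == LABEL_DIFFUSE) == 0

    def test_cohort_mean_t_diffuse_far_below_three_sd(self):
        """At cohort-mean diffuse burdens the personalized diffuse threshold
        collapses well below the one-size-fits-all 3 SD."""
        ts = []
        for seed in range(1, 9):
            spec = synthetic.SyntheticCohortSpec(seed=seed)
            stack, t1, _ = synthetic.generate_lge_t1_pair(spec)
            thr, _, _ = fusion.fuse(stack, t1, mode="lge_t1")
            ts.append(thr.t_diffuse)
        mean_t = float(np.mean(ts))
        assert 0.0 < mean_t < 2.5


class TestApplyAndQuantify:
    def test_monotone_in_thresholds(self, default_pair):
        stack, _, _ = default_pair
        stats = fusion.estimate_remote_stats_per_slice(stack)
        fr = []
        for td in (0.5, 1.5, 3.0):
            lm = fusion.apply_thresholds_to_stack(
                stack, stats, PersonalizedThresholds(td, 6.0))
            fr.append(fusion.quantify_fibrosis(lm).diffuse_pct)
        assert fr[0] >= fr[1] >= fr[2]

    def test_lge_only_special_case_bit_matches(self, default_pair):
        stack, _, _ = default_pair
        stats = fusion.estimate_remote_stats_per_slice(stack)
        via_thresholds = fusion.apply_thresholds_to_stack(
            stack, stats, PersonalizedThresholds(3.0, 5.0))
        via_pipeline = fusion.lge_only_pipeline(stack, stats)
        np.testing.assert_array_equal(via_thresholds.labels, via_pipeline.labels)

    def test_uniform_stack_slices_agree(self, rng):
        """Slices that are copies of one another give identical fractions."""
        sl = rng.normal(100, 10, (30, 30)) + rng.exponential(10, (30, 30))
        stack = fusion.LGEStack(np.repeat(sl[..., None], 5, axis=2),
                                np.ones((30, 30, 5), bool), (2.0, 8.0),
                                np.arange(5) * 8.0)
        stats = fusion.estimate_remote_stats_per_slice(stack)
        lm = fusion.apply_thresholds_to_stack(stack, stats,
                                              PersonalizedThresholds(2.0, 4.0))
        per_slice = [(lm.labels[:, :, k] == LABEL_DIFFUSE).sum()
                     for k in range(5)]
        assert len(set(per_slice)) == 1

    def test_quantify_all_normal(self):
        lm = TissueLabelMap(np.ones((10, 10), dtype=np.int8), (1.0, 1.0))
        fr = fusion.quantify_fibrosis(lm)
        assert fr.diffuse_pct == 0.0 and fr.dense_pct == 0.0

    def test_quantify_counts_equal_tally(self, default_pair):
        _, _, labels = default_pair
        fr = fusion.quantify_fibrosis(labels)
        myo = labels.myocardium.sum()
        assert fr.dense_pct == pytest.approx(
            100.0 * (labels.labels == LABEL_DENSE).sum() / myo)

    def test_quantify_empty_rejected(self):
        lm = TissueLabelMap(np.zeros((5, 5), dtype=np.int8), (1.0, 1.0))
        with pytest.raises(ValueError):
            fusion.quantify_fibrosis(lm)

    def test_threshold_invariant_enforced(self):
        with pytest.raises(ValueError):
            PersonalizedThresholds(5.0, 3.0)
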