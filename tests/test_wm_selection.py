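import numpy as np
import pytest

from dscquant import wm_selection as wm
from dscquant.errors import EmptyRoiError, LabelError, MaskError, ParameterError
from dscquant.io_volumes import LabelVolume, ProbabilityMap
from dscquant.synthetic_phantom import CLASS_TUMOR, CLASS_WM


class TestFeatureCurves:
    def test_truncation_length(self, noisy_conc):
        _, timing, conc = noisy_conc
        feats, voxel_mask = wm.feature_curves(conc, timing)
        assert feats.shape[1] == conc.n_frames - timing.entrance
        assert feats.shape[0] == voxel_mask.sum()

    def test_identical_curves_identical_features(self, rng):
        from dscquant.bolus_detection import BolusTiming
        from dscquant.concentration import ConcentrationSeries

        curve = rng.normal(size=20)
        delta = np.stack([curve, curve, rng.normal(size=20)], axis=1)
        conc = ConcentrationSeries(
            delta_r2s=delta.reshape(20, 1, 1, 3),
            s_base=np.full((1, 1, 3), 200.0),
            timing=BolusTiming(n_discarded=0, baseline_window=(0, 4),
                               entrance=5, trough=9, exit=14),
            frame_spacing=2.2, te=60.0, mask=np.ones((1, 1, 3), bool))
        feats, _ = wm.feature_curves(conc)
        np.testing.assert_array_equal(feats[0], feats[1])
        assert not np.array_equal(feats[0], feats[2])

    def test_between_class_distance_exceeds_within(self, noisy_conc,
                                                   default_phantom):
        _, truth = default_phantom
        _, timing, conc = noisy_conc
        feats, voxel_mask = wm.feature_curves(conc, timing)
        labels = truth.class_labels[voxel_mask]
        wm_f = feats[labels == CLASS_WM]
        tm_f = feats[labels == CLASS_TUMOR]
        within = np.linalg.norm(wm_f - wm_f.mean(0), axis=1).mean()
        between = np.linalg.norm(wm_f.mean(0) - tm_f.mean(0))
        assert between > within


class TestMeanShift:
    def test_identical_features_single_cluster(self):
        feats = np.tile(np.arange(5.0), (20, 1))
        res = wm.mean_shift_cluster(feats, reduce=False)
        assert res.n_clusters == 1

    def test_two_separated_blobs(self, rng):
        a = rng.normal(0.0, 0.1, size=(40, 3))
        b = rng.normal(0.0, 0.1, size=(40, 3)) + 10.0
        feats = np.vstack([a, b])
        res = wm.mean_shift_cluster(feats, bandwidth=1.0, reduce=False)
        assert res.n_clusters == 2
        labels = np.asarray(res.label_map)
        # brute-force nearest-mode oracle
        modes = np.array(res.modes)
        oracle = np.argmin(
            ((feats[:, None, :] - modes[None]) ** 2).sum(-1), axis=1)
        assert np.array_equal(labels, oracle)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_bad_bandwidth_raises(self, rng):
        feats = rng.normal(size=(20, 3))
        with pytest.raises(ParameterError):
            wm.mean_shift_cluster(feats, bandwidth=-1.0)

    def test_too_few_voxels_raises(self):
        with pytest.raises(MaskError):
            wm.mean_shift_cluster(np.ones((5, 3)))

    def test_mode_count_nonincreasing_in_bandwidth(self, rng):
        feats = np.vstack([rng.normal(0, 0.3, (30, 2)),
                           rng.normal(5, 0.3, (30, 2)),
                           rng.normal([0, 5], 0.3, (30, 2))])
        counts = [wm.mean_shift_cluster(feats, bandwidth=b, reduce=False).n_clusters
                  for b in (0.5, 1.5, 4.0, 20.0)]
        assert np.all(np.diff(counts) <= 0)

    def test_three_class_phantom_recovers_wm_cluster(self, noisy_conc,
                                                     default_phantom):
        _, truth = default_phantom
        _, timing, conc = noisy_conc
        feats, voxel_mask = wm.feature_curves(conc, timing)
        res = wm.mean_shift_cluster(feats, spatial_mask=voxel_mask,
                                    spatial_shape=conc.spatial_shape, seed=0)
        assert res.n_clusters >= 3
        true_wm = truth.class_labels == CLASS_WM
        purities = []
        for k in range(res.n_clusters):
            in_k = res.label_map == k
            if in_k.sum() >= 50:
                purities.append((in_k & true_wm).sum() / in_k.sum())
        assert max(purities) >= 0.8

    def test_deterministic_across_runs(self, noisy_conc):
        _, timing, conc = noisy_conc
        feats, voxel_mask = wm.feature_curves(conc, timing)
        r1 = wm.mean_shift_cluster(feats, spatial_mask=voxel_mask,
                                   spatial_shape=conc.spatial_shape, seed=0)
        r2 = wm.mean_shift_cluster(feats, spatial_mask=voxel_mask,
                                   spatial_shape=conc.spatial_shape, seed=0)
        np.testing.assert_array_equal(r1.label_map, r2.label_map)


class TestSelectWmCluster:
    def _clusters_single(self, shape=(2, 4, 4)):
        label_map = np.zeros(shape, int)
        return wm.ClusterResult(label_map=label_map, modes=[np.zeros(3)],
                                bandwidth=1.0, n_clusters=1)

    def test_single_cluster_full_probability(self):
        clusters = self._clusters_single()
        prob = ProbabilityMap(prob=np.ones((2, 4, 4)))
        roi = wm.select_wm_cluster(clusters, prob)
        assert roi.n_voxels == 32
        assert roi.source == "automatic"

    def test_threshold_is_inclusive_at_least(self):
        clusters = self._clusters_single()
        prob = ProbabilityMap(prob=np.full((2, 4, 4), 0.90))
        with pytest.raises(EmptyRoiError):
            wm.select_wm_cluster(clusters, prob, threshold=0.95)
        # exactly 0.95 satisfies "at least 95%"
        prob95 = ProbabilityMap(prob=np.full((2, 4, 4), 0.95))
        roi = wm.select_wm_cluster(clusters, prob95, threshold=0.95)
        assert roi.n_voxels == 32

    def test_roi_subset_of_high_probability_and_disjoint_from_tumor(
            self, noisy_conc, default_phantom):
        _, truth = default_phantom
        _, timing, conc = noisy_conc
        tumor = truth.class_labels == CLASS_TUMOR
        roi, _ = wm.automatic_wm_roi(conc, truth.wm_probability,
                                     tumor_mask=tumor, seed=0)
        assert np.all(truth.wm_probability.prob[roi.mask] >= 0.95)
        assert not (roi.mask & tumor).any()

    def test_phantom_dice_against_true_wm(self, noisy_conc, default_phantom):
        _, truth = default_phantom
        _, timing, conc = noisy_conc
        tumor = truth.class_labels == CLASS_TUMOR
        roi, _ = wm.automatic_wm_roi(conc, truth.wm_probability,
                                     tumor_mask=tumor, seed=0)
        true_wm = truth.class_labels == CLASS_WM
        dice = 2 * (roi.mask & true_wm).sum() / (roi.mask.sum() + true_wm.sum())
        assert dice >= 0.8


class TestManualWmRoi:
    def _label_volume(self, n=50, shape=(2, 8, 8)):
        labels = np.zeros(shape, np.int32)
        labels.reshape(-1)[:n] = 1
        return LabelVolume(labels=labels)

    def test_plain_count(self):
        roi = wm.manual_wm_roi(self._label_volume(), label=1)
        assert roi.n_voxels == 50
        assert roi.source == "manual"

    def test_absent_label_raises(self):
        with pytest.raises(LabelError):
            wm.manual_wm_roi(self._label_volume(), label=7)

    def test_tumor_subtraction(self):
        vol = self._label_volume()
        tumor = np.zeros((2, 8, 8), bool)
        tumor.reshape(-1)[:10] = True  # 10 of the 50 labelled voxels
        roi = wm.manual_wm_roi(vol, label=1, tumor_mask=tumor)
        assert roi.n_voxels == 40

    def test_empty_after_exclusion_raises(self):
        vol = self._label_volume(n=10)
        tumor = np.zeros((2, 8, 8), bool)
        tumor.reshape(-1)[:10] = True
        with pytest.raises(EmptyRoiError):
            wm.manual_wm_roi(vol, label=1, tumor_mask=tumor)
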