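"""Fiber marker calls, nucleus detection and Pax7 scoring."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import regenquant as rq
from regenquant.classify import (
    ChannelThresholds,
    auto_threshold,
    classify_fibers,
    detect_nuclei,
    score_pax7,
)
from regenquant.segmentation import LabelMap


class TestClassifyFibers:
    def test_noiseless_calls_match_truth_exactly(self, segmented):
        phantom, lm = segmented
        calls = classify_fibers(lm, phantom.channel("emhc"), phantom.channel("igg"))
        matches = rq.match_labels(phantom.label_map, lm, iou_threshold=0.5)
        truth = phantom.truth.set_index("fiber_id")
        by_id = {c.fiber_id: c for c in calls}
        for _, row in matches.iterrows():
            c = by_id[int(row.pred_id)]
            assert c.is_emhc_pos == bool(truth.loc[int(row.truth_id), "is_emhc"])
            assert c.is_igg_pos == bool(truth.loc[int(row.truth_id), "is_igg"])

    def test_all_zero_channels_give_no_positives(self, segmented):
        _, lm = segmented
        zero = np.zeros_like(lm.labels, dtype=float)
        calls = classify_fibers(lm, zero, zero)
        assert not any(c.is_emhc_pos for c in calls)
        assert not any(c.is_igg_pos for c in calls)

    def test_background_only_channel_gives_no_positives(self, noiseless_phantom):
        """Noise alone must not be split into a fake positive class."""
        ph = noiseless_phantom
        lm = rq.segment_fibers(ph.channel("laminin"), pixel_size=1.0)
        rng = np.random.default_rng(0)
        noise = 1.0 + rng.normal(0, 0.05, lm.labels.shape)
        calls = classify_fibers(lm, noise, noise)
        assert not any(c.is_emhc_pos for c in calls)

    def test_class_count_invariants(self, segmented):
        phantom, lm = segmented
        calls = classify_fibers(lm, phantom.channel("emhc"), phantom.channel("igg"))
        n_total = len(calls)
        assert sum(c.is_emhc_pos for c in calls) <= n_total
        assert sum(c.is_igg_pos for c in calls) <= n_total

    def test_fixed_threshold_monotonicity(self, segmented):
        """Raising a fixed threshold never increases positive calls."""
        phantom, lm = segmented
        emhc, igg = phantom.channel("emhc"), phantom.channel("igg")
        counts = []
        for t in (0.5, 2.0, 4.0, 8.0):
            calls = classify_fibers(lm, emhc, igg,
                                    ChannelThresholds(emhc=t, igg=t))
            counts.append(sum(c.is_emhc_pos for c in calls))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_labelmap_rejected(self):
        lm = LabelMap(np.zeros((20, 20), dtype=np.int32), 1.0)
        with pytest.raises(ValueError, match="empty labelmap"):
            classify_fibers(lm, np.ones((20, 20)), np.ones((20, 20)))

    def test_erosion_annihilation_falls_back_with_warning(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5, 5] = 1  # single-pixel fiber: any erosion removes it
        lab[10:18, 10:18] = 2
        lm = LabelMap(lab, 1.0)
        img = np.ones((20, 20))
        with pytest.warns(UserWarning, match="annihilated"):
            calls = classify_fibers(lm, img, img, ChannelThresholds(interior_erosion=2.0))
        assert len(calls) == 2
        assert np.isfinite([c.mean_emhc for c in calls]).all()

    def test_double_positive_fibers_counted_in_both_classes(self):
        lab = np.zeros((30, 30), dtype=np.int32)
        lab[2:12, 2:12] = 1
        lab[18:28, 18:28] = 2
        lm = LabelMap(lab, 1.0)
        both = np.where(lab == 1, 9.0, 1.0)
        calls = classify_fibers(lm, both, both, ChannelThresholds(emhc=5.0, igg=5.0))
        c1 = next(c for c in calls if c.fiber_id == 1)
        assert c1.is_emhc_pos and c1.is_igg_pos


class TestAutoThreshold:
    def test_separated_classes_found(self):
        rng = np.random.default_rng(0)
        means = np.concatenate([1 + 0.02 * rng.random(90), 5 + 0.02 * rng.random(10)])
        t = auto_threshold(means)
        assert t is not None
        assert (means > t).sum() == 10  # exactly the upper class

    def test_pure_noise_returns_none(self):
        rng = np.random.default_rng(1)
        assert auto_threshold(1 + 0.05 * rng.random(200)) is None

    def test_constant_returns_none(self):
        assert auto_threshold(np.full(50, 2.0)) is None


def _spot_image(coords, shape=(120, 120), sigma=3.0, amp=7.0):
    img = np.zeros(shape)
    for y, x in coords:
        img[y, x] = amp * 2 * np.pi * sigma**2
    return 1.0 + ndi.gaussian_filter(img, sigma)


class TestDetectNuclei:
    def test_well_separated_nuclei_all_found(self):
        coords = [(15 + 22 * i, 15 + 22 * j) for i in range(5) for j in range(5)]
        nuclei = detect_nuclei(_spot_image(coords), pixel_size=1.0)
        assert len(nuclei) == 25

    def test_overlapping_pair_split(self):
        nuclei = detect_nuclei(_spot_image([(30, 22), (30, 38)], shape=(60, 60)),
                               pixel_size=1.0)
        assert len(nuclei) == 2

    def test_blank_image_empty(self):
        assert detect_nuclei(np.zeros((40, 40))) == []

    def test_nucleus_masks_disjoint(self):
        coords = [(20, 20), (20, 40), (40, 30)]
        nuclei = detect_nuclei(_spot_image(coords, shape=(60, 60)), pixel_size=1.0)
        seen = set()
        for n in nuclei:
            px = {tuple(p) for p in n.coords}
            assert not (px & seen)
            seen |= px


class TestScorePax7:
    def _setup(self):
        lab = np.zeros((60, 60), dtype=np.int32)
        for k, (y, x) in enumerate([(10, 10), (10, 40), (40, 10), (40, 40)], 1):
            lab[y:y + 15, x:x + 15] = k
        lm = LabelMap(lab, 1.0)
        coords = [(12, 12), (12, 42), (42, 12), (42, 42), (30, 30)]
        dapi = _spot_image(coords, shape=(60, 60))
        nuclei = detect_nuclei(dapi, pixel_size=1.0)
        return lm, coords, nuclei

    def test_counts_and_ratio(self):
        lm, coords, nuclei = self._setup()
        pax7 = _spot_image(coords[:2], shape=(60, 60))  # 2 of 5 Pax7+
        scored, ppf = score_pax7(nuclei, pax7, lm)
        assert sum(s.is_pax7_pos for s in scored) == 2
        assert ppf == pytest.approx(2 / 4)

    def test_ratio_arithmetic(self):
        """20 positives over 400 fibers gives 0.05 per fiber."""
        lab = np.zeros((10, 1200), dtype=np.int32)
        for f in range(400):
            lab[2:8, f * 3] = f + 1
        lm = LabelMap(lab, 1.0)
        nuclei = [
            rq.NucleusCall(nucleus_id=i, centroid=(5.0, float(3 * i)), area_px=1,
                           coords=np.array([[5, 3 * i]]))
            for i in range(100)
        ]
        pax7 = np.ones((10, 1200))
        for i in range(20):
            pax7[5, 3 * i] = 9.0  # first 20 nuclei positive
        scored, ppf = score_pax7(nuclei, pax7, lm)
        assert sum(s.is_pax7_pos for s in scored) == 20
        assert ppf == pytest.approx(20 / 400)

    def test_blacklist_excludes_reviewed_regions(self):
        lm, coords, nuclei = self._setup()
        pax7 = _spot_image(coords[:3], shape=(60, 60))  # 3 positives
        # blacklist covers the nucleus near (12, 12)
        blacklist = [[(5, 5), (5, 20), (20, 20), (20, 5)]]
        scored, ppf = score_pax7(nuclei, pax7, lm, blacklist=blacklist)
        assert sum(s.is_pax7_pos for s in scored) == 3  # scoring unchanged
        assert ppf == pytest.approx(2 / 4)  # counting excludes the reviewed one

    def test_zero_fibers_rejected(self):
        lm = LabelMap(np.zeros((20, 20), dtype=np.int32), 1.0)
        with pytest.raises(ValueError, match="no fibers"):
            score_pax7([], np.ones((20, 20)), lm)

    def test_fiber_context_assigned(self):
        lm, coords, nuclei = self._setup()
        pax7 = np.ones((60, 60))
        scored, _ = score_pax7(nuclei, pax7, lm)
        contexts = {s.fiber_context for s in scored}
        assert any(isinstance(c, int) for c in contexts)
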