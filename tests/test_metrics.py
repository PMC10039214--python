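"""Metric correctness against exhaustive oracles and identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pelvreg import metrics
from pelvreg.io import OrganMaskSet


def _mask(rng, h=12, w=12, p=0.4):
    return (rng.random((h, w)) < p).astype(np.uint8)


class TestOverlapMetrics:
    def test_dice_identities(self, rng):
        a = _mask(rng)
        a[0, 0] = 1
        assert metrics.dice(a, a) == 1.0
        assert metrics.dice(a, np.zeros_like(a)) == 0.0
        assert metrics.dice(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_shifted_block_counts(self):
        a = np.zeros((4, 4), np.uint8)
        a[:3, :3] = 1
        b = np.zeros((4, 4), np.uint8)
        b[:3, 1:4] = 1
        assert metrics.dice(a, b) == pytest.approx(2 * 6 / 18)
        assert metrics.jaccard(a, b) == pytest.approx(6 / 12)

    def test_jaccard_dice_identity(self, rng):
        for _ in range(50):
            a, b = _mask(rng), _mask(rng)
            d = metrics.dice(a, b)
            j = metrics.jaccard(a, b)
            assert j == pytest.approx(d / (2 - d), abs=1e-12)
            assert j <= d + 1e-15

    def test_symmetry(self, rng):
        a, b = _mask(rng), _mask(rng)
        assert metrics.dice(a, b) == metrics.dice(b, a)
        assert metrics.jaccard(a, b) == metrics.jaccard(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            metrics.dice(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
           hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)))
    def test_dice_bounds_property(self, a, b):
        d = metrics.dice(a, b)
        j = metrics.jaccard(a, b)
        assert 0.0 <= j <= d <= 1.0


class TestASSD:
    def test_identical_masks_zero(self, rng):
        a = _mask(rng)
        a[5, 5] = 1
        assert metrics.assd(a, a, spacing=1.0) == 0.0

    def test_single_pixel_pair_euclidean(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert metrics.assd(a, b, spacing=1.0) == pytest.approx(5.0)

    def test_spacing_honoured(self):
        a = np.zeros((4, 8), np.uint8)
        b = np.zeros((4, 8), np.uint8)
        a[1, 1] = 1
        b[1, 5] = 1  # 4 px apart along x
        assert metrics.assd(a, b, spacing=(1.0, 0.5)) == pytest.approx(2.0)

    def test_empty_mask_raises(self):
        a = np.zeros((4, 4), np.uint8)
        b = a.copy()
        b[1, 1] = 1
        with pytest.raises(ValueError):
            metrics.assd(a, b)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            a, b = _mask(rng, 16, 16), _mask(rng, 16, 16)
            if not (a.any() and b.any()):
                continue
            fast = metrics.assd(a, b, spacing=1.0)
            slow = metrics.assd_bruteforce(a, b, spacing=1.0)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_symmetry_and_translation_invariance(self, rng):
        a = np.zeros((20, 20), np.uint8)
        b = np.zeros((20, 20), np.uint8)
        a[4:9, 5:11] = 1
        b[6:10, 7:12] = 1
        assert metrics.assd(a, b) == pytest.approx(metrics.assd(b, a))
        assert metrics.assd(np.roll(a, 3, 1), np.roll(b, 3, 1)) == \
            pytest.approx(metrics.assd(a, b))


class TestContours:
    def test_empty_mask_no_contours(self):
        assert metrics.extract_contours(np.zeros((8, 8))) == []

    def test_full_frame_single_closed_contour(self):
        cs = metrics.extract_contours(np.ones((10, 12)))
        assert len(cs) == 1
        np.testing.assert_allclose(cs[0][0], cs[0][-1])

    def test_disk_area_close_to_pixel_count(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 12 ** 2).astype(np.uint8)
        cs = metrics.extract_contours(disk)
        assert len(cs) == 1
        area = metrics.contour_area(cs[0])
        assert area == pytest.approx(disk.sum(), rel=0.05)

    def test_two_blobs_two_contours(self):
        m = np.zeros((20, 20), np.uint8)
        m[2:6, 2:6] = 1
        m[12:17, 11:18] = 1
        assert len(metrics.extract_contours(m)) == 2


class TestEvaluate:
    def _sets(self, arrays):
        return OrganMaskSet({k: v for k, v in arrays.items()})

    def test_identical_sets_perfect_scores(self, rng):
        m = {o: _mask(rng, 16, 16) for o in ("bladder", "cervix", "rectum")}
        for v in m.values():
            v[8, 8] = 1
        s = self._sets(m)
        rep = metrics.evaluate([(s, s), (s, s)], spacing=1.0)
        for o in ("bladder", "cervix", "rectum"):
            assert rep[o].dice_mean == 1.0
            assert rep[o].dice_sd == 0.0
            assert rep[o].assd_mean_mm == 0.0
            assert rep[o].n_slices_evaluated == 2

    def test_mean_and_population_sd(self):
        # two slices engineered to Dice 0.6 and 0.8
        a1 = np.zeros((4, 10), np.uint8); a1[0, :5] = 1
        b1 = np.zeros((4, 10), np.uint8); b1[0, 2:7] = 1   # dice 0.6
        a2 = np.zeros((4, 10), np.uint8); a2[0, :8] = 1
        b2 = np.zeros((4, 10), np.uint8); b2[0, 2:10] = 1  # dice 0.75
        b2[1, 0] = 0
        pairs = [(self._sets({"bladder": a1}), self._sets({"bladder": b1})),
                 (self._sets({"bladder": a2}), self._sets({"bladder": b2}))]
        rep = metrics.evaluate(pairs, spacing=1.0)
        d1 = metrics.dice(a1, b1)
        d2 = metrics.dice(a2, b2)
        assert rep["bladder"].dice_mean == pytest.approx((d1 + d2) / 2)
        assert rep["bladder"].dice_sd == pytest.approx(abs(d1 - d2) / 2)

    def test_empty_reference_slices_excluded(self, rng):
        full = _mask(rng, 8, 8)
        full[4, 4] = 1
        empty = np.zeros((8, 8), np.uint8)
        pairs = [(self._sets({"rectum": full}), self._sets({"rectum": full})),
                 (self._sets({"rectum": empty}), self._sets({"rectum": full}))]
        rep = metrics.evaluate(pairs, spacing=1.0)
        assert rep["rectum"].n_slices_evaluated == 1

    def test_organ_with_no_evaluable_slices_is_missing(self):
        empty = np.zeros((8, 8), np.uint8)
        pairs = [(self._sets({"cervix": empty}), self._sets({"cervix": empty}))]
        rep = metrics.evaluate(pairs, spacing=1.0)
        assert "cervix" not in rep

    def test_jaccard_below_dice_in_report(self, rng):
        pairs = []
        for _ in range(4):
            a = {o: _mask(rng, 16, 16) for o in ("bladder", "cervix",
                                                 "rectum")}
            b = {o: _mask(rng, 16, 16) for o in ("bladder", "cervix",
                                                 "rectum")}
            pairs.append((self._sets(a), self._sets(b)))
        rep = metrics.evaluate(pairs, spacing=1.0)
        for o in rep.organs:
            assert rep[o].jaccard_mean <= rep[o].dice_mean + 1e-12

    def test_report_frame_layout(self, rng):
        m = {o: _mask(rng) for o in ("bladder", "cervix", "rectum")}
        for v in m.values():
            v[4, 4] = 1
        s = self._sets(m)
        frame = metrics.evaluate([(s, s)], spacing=1.0).to_frame()
        assert set(frame.columns) == {"organ", "metric", "mean", "sd", "n"}
        assert len(frame) == 9
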