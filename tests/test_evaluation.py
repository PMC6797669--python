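"""TRE, Dice variants, mask statistics, Pearson and capture range."""

import numpy as np
import pytest

from usreg import (
    CaptureRangeProtocol,
    LandmarkSet,
    Mask3D,
    RigidTransform,
    TransformChain,
    Volume3D,
    capture_range,
    capture_range_from_table,
    dice,
    dice_correspondence_restricted,
    mask_stats,
    pearson,
    tre,
)
from usreg.errors import CorrespondenceError, UndefinedStatisticError


def _mask(arr, spacing=(1, 1, 1)):
    v = Volume3D(data=np.zeros(arr.shape, np.float32), spacing=spacing, origin=(0, 0, 0))
    return Mask3D.like(v, np.asarray(arr).astype(np.uint8))


class TestTRE:
    def test_identical_sets_zero(self, rng):
        lm = LandmarkSet(rng.uniform(0, 10, (6, 3)))
        rep = tre(lm, LandmarkSet(lm.points.copy()))
        assert rep.mean == rep.max == 0.0
        assert rep.n_landmarks == 6

    def test_three_four_five_offset(self, rng):
        a = LandmarkSet(rng.uniform(0, 10, (5, 3)))
        b = LandmarkSet(a.points + np.array([3.0, 4.0, 0.0]))
        rep = tre(a, b)
        assert rep.mean == pytest.approx(5.0)
        assert rep.std == pytest.approx(0.0)
        assert rep.min == rep.max == pytest.approx(5.0)

    def test_matches_per_point_oracle(self, rng):
        a = LandmarkSet(rng.uniform(0, 10, (7, 3)))
        b = LandmarkSet(rng.uniform(0, 10, (7, 3)))
        chain = TransformChain([RigidTransform(translation=[1, 0, -2],
                                               rotation=[0.1, 0, 0.05], center=[5, 5, 5])])
        rep = tre(a, b, chain)
        for i in range(7):
            d = np.linalg.norm(chain.apply(a.points[i]) - b.points[i])
            assert rep.distances[i] == pytest.approx(d)

    def test_size_mismatch_is_correspondence_error(self, rng):
        with pytest.raises(CorrespondenceError):
            tre(LandmarkSet(rng.random((3, 3))), LandmarkSet(rng.random((2, 3))))

    def test_invariant_under_global_rigid_conjugation(self, rng):
        a = LandmarkSet(rng.uniform(0, 10, (6, 3)))
        b = LandmarkSet(rng.uniform(0, 10, (6, 3)))
        chain = TransformChain([RigidTransform(translation=[0.5, -1, 2])])
        g = RigidTransform(translation=[4, 1, -3], rotation=[0.2, -0.1, 0.3], center=[2, 2, 2])
        ga = LandmarkSet(g.apply(a.points))
        gb = LandmarkSet(g.apply(b.points))
        conj = TransformChain([g.inverse(), *chain.steps, g])
        np.testing.assert_allclose(tre(ga, gb, conj).distances, tre(a, b, chain).distances,
                                   atol=1e-9)


class TestDice:
    def test_examples_and_oracle(self, rng):
        a = np.zeros((4, 4, 4), bool)
        a[:2, :2, :2] = True
        b = np.zeros((4, 4, 4), bool)
        b[1:3, :2, :2] = True
        assert dice(_mask(a), _mask(a)) == 1.0
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)
        r1 = rng.random((5, 5, 5)) > 0.6
        r2 = rng.random((5, 5, 5)) > 0.6
        inter = np.logical_and(r1, r2).sum()
        expected = 2 * inter / (r1.sum() + r2.sum())
        assert dice(_mask(r1), _mask(r2)) == pytest.approx(expected)

    def test_correspondence_restricted_discards_false_positives(self):
        manual = np.zeros((10, 10, 10), bool)
        manual[1:4, 1:4, 1:4] = True
        pred = manual.copy()
        pred[7:9, 7:9, 7:9] = True  # far disjoint blob
        assert dice(_mask(pred), _mask(manual)) < 1.0
        assert dice_correspondence_restricted(_mask(pred), _mask(manual)) == 1.0

    def test_correspondence_restricted_no_overlap_is_zero(self):
        manual = np.zeros((8, 8, 8), bool)
        manual[:2, :2, :2] = True
        pred = np.zeros((8, 8, 8), bool)
        pred[5:7, 5:7, 5:7] = True
        assert dice_correspondence_restricted(_mask(pred), _mask(manual)) == 0.0

    def test_mixed_components_match_bookkeeping_oracle(self):
        from scipy import ndimage

        manual = np.zeros((12, 12, 12), bool)
        manual[2:5, 2:5, 2:5] = True
        pred = np.zeros((12, 12, 12), bool)
        pred[3:6, 3:6, 3:6] = True      # overlapping component
        pred[9:11, 9:11, 9:11] = True   # disjoint component
        labels, n = ndimage.label(pred, structure=np.ones((3, 3, 3)))
        kept = np.zeros_like(pred)
        for lab in range(1, n + 1):
            comp = labels == lab
            if np.logical_and(comp, manual).any():
                kept |= comp
        expected = 2 * np.logical_and(kept, manual).sum() / (kept.sum() + manual.sum())
        got = dice_correspondence_restricted(_mask(pred), _mask(manual))
        assert got == pytest.approx(expected)

    def test_restricted_never_below_plain(self, rng):
        for _ in range(10):
            a = rng.random((8, 8, 8)) > 0.7
            b = rng.random((8, 8, 8)) > 0.7
            assert dice_correspondence_restricted(_mask(a), _mask(b)) >= dice(_mask(a), _mask(b)) - 1e-12


class TestMaskStats:
    def test_constant_volume(self):
        v = Volume3D(data=np.full((4, 4, 4), 7.0, np.float32), spacing=(1, 1, 1), origin=(0, 0, 0))
        m = Mask3D.like(v, (np.arange(64).reshape(4, 4, 4) % 2).astype(np.uint8))
        st = mask_stats(v, m)
        assert st.mean_inside == pytest.approx(7.0)
        assert st.mean_outside == pytest.approx(7.0)

    def test_checkerboard(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        board = (idx % 2).astype(np.float32)
        v = Volume3D(data=board, spacing=(0.5, 0.5, 0.5), origin=(0, 0, 0))
        m = Mask3D.like(v, (board > 0).astype(np.uint8))
        st = mask_stats(v, m)
        assert st.mean_inside == pytest.approx(1.0)
        assert st.mean_outside == pytest.approx(0.0)
        assert st.volume_mm3 == pytest.approx((board > 0).sum() * 0.125)

    def test_phantom_contrast(self, small_case):
        st = mask_stats(small_case.volume, small_case.mask)
        assert st.mean_inside > st.mean_outside

    def test_empty_mask_reports_missing(self):
        v = Volume3D(data=np.ones((4, 4, 4), np.float32), spacing=(1, 1, 1), origin=(0, 0, 0))
        st = mask_stats(v, Mask3D.like(v, np.zeros((4, 4, 4), np.uint8)))
        assert st.mean_inside is None


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(UndefinedStatisticError):
            pearson([1, 1, 1], [1, 2, 3])


class TestCaptureRange:
    def test_fixed_table_definition(self):
        table = {1.0: (5, 5), 2.0: (5, 5), 3.0: (3, 5)}
        res = capture_range_from_table(table, 0.80)
        assert res.range_mm == 2.0
        assert not res.censored

    def test_all_pass_is_censored(self):
        res = capture_range_from_table({1.0: (5, 5), 2.0: (4, 5)}, 0.80)
        assert res.range_mm == 2.0
        assert res.censored

    def test_no_offset_passes(self):
        res = capture_range_from_table({1.0: (1, 5)}, 0.80)
        assert res.range_mm == 0.0
        assert res.diagnostic

    def test_threshold_monotonicity(self, small_case, rng):
        # with a fixed stub registration, enlarging the success threshold
        # never decreases the returned range
        residuals = {}

        def stub(ref, tmpl, init):
            # pretend registration corrects 80% of the initial misalignment
            return TransformChain([RigidTransform(translation=0.2 * init.translation)])

        proto_small = CaptureRangeProtocol(offsets_mm=(1.0, 2.0, 3.0), trials_per_offset=3,
                                           success_threshold_mm=0.45)
        proto_large = CaptureRangeProtocol(offsets_mm=(1.0, 2.0, 3.0), trials_per_offset=3,
                                           success_threshold_mm=0.65)
        lm = small_case.landmarks
        r_small = capture_range(small_case.mask, small_case.mask, lm, lm,
                                proto_small, seed=0, register_fn=stub)
        r_large = capture_range(small_case.mask, small_case.mask, lm, lm,
                                proto_large, seed=0, register_fn=stub)
        assert r_large.range_mm >= r_small.range_mm
        # residual = 0.2 * offset, so thresholds 0.45 / 0.65 cut at 2 / 3 mm
        assert r_small.range_mm == 2.0
        assert r_large.range_mm == 3.0

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            CaptureRangeProtocol(offsets_mm=(2.0, 1.0))
        with pytest.raises(ValueError):
            CaptureRangeProtocol(success_fraction=0.0)
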