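import math

import numpy as np
import pytest

from uslesion import (BBox, Delta, OracleRegressor, ZeroRegressor, apply_delta,
                      box_jaccard, encode_delta, iterate_regression,
                      regression_loss, smooth_l1, step_target)
from uslesion.regress import train_regressor

from conftest import random_box


class TestDeltaTransforms:
    def test_translation_only_worked_case(self):
        d = encode_delta(BBox(10, 20, 40, 60), BBox(14, 26, 40, 60))
        assert (d.t_x, d.t_y, d.t_w, d.t_h) == pytest.approx((0.1, 0.1, 0.0, 0.0))

    def test_identity(self):
        b = BBox(3, 4, 5, 6)
        assert encode_delta(b, b) == Delta(0, 0, 0, 0)
        assert apply_delta(b, Delta(0, 0, 0, 0)) == b

    def test_width_doubling_is_log_two(self):
        d = encode_delta(BBox(0, 0, 10, 10), BBox(0, 0, 20, 10))
        assert d.t_w == pytest.approx(math.log(2))
        assert (d.t_x, d.t_y, d.t_h) == (0, 0, 0)

    def test_apply_worked_case(self):
        out = apply_delta(BBox(0, 0, 10, 10), Delta(0.5, 0.2, math.log(2), 0))
        assert (out.x, out.y, out.w, out.h) == pytest.approx((5, 2, 20, 10))

    def test_round_trip_on_random_pairs(self, rng):
        for _ in range(1000):
            b, g = random_box(rng), random_box(rng)
            out = apply_delta(b, encode_delta(b, g))
            assert abs(out.x - g.x) <= 1e-9
            assert abs(out.y - g.y) <= 1e-9
            assert abs(out.w - g.w) <= 1e-9
            assert abs(out.h - g.h) <= 1e-9


class TestStepTarget:
    def test_first_step_closes_quarter_of_gap(self):
        t = step_target(BBox(0, 0, 10, 10), BBox(8, 0, 10, 10), s=1, S=4)
        assert (t.x, t.y, t.w, t.h) == pytest.approx((2, 0, 10, 10))

    def test_last_step_target_is_truth(self, rng):
        for _ in range(20):
            b, g = random_box(rng), random_box(rng)
            t = step_target(b, g, s=5, S=5)
            assert (t.x, t.y, t.w, t.h) == pytest.approx((g.x, g.y, g.w, g.h))

    def test_truth_is_fixed_point(self):
        g = BBox(4, 5, 6, 7)
        for s in range(1, 5):
            assert step_target(g, g, s, 4) == g

    @pytest.mark.parametrize("s,S", [(0, 4), (5, 4), (-1, 3)])
    def test_step_out_of_range(self, s, S):
        with pytest.raises(ValueError):
            step_target(BBox(0, 0, 1, 1), BBox(0, 0, 1, 1), s, S)


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (0.5, 0.125), (-2.0, 1.5), (1.0, 0.5), (-0.999, 0.4990005),
    ])
    def test_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_vectorized(self):
        out = smooth_l1(np.array([0.0, 0.5, -2.0]))
        assert np.allclose(out, [0.0, 0.125, 1.5])


class TestRegressionLoss:
    def test_exact_predictions_give_zero(self, rng):
        boxes = [random_box(rng) for _ in range(5)]
        truths = [random_box(rng) for _ in range(5)]
        preds = [encode_delta(b, step_target(b, g, 2, 4))
                 for b, g in zip(boxes, truths)]
        terms = regression_loss(preds, boxes, truths, s=2, S=4, bg_bound=0.0)
        assert terms.total == pytest.approx(0.0, abs=1e-12)

    def test_background_box_contributes_nothing(self):
        b, g = BBox(0, 0, 10, 10), BBox(10, 0, 10, 10)  # disjoint, J = 0
        terms = regression_loss([Delta(1, 1, 1, 1)], [b], [g], s=1, S=1)
        assert terms.total == 0.0
        assert not terms.foreground[0]

    def test_worked_half_overlap_case(self):
        """B and G overlap at J = 1/3; a zero prediction against the single-
        step target delta (0.5, 0, 0, 0) costs smooth_l1(0.5) = 0.125."""
        b, g = BBox(0, 0, 10, 10), BBox(5, 0, 10, 10)
        terms = regression_loss([Delta(0, 0, 0, 0)], [b], [g], s=1, S=1)
        assert terms.total == pytest.approx(0.125)
        assert terms.foreground[0]

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            regression_loss([], [BBox(0, 0, 1, 1)], [BBox(0, 0, 1, 1)], 1, 1)


class TestIteration:
    def test_zero_stub_keeps_box_fixed(self):
        b = BBox(1, 2, 3, 4)
        traj = iterate_regression(b, np.zeros((20, 20)), ZeroRegressor(), 4)
        assert len(traj) == 5
        assert all(t == b for t in traj)

    @pytest.mark.parametrize("S", [1, 2, 4, 8])
    def test_oracle_reaches_truth_in_exactly_S_steps(self, S, rng):
        for _ in range(25):
            b, g = random_box(rng), random_box(rng)
            traj = iterate_regression(b, np.zeros((64, 64)), OracleRegressor(g), S)
            last = traj[-1]
            assert len(traj) == S + 1
            for got, want in zip((last.x, last.y, last.w, last.h),
                                 (g.x, g.y, g.w, g.h)):
                assert abs(got - want) <= 1e-9

    def test_oracle_iou_never_decreases(self, rng):
        for _ in range(100):
            b, g = random_box(rng), random_box(rng)
            traj = iterate_regression(b, np.zeros((64, 64)), OracleRegressor(g), 4)
            ious = [box_jaccard(t, g) for t in traj]
            assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(ious, ious[1:]))

    def test_invalid_step_count(self):
        with pytest.raises(ValueError):
            iterate_regression(BBox(0, 0, 1, 1), np.zeros((4, 4)),
                               ZeroRegressor(), 0)


class TestTrainRegressor:
    def test_empty_samples_error(self):
        with pytest.raises(ValueError):
            train_regressor([])

    def test_all_background_samples_error(self):
        img = np.zeros((40, 40))
        samples = [(img, BBox(0, 0, 5, 5), BBox(30, 30, 5, 5))]  # disjoint
        with pytest.raises(ValueError, match="background"):
            train_regressor(samples)
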