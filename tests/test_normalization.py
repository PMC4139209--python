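"""Normalization contracts: M/A transform, lowess detrending, centering."""

import numpy as np
import pytest

from atromir.matrix import ExpressionMatrix
from atromir.normalization import (MAArray, average_replicate_spots,
                                   between_array_center, compute_ma,
                                   lowess_normalize)


class TestComputeMA:
    def test_equal_channels_give_zero_ratio(self):
        arr = compute_ma(np.array([100.0]), np.array([100.0]))
        assert arr.M[0] == pytest.approx(0.0)
        assert arr.A[0] == pytest.approx(np.log2(100), abs=1e-4)

    def test_doubling_gives_unit_log_ratio(self):
        arr = compute_ma(np.array([200.0]), np.array([100.0]))
        assert arr.M[0] == pytest.approx(1.0)

    def test_nonpositive_channel_masks_without_error(self):
        arr = compute_ma(np.array([100.0, 50.0]), np.array([0.0, 25.0]))
        assert arr.mask[0] and not arr.mask[1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_ma(np.ones(3), np.ones(2))


class TestLowessNormalize:
    def test_flat_input_is_fixed_point(self):
        arr = MAArray(np.zeros(50), np.linspace(4, 14, 50), np.zeros(50, bool))
        out = lowess_normalize(arr)
        assert np.allclose(out.M, 0.0, atol=1e-9)

    def test_sinusoidal_dye_bias_removed(self, rng):
        n = 2000
        A = rng.uniform(4, 14, n)
        planted = np.zeros(n)
        planted[:50] = 2.0
        M = 0.5 * np.sin(A) + planted
        out = lowess_normalize(MAArray(M, A, np.zeros(n, bool)))
        assert np.median(np.abs(out.M[50:])) < 0.05

    def test_linear_bias_with_full_span_removed_exactly(self):
        A = np.linspace(0, 10, 100)
        out = lowess_normalize(MAArray(0.3 + 0.2 * A, A, np.zeros(100, bool)),
                               frac=1.0, iters=0)
        assert np.max(np.abs(out.M)) < 1e-6

    def test_idempotent_to_tolerance(self, rng):
        # absolute tolerance at post-normalization residual scale, plus a
        # scale-relative bound on a noisier instance
        n = 1500
        A = rng.uniform(4, 14, n)
        o1 = lowess_normalize(MAArray(rng.normal(0, 0.02, n), A,
                                      np.zeros(n, bool)))
        o2 = lowess_normalize(o1)
        assert np.sqrt(np.mean((o2.M - o1.M) ** 2)) < 1e-3
        b1 = lowess_normalize(MAArray(rng.normal(0, 0.3, n), A,
                                      np.zeros(n, bool)))
        b2 = lowess_normalize(b1)
        rel = np.sqrt(np.mean((b2.M - b1.M) ** 2)) / np.sqrt(np.mean(b1.M ** 2))
        assert rel < 0.05

    def test_mask_preserved_and_too_few_spots_rejected(self, rng):
        n = 60
        mask = np.zeros(n, bool)
        mask[::3] = True
        arr = MAArray(rng.normal(size=n), rng.uniform(4, 14, n), mask)
        out = lowess_normalize(arr)
        assert np.array_equal(out.mask, mask)
        tiny = MAArray(np.zeros(9), np.arange(9.0), np.zeros(9, bool))
        with pytest.raises(ValueError, match="median centering"):
            lowess_normalize(tiny)


class TestBetweenArrayCenter:
    def test_constant_offset_removed(self):
        base = np.array([[0.1], [0.5], [-0.2], [0.0], [0.3]])
        m = ExpressionMatrix(
            [f"f{i}" for i in range(5)], ["a", "b"],
            np.hstack([base, base + 3.0]),
        )
        out = between_array_center(m)
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_idempotent(self, rng):
        m = ExpressionMatrix(
            [f"f{i}" for i in range(40)], ["a", "b", "c"],
            rng.normal(size=(40, 3)),
        )
        once = between_array_center(m)
        twice = between_array_center(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_disjoint_masks_center_on_unmasked_only(self):
        # hand-computed 3x2: array a observes (1, 3) -> median 2;
        # array b observes (10, 20) -> median 15
        vals = np.array([[1.0, np.nan], [3.0, 10.0], [np.nan, 20.0]])
        m = ExpressionMatrix(["f1", "f2", "f3"], ["a", "b"], vals)
        out = between_array_center(m)
        assert out.values[0, 0] == pytest.approx(-1.0)
        assert out.values[1, 0] == pytest.approx(1.0)
        assert out.values[1, 1] == pytest.approx(-5.0)
        assert out.values[2, 1] == pytest.approx(5.0)
        assert np.array_equal(out.mask, m.mask)

    def test_per_array_median_zero_after_loess_pseudo(self, rng):
        vals = rng.normal(size=(200, 4)) + np.array([0.0, 1.0, -0.5, 2.0])
        m = ExpressionMatrix([f"f{i}" for i in range(200)],
                             list("abcd"), vals)
        out = between_array_center(m, method="loess_pseudo")
        for j in range(4):
            assert abs(np.median(out.values[:, j])) < 1e-9

    def test_fully_masked_array_named_in_error(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        m = ExpressionMatrix(["f1", "f2"], ["ok", "dead"], vals)
        with pytest.raises(ValueError, match="dead"):
            between_array_center(m)


class TestAverageReplicateSpots:
    def test_mean_of_replicates(self):
        arr = MAArray(np.array([1.0, 3.0]), np.zeros(2), np.zeros(2, bool),
                      spot_map=["g1", "g1"])
        ids, vals, mask = average_replicate_spots(arr)
        assert ids == ["g1"] and vals[0] == pytest.approx(2.0) and not mask[0]

    def test_masked_spot_excluded(self):
        arr = MAArray(np.array([1.0, 99.0]), np.zeros(2),
                      np.array([False, True]), spot_map=["g1", "g1"])
        _, vals, mask = average_replicate_spots(arr)
        assert vals[0] == pytest.approx(1.0) and not mask[0]

    def test_all_spots_masked_masks_feature(self):
        arr = MAArray(np.array([1.0, 2.0]), np.zeros(2),
                      np.array([True, True]), spot_map=["g1", "g1"])
        _, _, mask = average_replicate_spots(arr)
        assert mask[0]

    def test_unmapped_spot_rejected(self):
        arr = MAArray(np.array([1.0]), np.zeros(1), np.zeros(1, bool),
                      spot_map=None)
        with pytest.raises(ValueError):
            average_replicate_spots(arr)
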