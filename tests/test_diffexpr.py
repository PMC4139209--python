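"""Permutation ANOVA, fold-change classes and the SAM-style statistic."""

import numpy as np
import pytest
from scipy import stats

from atromir.diffexpr import (classify_de, fold_change, permutation_anova,
                              sam_two_class)
from atromir.matrix import ExpressionMatrix, SampleMeta


def make_matrix(values, groups, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    ids = feature_ids or [f"f{i}" for i in range(n_f)]
    sids = [f"s{j}" for j in range(n_s)]
    meta = {s: SampleMeta(g) for s, g in zip(sids, groups)}
    return ExpressionMatrix(ids, sids, values, sample_meta=meta)


class TestPermutationAnova:
    def test_no_between_group_variance_gives_f_zero_p_one(self):
        m = make_matrix([[1.0, 1.0, 1.0, 1.0]], ["a", "a", "b", "b"])
        (r,) = permutation_anova(m, n_perm=50, rng_seed=0)
        assert r.F_stat == 0.0
        assert r.p_perm == 1.0

    def test_perfect_separation_attains_minimum_p(self):
        m = make_matrix([[0.0, 0.0, 10.0, 10.0]], ["a", "a", "b", "b"])
        (r,) = permutation_anova(m, n_perm=1000, rng_seed=0)
        assert np.isinf(r.F_stat)
        # 4 labels -> 24 arrangements enumerated; 8 preserve the partition
        assert r.p_perm == pytest.approx((1 + 8) / 25)

    def test_p_invariant_to_feature_scaling(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=12)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        m1 = make_matrix([row], groups)
        m2 = make_matrix([row * 7.3], groups)
        r1 = permutation_anova(m1, n_perm=200, rng_seed=5)[0]
        r2 = permutation_anova(m2, n_perm=200, rng_seed=5)[0]
        assert r1.p_perm == r2.p_perm

    def test_masked_out_group_marks_feature_untested(self):
        vals = [[1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0]]
        m = make_matrix(vals, ["a", "a", "b", "b"])
        res = permutation_anova(m, n_perm=20, rng_seed=0)
        assert not res[0].tested
        assert res[1].tested

    def test_optional_bh_adjustment_fills_p_adj(self):
        rng = np.random.default_rng(6)
        groups = ["a"] * 3 + ["b"] * 3
        m = make_matrix(rng.normal(size=(30, 6)), groups)
        plain = permutation_anova(m, n_perm=50, rng_seed=2)
        adj = permutation_anova(m, n_perm=50, rng_seed=2, bh_adjust=True)
        assert all(r.p_adj is None for r in plain)
        assert all(r.p_adj is not None and r.p_adj >= r.p_perm - 1e-12
                   for r in adj if r.tested)

    def test_null_p_values_not_anticonservative(self):
        rng = np.random.default_rng(11)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        m = make_matrix(rng.normal(size=(400, 12)), groups)
        pvals = [r.p_perm for r in permutation_anova(m, n_perm=200, rng_seed=1)]
        # stochastically >= uniform: one-sided KS must not reject
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestFoldChange:
    def test_basic_and_derived_values(self):
        vals = [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, -0.3219, -0.3219]]
        m = make_matrix(vals, ["control", "control", "Den7", "Den7"])
        fc = fold_change(m, "Den7")
        assert fc["f0"] == pytest.approx(1.0)
        assert fc["f1"] == pytest.approx(2.0)
        assert fc["f2"] == pytest.approx(0.8, abs=1e-4)

    def test_missing_condition_rejected(self):
        m = make_matrix([[0.0, 1.0]], ["control", "Den7"])
        with pytest.raises(ValueError):
            fold_change(m, "STZ")

    def test_no_control_columns_uses_zero_reference(self):
        m = make_matrix([[1.0, 1.0]], ["Den7", "Den7"])
        assert fold_change(m, "Den7")["f0"] == pytest.approx(2.0)


class TestClassifyDe:
    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (1.0, 0.001, "unchanged"),   # inside the dead band
            (1.3, 0.01, "up"),
            (0.5, 0.2, "unchanged"),     # fails significance
            (0.7, 0.01, "down"),
            (1.2, 0.01, "unchanged"),    # boundary excluded
        ],
    )
    def test_dead_band_and_significance(self, fc, p, expected):
        assert classify_de(fc, p) == expected

    def test_monotone_in_fc(self):
        # raising fc at fixed p never demotes an up call
        fcs = np.linspace(0.5, 3.0, 60)
        classes = [classify_de(f, 0.01) for f in fcs]
        first_up = classes.index("up")
        assert all(c == "up" for c in classes[first_up:])

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            classify_de(0.0, 0.01)


class TestSamTwoClass:
    def test_identical_groups_give_zero_d(self):
        vals = np.tile([1.0, 2.0, 1.0, 2.0], (5, 1))
        m = make_matrix(vals, ["x", "x", "y", "y"])
        res = sam_two_class(m, ["x", "x", "y", "y"], "x", "y",
                            n_perm=20, rng_seed=0)
        assert all(r.d_stat == pytest.approx(0.0) for r in res)

    def test_planted_shift_attains_max_abs_d(self):
        rng = np.random.default_rng(8)
        sd = 0.2
        vals = rng.normal(0, sd, size=(500, 8))
        vals[7, 4:] += 5 * sd
        groups = ["x"] * 4 + ["y"] * 4
        m = make_matrix(vals, groups)
        res = sam_two_class(m, groups, "x", "y", n_perm=50, rng_seed=0)
        ds = np.array([r.d_stat for r in res])
        assert np.argmax(np.abs(ds)) == 7
        assert res[7].q_value <= 0.05

    def test_with_zero_s0_matches_t_statistic_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 10))
        groups = ["x"] * 5 + ["y"] * 5
        m = make_matrix(vals, groups)
        res = sam_two_class(m, groups, "x", "y", n_perm=5, rng_seed=0, s0=0.0)
        for i, r in enumerate(res):
            a, b = vals[i, :5], vals[i, 5:]
            pooled = ((a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8) ** 0.5
            se = pooled * np.sqrt(1 / 5 + 1 / 5)
            assert r.d_stat == pytest.approx((a.mean() - b.mean()) / se, rel=1e-9)

    def test_absent_group_rejected(self):
        m = make_matrix([[1.0, 2.0]], ["x", "x"])
        with pytest.raises(ValueError):
            sam_two_class(m, ["x", "x"], "x", "zzz", n_perm=5, rng_seed=0)
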