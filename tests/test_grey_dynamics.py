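import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from greynet.grey_dynamics import (
    AssociationMatrix,
    DgaParams,
    build_window_schedule,
    dynamic_grey_association,
    first_difference,
    next_window_length,
    softmax_entropy,
    window_relational_grade,
)
from greynet.io_formats import ExpressionTable, ValidationError

from _oracles import oracle_dga, oracle_entropy, oracle_schedule


class TestFirstDifference:
    def test_consecutive_differences(self):
        np.testing.assert_allclose(first_difference([1, 3, 6, 10]), [2, 3, 4])
        np.testing.assert_allclose(first_difference([5, 5, 5]), [0, 0])
        assert first_difference([1.0, 2.5]).shape == (1,)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            first_difference([1.0])


class TestSoftmaxEntropy:
    def test_uniform_segment_hits_log2_bound(self):
        rec = softmax_entropy([3.0, 3.0, 3.0, 3.0])
        np.testing.assert_allclose(rec.probabilities, [0.25] * 4)
        assert rec.entropy == pytest.approx(2.0)

    def test_singleton_has_zero_entropy(self):
        rec = softmax_entropy([7.0])
        assert rec.probabilities[0] == 1.0
        assert rec.entropy == 0.0

    def test_hand_computed_two_point_case(self):
        # |d| = [0, ln 2]: exp -> [1, 2], p = [1/3, 2/3]
        rec = softmax_entropy([0.0, math.log(2)])
        np.testing.assert_allclose(rec.probabilities, [1 / 3, 2 / 3], atol=1e-12)
        expected = -(1 / 3) * math.log2(1 / 3) - (2 / 3) * math.log2(2 / 3)
        assert rec.entropy == pytest.approx(expected)
        assert rec.entropy == pytest.approx(0.9183, abs=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12)
    )
    def test_entropy_bounds_and_probability_simplex(self, seg):
        rec = softmax_entropy(seg)
        assert 0.0 <= rec.entropy <= math.log2(len(seg)) + 1e-9
        assert rec.probabilities.min() >= 0
        assert rec.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        # equality with log2(L) iff |d| constant
        if len(set(abs(v) for v in seg)) == 1:
            assert rec.entropy == pytest.approx(math.log2(len(seg)))

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            seg = rng.normal(size=rng.integers(1, 10))
            assert softmax_entropy(seg).entropy == pytest.approx(
                oracle_entropy(seg), abs=1e-12
            )


class TestNextWindowLength:
    def test_unit_ratio_keeps_length(self):
        assert next_window_length(1.5, 1.5, 4, (2, 10)) == 4

    def test_clamped_to_bounds(self):
        assert next_window_length(2.0, 1.0, 3, (2, 5)) == 5
        assert next_window_length(1.0, 2.0, 4, (2, 10)) == 2

    def test_zero_previous_entropy_keeps_length(self):
        assert next_window_length(1.0, 0.0, 3, (2, 10)) == 3

    def test_round_half_to_even(self):
        # ratio 0.5 * L_prev 5 = 2.5 -> rounds to 2 (half-to-even)
        assert next_window_length(1.0, 2.0, 5, (2, 10)) == 2
        # ratio 0.5 * 7 = 3.5 -> 4
        assert next_window_length(1.0, 2.0, 7, (2, 10)) == 4


class TestWindowSchedule:
    def test_constant_series_constant_lengths(self):
        # constant diffs -> uniform softmax -> entropy log2(L) each window;
        # first ratio log2(3)/log2(3)=1, later ratios 1 -> all lengths 3
        sched = build_window_schedule(np.arange(10.0), 3, (2, 9))
        assert [l for _, l in sched.windows] == [3, 3, 3]

    def test_single_leftover_point_joins_last_window(self):
        sched = build_window_schedule(np.arange(8.0), 3, (2, 7))  # 7 diffs
        assert sched.windows == [(0, 3), (3, 4)]

    def test_tiling_covers_difference_axis(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 30))
            series = rng.normal(size=n)
            L_init = int(rng.integers(2, max(3, (n - 1) // 2 + 1)))
            sched = build_window_schedule(series, L_init, (2, n - 1))
            starts = [s for s, _ in sched.windows]
            lens = [l for _, l in sched.windows]
            assert starts[0] == 0
            for i in range(1, len(starts)):  # no gaps, no overlaps
                assert starts[i] == starts[i - 1] + lens[i - 1]
            assert sum(lens) == n - 1
            assert all(2 <= l for l in lens)
            assert all(l <= n - 1 for l in lens)

    def test_recurrence_matches_step_by_step_oracle(self, rng):
        series = rng.normal(loc=5.0, scale=2.0, size=21)
        sched = build_window_schedule(series, 4, (2, 10))
        assert sched.windows == oracle_schedule(list(series), 4, 2, 10)
        for _ in range(20):
            s = rng.normal(size=21)
            assert build_window_schedule(s, 4, (2, 10)).windows == oracle_schedule(
                list(s), 4, 2, 10
            )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            build_window_schedule(np.arange(4.0), 5, (2, 10))


class TestWindowRelationalGrade:
    def test_identical_series_grade_one(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        res = window_relational_grade(y, X, rho=0.5)
        np.testing.assert_allclose(res.xi[0], 1.0)
        assert res.grade[0] == pytest.approx(1.0)

    def test_pooled_max_position_value(self):
        # residuals: gene0 -> [0,0,0]; gene1 -> [M,0,0]; pooled min 0, max M
        # xi at the max-residual position = 0.5M / 1.5M = 1/3
        y = np.zeros(3)
        X = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        res = window_relational_grade(y, X, rho=0.5)
        assert res.xi[1, 0] == pytest.approx(1 / 3)
        assert res.xi[1, 1] == pytest.approx(1.0)

    def test_all_zero_residuals_degenerate_window(self):
        y = np.array([1.0, 2.0])
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        res = window_relational_grade(y, X)
        np.testing.assert_allclose(res.xi, 1.0)

    def test_no_comparatives_rejected(self):
        with pytest.raises(ValidationError):
            window_relational_grade([1.0, 2.0], np.empty((0, 2)))

    def test_coefficients_in_unit_interval(self, rng):
        for _ in range(20):
            y = rng.normal(size=5)
            X = rng.normal(size=(4, 5))
            res = window_relational_grade(y, X, rho=rng.uniform(0.05, 1.0))
            assert np.all(res.xi > 0) and np.all(res.xi <= 1.0 + 1e-12)


class TestDynamicGreyAssociation:
    def test_exact_copy_scores_one(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(1, 10, size=12)
        table = ExpressionTable(
            gene_ids=["g1", "copy", "other"],
            blocks=[np.vstack([base, base, rng.uniform(1, 10, size=12)])],
        )
        dga = dynamic_grey_association(table)
        i, j = 1, 0  # copy vs target g1
        assert dga.scores[i, j] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(10):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(6, 13))
            nb = int(rng.integers(1, 3))
            blocks = [rng.uniform(0, 10, size=(m, n)) for _ in range(nb)]
            table = ExpressionTable(
                gene_ids=[f"g{i}" for i in range(m)], blocks=blocks
            )
            got = dynamic_grey_association(table).scores
            want = np.array(oracle_dga([b.tolist() for b in blocks]))
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_off_diagonal_range(self, toy_table):
        dga = dynamic_grey_association(toy_table)
        off = dga.scores[~np.eye(3, dtype=bool)]
        assert np.all(off > 0) and np.all(off <= 1.0)
        assert np.all(np.diag(dga.scores) == 0)

    def test_gene_permutation_equivariance(self, toy_table):
        dga = dynamic_grey_association(toy_table).scores
        perm = [2, 0, 1]
        permuted = ExpressionTable(
            gene_ids=[toy_table.gene_ids[i] for i in perm],
            blocks=[b[perm] for b in toy_table.blocks],
        )
        dga_p = dynamic_grey_association(permuted).scores
        np.testing.assert_allclose(dga_p, dga[np.ix_(perm, perm)], atol=1e-12)

    def test_affine_scale_invariance_under_zscore(self, toy_table):
        dga = dynamic_grey_association(toy_table, DgaParams(normalization="zscore"))
        scaled_blocks = [b.copy() for b in toy_table.blocks]
        scaled_blocks[0][1] = 3.7 * scaled_blocks[0][1] + 11.0
        scaled = ExpressionTable(gene_ids=toy_table.gene_ids, blocks=scaled_blocks)
        dga_s = dynamic_grey_association(scaled, DgaParams(normalization="zscore"))
        np.testing.assert_allclose(dga_s.scores, dga.scores, atol=1e-10)

    def test_global_extrema_pooling_mode_runs(self, toy_table):
        dga = dynamic_grey_association(
            toy_table, DgaParams(pool_extrema="global")
        )
        off = dga.scores[~np.eye(3, dtype=bool)]
        assert np.all(off > 0) and np.all(off <= 1.0)

    def test_replicate_blocks_averaged(self, rng):
        b1 = rng.uniform(0, 5, size=(3, 8))
        b2 = rng.uniform(0, 5, size=(3, 8))
        both = ExpressionTable(gene_ids=["a", "b", "c"], blocks=[b1, b2])
        only1 = ExpressionTable(gene_ids=["a", "b", "c"], blocks=[b1])
        only2 = ExpressionTable(gene_ids=["a", "b", "c"], blocks=[b2])
        np.testing.assert_allclose(
            dynamic_grey_association(both).scores,
            0.5
            * (
                dynamic_grey_association(only1).scores
                + dynamic_grey_association(only2).scores
            ),
            atol=1e-12,
        )


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        DgaParams(rho=0.0)
    with pytest.raises(ValidationError):
        DgaParams(normalization="quantile")
    with pytest.raises(ValidationError):
        DgaParams(pool_extrema="everywhere")
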