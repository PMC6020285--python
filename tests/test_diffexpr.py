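"""Fold change, t-tests, BH adjustment and significance gating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossde import ExpressionMatrix, adjust_bh, de_test, fold_change, make_design, significant
from crossde.diffexpr import DETable, UP, DOWN, FLAT
from crossde.errors import ValidationError


def bh_brute_force(p):
    """BH by its definition: q_i = min over j>=i (sorted) of p_(j)*m/j, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = min(1.0, q_sorted[rank])
    return out


def welch_p_closed_form(a, b):
    """Textbook Welch t: statistic, Welch-Satterthwaite df, survival of t."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    tstat = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * tdist.sf(abs(tstat), df)


def matrix_from_log2(log2_a, log2_b):
    """Two-condition matrix from per-condition log2 rows (one gene per row)."""
    a = np.atleast_2d(np.asarray(log2_a, float))
    b = np.atleast_2d(np.asarray(log2_b, float))
    values = np.exp2(np.hstack([a, b]))
    cols = [f"a{i}" for i in range(a.shape[1])] + [f"b{i}" for i in range(b.shape[1])]
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(a.shape[0])], columns=cols)
    design = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return ExpressionMatrix(values=frame, design=design)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([20.0, 20.0], [10.0, 10.0], 2.0),
            ([5.0, 5.0], [5.0, 5.0], 1.0),
            ([8.0, 12.0], [5.0, 5.0], 2.0),  # arithmetic means: 10/5
        ],
    )
    def test_hand_examples(self, a, b, expected):
        frame = pd.DataFrame(
            [a + b], index=["g"], columns=["a1", "a2", "b1", "b2"]
        )
        m = ExpressionMatrix(values=frame, design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        fc = fold_change(m, make_design(m, "A", "B"))
        assert fc.loc["g", "fc"] == pytest.approx(expected)

    def test_orientation_reciprocity(self, rng):
        values = pd.DataFrame(
            np.exp2(rng.normal(8, 1, (30, 4))),
            index=[f"g{i}" for i in range(30)],
            columns=["a1", "a2", "b1", "b2"],
        )
        m = ExpressionMatrix(values=values, design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        ab = fold_change(m, make_design(m, "A", "B"))["fc"]
        ba = fold_change(m, make_design(m, "B", "A"))["fc"]
        np.testing.assert_allclose(ab * ba, 1.0, rtol=1e-12)

    def test_missing_condition_errors(self, tiny_matrix):
        with pytest.raises(ValidationError):
            make_design(tiny_matrix, "SHH", "Cyc")


class TestAdjustBH:
    def test_derived_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.005, 0.011, 0.02, 0.04]),
            [0.02, 0.022, 0.08 / 3, 0.04],
            rtol=1e-9,
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.3] * 7), [0.3] * 7)

    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_bh([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_definition(self, pvals):
        np.testing.assert_allclose(adjust_bh(pvals), bh_brute_force(pvals), rtol=1e-10, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1, allow_nan=False), min_size=1, max_size=40))
    def test_adjusted_at_least_raw(self, pvals):
        assert np.all(adjust_bh(pvals) >= np.asarray(pvals) - 1e-15)


class TestDeTest:
    def test_identical_groups_p_one(self):
        m = matrix_from_log2([5, 5, 5, 5], [5, 5, 5, 5])
        table = de_test(m, make_design(m, "A", "B"))
        row = table.frame.iloc[0]
        assert row["p"] == 1.0
        assert row["direction"] == FLAT

    def test_strong_separation_with_jitter(self):
        jit = np.array([1e-4, -1e-4, 2e-4, -2e-4])
        m = matrix_from_log2(5 + jit, 4 + jit)
        table = de_test(m, make_design(m, "A", "B"))
        row = table.frame.iloc[0]
        assert row["p"] < 1e-6
        assert row["direction"] == UP
        assert row["fc"] == pytest.approx(2.0, rel=1e-3)

    def test_zero_variance_unequal_means_smallest_positive(self, caplog):
        m = matrix_from_log2([5, 5, 5, 5], [4, 4, 4, 4])
        with caplog.at_level("WARNING"):
            table = de_test(m, make_design(m, "A", "B"))
        p = table.frame.iloc[0]["p"]
        assert 0 < p <= np.finfo(float).tiny
        assert "zero within-group variance" in caplog.text

    def test_sample_permutation_invariance(self, rng):
        values = np.exp2(rng.normal(8, 1, (25, 8)))
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        design = {c: ("A" if c.startswith("a") else "B") for c in cols}
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(25)], columns=cols)
        m1 = ExpressionMatrix(values=frame, design=design)
        shuffled = ["a2", "a0", "a3", "a1", "b3", "b1", "b0", "b2"]
        m2 = ExpressionMatrix(values=frame[shuffled], design=design)
        t1 = de_test(m1, make_design(m1, "A", "B")).frame
        t2 = de_test(m2, make_design(m2, "A", "B")).frame
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-12)
        np.testing.assert_allclose(t1["fc"], t2["fc"], rtol=1e-12)

    def test_welch_matches_textbook_closed_form(self, rng):
        a = np.array([5.1, 4.7])
        b = np.array([3.9, 4.4])
        m = matrix_from_log2(a, b)
        table = de_test(m, make_design(m, "A", "B"))
        assert table.frame.iloc[0]["p"] == pytest.approx(welch_p_closed_form(a, b), rel=1e-10)

    def test_student_t_matches_pooled_closed_form(self):
        from scipy.stats import t as tdist

        a = np.array([5.1, 4.7, 5.3])
        b = np.array([3.9, 4.4, 4.1])
        m = matrix_from_log2(a, b)
        table = de_test(m, make_design(m, "A", "B"), method="student_t")
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        expected = 2 * tdist.sf(abs(tstat), len(a) + len(b) - 2)
        assert table.frame.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)

    def test_unknown_method_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError, match="method"):
            de_test(tiny_matrix, make_design(tiny_matrix, "SHH", "Veh"), method="nonsense")


class TestSignificant:
    def _table(self, fdrs, directions):
        frame = pd.DataFrame(
            {
                "mean_a": 1.0, "mean_b": 1.0,
                "fc": [2.0 if d == UP else (0.5 if d == DOWN else 1.0) for d in directions],
                "log2fc": 0.0, "p": fdrs, "fdr": fdrs, "direction": directions,
            },
            index=[f"g{i}" for i in range(len(fdrs))],
        )
        return DETable("t", "A", "B", frame)

    def test_strict_inequality_at_threshold(self):
        t = self._table([0.009, 0.01, 0.5], [UP, UP, DOWN])
        assert significant(t, 0.01) == {("g0", UP)}

    def test_permissive_threshold(self):
        t = self._table([0.009, 0.01, 0.8], [UP, UP, DOWN])
        assert len(significant(t, 0.75)) == 2

    def test_alpha_one_returns_all_non_flat(self):
        t = self._table([0.2, 0.9, 0.99], [UP, DOWN, FLAT])
        assert significant(t, 1.0) == {("g0", UP), ("g1", DOWN)}

    def test_invalid_alpha(self):
        t = self._table([0.5], [UP])
        with pytest.raises(ValidationError):
            significant(t, 0.0)
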