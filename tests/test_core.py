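"""Residue/MSR algebra and the expression-matrix data model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from shieldbic import (
    Bicluster,
    DegenerateRegionError,
    ExpressionMatrix,
    axis_msr,
    means,
    msr,
    residues,
    variance,
)

from .conftest import axis_msr_oracle, msr_oracle

small_real_matrices = arrays(
    float,
    st.tuples(st.integers(3, 6), st.integers(3, 6)),
    elements=st.integers(-9, 9).map(float),
)


class TestMeans:
    @pytest.mark.parametrize(
        "mat, rows, cols, overall",
        [
            ([[1, 2], [3, 4]], [1.5, 3.5], [2, 3], 2.5),
            ([[7, 7], [7, 7]], [7, 7], [7, 7], 7.0),
        ],
    )
    def test_small_examples(self, mat, rows, cols, overall):
        rm, cm, ov = means(np.asarray(mat, dtype=float))
        np.testing.assert_allclose(rm, rows)
        np.testing.assert_allclose(cm, cols)
        assert ov == pytest.approx(overall)

    def test_interference_submatrix(self, table1_true):
        rm, cm, ov = means(table1_true)
        np.testing.assert_allclose(rm, [2.0, 3.0, 35.0])
        np.testing.assert_allclose(cm, [4.0, 5.0, 31.0])
        assert ov == pytest.approx(120.0 / 9.0)

    def test_empty_region_raises(self):
        with pytest.raises(DegenerateRegionError):
            means(np.empty((0, 3)))


class TestResidues:
    def test_additive_annihilation(self, additive_4x4):
        np.testing.assert_allclose(residues(additive_4x4), 0.0, atol=1e-12)

    def test_two_by_two(self):
        r = residues(np.array([[1.0, 2.0], [3.0, 5.0]]))
        np.testing.assert_allclose(r, [[0.25, -0.25], [-0.25, 0.25]])

    def test_linearity_imaginary(self, rng):
        m = rng.integers(-5, 5, size=(4, 5)).astype(float)
        np.testing.assert_allclose(residues(1j * m), 1j * residues(m))


class TestMSR:
    def test_examples(self, table1_true, table1_replaced):
        assert msr(table1_replaced) == 0.0
        assert msr(np.array([[1.0, 2.0], [3.0, 5.0]])) == pytest.approx(0.0625)
        assert msr(table1_true) == pytest.approx(349.78, abs=0.01)

    def test_variance_is_unnormalised_sum(self):
        assert variance(np.array([[1.0, 2.0], [3.0, 4.0]])) == pytest.approx(5.0)

    def test_rejects_complex(self):
        with pytest.raises(TypeError, match="shielding"):
            msr(np.array([[1 + 1j, 2], [3, 4]]))
        with pytest.raises(TypeError):
            axis_msr(np.array([[1 + 1j, 2], [3, 4]]), "row", 0)
        # complex dtype with zero imaginary part is fine
        assert msr(np.array([[1.0, 2.0], [3.0, 5.0]], dtype=complex)) == pytest.approx(0.0625)

    def test_axis_scores_and_decomposition(self):
        a = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert axis_msr(a, "row", 0) == pytest.approx(0.0625)
        rows = [axis_msr(a, "row", i) for i in range(2)]
        cols = [axis_msr(a, "col", j) for j in range(2)]
        assert np.mean(rows) == pytest.approx(msr(a))
        assert np.mean(cols) == pytest.approx(msr(a))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_real_matrices)
    def test_matches_loop_oracle(self, a):
        assert msr(a) == pytest.approx(msr_oracle(a), abs=1e-12)
        assert axis_msr(a, "row", 0) == pytest.approx(
            axis_msr_oracle(a, "row", 0), abs=1e-12
        )
        assert axis_msr(a, "col", a.shape[1] - 1) == pytest.approx(
            axis_msr_oracle(a, "col", a.shape[1] - 1), abs=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        small_real_matrices,
        st.integers(-20, 20).map(float),
        st.integers(1, 4),
    )
    def test_additive_invariance_and_scaling(self, a, shift, c):
        base = msr(a)
        shifted = a.copy()
        shifted[1, :] += shift  # constant added to one row
        assert msr(shifted) == pytest.approx(base, abs=1e-9)
        shifted = a.copy()
        shifted[:, 0] += shift  # constant added to one column
        assert msr(shifted) == pytest.approx(base, abs=1e-9)
        assert msr(c * a) == pytest.approx(c * c * base, rel=1e-9, abs=1e-9)
        np.testing.assert_allclose(residues(c * a), c * residues(a), atol=1e-9)

    def test_nonnegative_and_zero_iff_additive(self, rng, additive_4x4):
        assert msr(additive_4x4) == pytest.approx(0.0, abs=1e-12)
        noisy = additive_4x4 + rng.normal(0, 1, additive_4x4.shape)
        assert msr(noisy) > 0


class TestDataModel:
    def test_region_extraction_bit_exact(self, rng):
        values = rng.uniform(0, 800, size=(6, 5))
        A = ExpressionMatrix(values)
        bic = Bicluster((0, 2, 5), (1, 4), 0.0)
        sub = A.bicluster_region(bic)
        assert np.array_equal(sub, values[np.ix_([0, 2, 5], [1, 4])])

    def test_label_validation(self):
        with pytest.raises(ValueError, match="length"):
            ExpressionMatrix(np.ones((2, 2)), row_labels=["a"])
        with pytest.raises(ValueError, match="unique"):
            ExpressionMatrix(np.ones((2, 2)), col_labels=["x", "x"])

    def test_bicluster_invariants(self):
        b = Bicluster((1, 2), (0, 3), 1.5)
        assert (b.n_rows, b.n_cols, b.size) == (2, 2, 4)
        assert b.cells() == {(1, 0), (1, 3), (2, 0), (2, 3)}
        with pytest.raises(DegenerateRegionError):
            Bicluster((), (0,), 0.0)
        with pytest.raises(ValueError):
            Bicluster((0,), (0,), -1.0)

    def test_missing_value_imputation(self, rng):
        values = np.array([[1.0, -1.0], [4.0, 9.0]])
        A = ExpressionMatrix(values, missing_sentinel=-1.0)
        out = A.imputed(rng)
        assert not out.missing_mask().any()
        assert 1.0 <= out.values[0, 1] <= 9.0
        assert out.values[0, 0] == 1.0  # observed entries untouched
        # deterministic under an identical generator state
        again = A.imputed(np.random.default_rng(20240917))
        twice = A.imputed(np.random.default_rng(20240917))
        assert np.array_equal(again.values, twice.values)
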