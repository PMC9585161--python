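import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def additive_4x4():
    """Exactly additive matrix b + p_i + q_j: MSR 0 by construction."""
    p = np.array([0.0, 3.0, -2.0, 7.0])
    q = np.array([1.0, -4.0, 2.5, 0.0])
    return 10.0 + p[:, None] + q[None, :]


@pytest.fixture
def table1_true():
    """The 3x3 sub-matrix of the interference example with its true values."""
    return np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 0.0], [7.0, 8.0, 90.0]])


@pytest.fixture
def table1_replaced():
    """The same sub-matrix after masking produced the bracketed values."""
    return np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])


def msr_oracle(a):
    """Independent loop-based evaluation of the residue/MSR formulas."""
    a = np.asarray(a)
    n, m = a.shape
    row_means = [sum(a[i, j] for j in range(m)) / m for i in range(n)]
    col_means = [sum(a[i, j] for i in range(n)) / n for j in range(m)]
    overall = sum(a[i, j] for i in range(n) for j in range(m)) / (n * m)
    total = 0.0
    for i in range(n):
        for j in range(m):
            r = a[i, j] - row_means[i] - col_means[j] + overall
            total += r * r
    return total / (n * m)


def axis_msr_oracle(a, axis, index):
    a = np.asarray(a)
    n, m = a.shape
    row_means = [sum(a[i, j] for j in range(m)) / m for i in range(n)]
    col_means = [sum(a[i, j] for i in range(n)) / n for j in range(m)]
    overall = a.sum() / (n * m)
    if axis == "row":
        return sum(
            (a[index, j] - row_means[index] - col_means[j] + overall) ** 2
            for j in range(m)
        ) / m
    return sum(
        (a[i, index] - row_means[i] - col_means[index] + overall) ** 2
        for i in range(n)
    ) / n
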