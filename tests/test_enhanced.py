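"""The shielded discovery loop: overlap recovery, non-rediscovery, reporting."""

import numpy as np
import pytest

from shieldbic import (
    Bicluster,
    ExpressionMatrix,
    SearchParams,
    ShieldParams,
    cc_discover,
    filter_by_variance,
    msr,
    overlapping_pair_dataset,
    report,
    shielded_discover,
    summarize,
    table1_fixture,
)
from shieldbic.core import BiclusterSet
from shieldbic.io import best_matches

#: benchmark scale at which the greedy inner search operates reliably
#: (implants are a material fraction of the matrix)
BENCH = dict(n=60, m=20)
BENCH_PARAMS = dict(delta=50.0, min_rows=2, min_cols=2)


def test_first_iteration_equals_baseline():
    """With K = 1 no shielding (or masking) ever runs, so the two searches
    coincide exactly."""
    A, _ = overlapping_pair_dataset(seed=3, **BENCH)
    params = SearchParams(n_biclusters=1, seed=3, **BENCH_PARAMS)
    b_cc = cc_discover(A, params)[0]
    b_sh = shielded_discover(A, params)[0]
    assert b_cc.rows == b_sh.rows
    assert b_cc.cols == b_sh.cols
    assert b_cc.msr_real == pytest.approx(b_sh.msr_real, abs=1e-9)


def test_recovers_both_overlapping_implants():
    """Two additive implants sharing a 4x3 overlap: the shielded search
    recovers both footprints, overlap intact."""
    A, truth = overlapping_pair_dataset(seed=1, **BENCH)
    res = shielded_discover(A, SearchParams(n_biclusters=20, seed=1, **BENCH_PARAMS))
    scores = best_matches(res, truth)
    assert all(s >= 0.9 for s in scores)
    # the shared cells belong to both recovered biclusters
    overlap = set(truth.implants[0].as_bicluster().cells()) & set(
        truth.implants[1].as_bicluster().cells()
    )
    for spec in truth.implants:
        from shieldbic.io import match_score

        best = max(res, key=lambda b: match_score(b, spec.as_bicluster()))
        assert overlap <= best.cells()


def test_masking_baseline_corrupts_the_overlap():
    """Over ten seeded datasets the baseline's recovery of the second
    implant is strictly worse on average: masking the first bicluster
    destroys the shared cells, while shielding preserves them."""
    cc_second, sh_second = [], []
    for seed in range(10):
        A, truth = overlapping_pair_dataset(seed=seed, **BENCH)
        params = SearchParams(n_biclusters=20, seed=seed, **BENCH_PARAMS)
        r_cc = cc_discover(A, params)
        r_sh = shielded_discover(A, params)
        m_cc = best_matches(r_cc, truth)
        m_sh = best_matches(r_sh, truth)
        # "second" = the implant the baseline recovered worse
        k = int(np.argmin(m_cc))
        cc_second.append(m_cc[k])
        sh_second.append(m_sh[k])
    assert np.mean(sh_second) > np.mean(cc_second)
    # the baseline can never reach a perfect second implant: its overlap
    # cells were replaced by random numbers
    assert max(cc_second) < 1.0
    assert max(sh_second) == pytest.approx(1.0)


def test_interference_example_not_rediscovered():
    """With the two previously clustered entries shielded, the sub-matrix
    that random masking fabricates is never reported."""
    fx = table1_fixture(seed=0)
    shaded = Bicluster((3, 4), (3,), 0.0)
    res = shielded_discover(
        fx.matrix,
        SearchParams(delta=300.0, n_biclusters=5, seed=0),
        warm_start=[shaded],
    )
    false_key = (set(fx.false_bicluster.rows), set(fx.false_bicluster.cols))
    for b in res:
        assert (set(b.rows), set(b.cols)) != false_key


def test_reported_msr_valid_for_raw_matrix():
    """Shielding preserves real parts, so every recorded MSR must equal the
    MSR recomputed from the original data."""
    A, _ = overlapping_pair_dataset(seed=2, **BENCH)
    res = shielded_discover(A, SearchParams(n_biclusters=6, seed=2, **BENCH_PARAMS))
    for b in res:
        recomputed = msr(A.region(b.rows, b.cols))
        assert b.msr_real == pytest.approx(recomputed, abs=1e-9)
        assert b.msr_real <= 50.0


def test_determinism_and_non_rediscovery():
    A, _ = overlapping_pair_dataset(seed=5, **BENCH)
    params = SearchParams(n_biclusters=10, seed=5, **BENCH_PARAMS)
    r1 = shielded_discover(A, params)
    r2 = shielded_discover(A, params)
    assert [(b.rows, b.cols, b.msr_real) for b in r1] == [
        (b.rows, b.cols, b.msr_real) for b in r2
    ]
    keys = [(b.rows, b.cols) for b in r1]
    assert len(keys) == len(set(keys))


def test_rejects_complex_entry_matrix():
    with pytest.raises(TypeError):
        shielded_discover(ExpressionMatrix(np.array([[1 + 1j, 2], [3, 4]])))


class TestReporting:
    def test_report_records(self):
        s = BiclusterSet(
            [Bicluster(tuple(range(10)), tuple(range(5)), 0.0)], method_tag="shielded"
        )
        df = report(s)
        assert df.loc[0, ["n_rows", "n_cols", "size", "msr"]].tolist() == [10, 5, 50, 0.0]

    def test_aggregates(self):
        s = BiclusterSet(
            [
                Bicluster((0, 1), (0, 1), 100.0),
                Bicluster((2, 3), (2, 3), 200.0),
            ]
        )
        stats = summarize(s)
        assert stats["msr_mean"] == pytest.approx(150.0)
        assert stats["msr_std"] == pytest.approx(50.0)
        assert stats["size_mean"] == pytest.approx(4.0)

    def test_empty_set(self):
        df = report(BiclusterSet())
        assert df.empty
        assert summarize(BiclusterSet())["n"] == 0

    def test_variance_filter(self, rng):
        values = rng.uniform(0, 800, size=(6, 6))
        values[:2, :2] = 7.0  # constant (trivial) block
        A = ExpressionMatrix(values)
        s = BiclusterSet(
            [Bicluster((0, 1), (0, 1), 0.0), Bicluster((2, 3, 4), (2, 3, 4), 1.0)]
        )
        kept = filter_by_variance(s, A, min_variance=1.0)
        assert len(kept) == 1
        assert kept[0].rows == (2, 3, 4)
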