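"""Greedy delta-bicluster search engine shared by the baseline and the
shielded variant.

One code path serves both methods: the deletion phases use the
magnitude-form scores and the addition phase the real-part scores from
:mod:`shieldbic.shielding`.  On a purely real working matrix the squared
residues are nonnegative reals, so the magnitude scores are *bit-identical*
to the classical real scores and the engine reduces exactly to the
Cheng-Church inner search; on a shielded (complex) working matrix the
magnitude scores inflate shielded rows/columns so the deletion phases expel
them, while the real-part addition scores let them rejoin when their raw
data fit the new bicluster.
"""

from __future__ import annotations

import numpy as np

from .shielding import (
    magnitude_col_scores,
    magnitude_row_scores,
    overall_score,
    real_col_scores,
    real_msr,
    real_row_scores,
)


def _region(values: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return values[np.ix_(rows, cols)]


def multiple_deletion(
    values: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    *,
    delta: float,
    alpha: float,
    min_rows: int,
    min_cols: int,
    min_dim: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast collective deletion: repeatedly delete every row, then every
    column, whose score exceeds ``alpha * H``; stops when ``H <= delta`` or
    a full pass deletes nothing.

    On clean (real) data each axis participates only while it has more
    than ``min_dim`` entries: with few entries on the opposite axis the
    scores scatter so widely that repeated tail-truncation at ``alpha * H``
    would cascade down to nothing, so small matrices go straight to
    single-node deletion.  While the region still contains shielded
    (complex) entries the phase is active regardless of size -- expelling
    shielded rows/columns collectively is what it is for, and their
    magnitude scores dwarf ``alpha * H`` while clean rows sit far below
    it, so no cascade is possible."""
    is_complex = np.iscomplexobj(values)
    max_passes = values.shape[0] + values.shape[1]
    for _ in range(max_passes):
        sub = _region(values, rows, cols)
        has_shield = is_complex and bool(np.any(sub.imag != 0))
        H = overall_score(sub)
        if H <= delta:
            break
        deleted = False
        if len(rows) > min_dim or has_shield:
            scores = magnitude_row_scores(sub)
            keep = ~(scores > alpha * H)
            if keep.sum() < min_rows:  # retain the best-scoring survivors
                keep = np.zeros(len(rows), dtype=bool)
                keep[np.argsort(scores)[:min_rows]] = True
            if keep.sum() < len(rows):
                rows = rows[keep]
                deleted = True
                sub = _region(values, rows, cols)
                has_shield = is_complex and bool(np.any(sub.imag != 0))
                H = overall_score(sub)
                if H <= delta:
                    break
        if len(cols) > min_dim or has_shield:
            scores = magnitude_col_scores(sub)
            keep = ~(scores > alpha * H)
            if keep.sum() < min_cols:
                keep = np.zeros(len(cols), dtype=bool)
                keep[np.argsort(scores)[:min_cols]] = True
            if keep.sum() < len(cols):
                cols = cols[keep]
                deleted = True
        if not deleted:
            break
    return rows, cols


def single_deletion(
    values: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    *,
    delta: float,
    min_rows: int,
    min_cols: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Remove one row or column at a time -- whichever has the largest
    score, ties broken row-before-column then lowest index -- until
    ``H <= delta``.  Returns ``(rows, cols, degenerate)`` where
    ``degenerate`` flags that the region hit the minimum dimensions while
    still exceeding ``delta``."""
    max_steps = values.shape[0] * values.shape[1]
    for _ in range(max_steps):
        sub = _region(values, rows, cols)
        if overall_score(sub) <= delta:
            return rows, cols, False
        best_row = best_col = None
        if len(rows) > min_rows:
            rs = magnitude_row_scores(sub)
            best_row = int(np.argmax(rs))
        if len(cols) > min_cols:
            cs = magnitude_col_scores(sub)
            best_col = int(np.argmax(cs))
        if best_row is None and best_col is None:
            return rows, cols, True
        if best_col is None or (best_row is not None and rs[best_row] >= cs[best_col]):
            rows = np.delete(rows, best_row)
        else:
            cols = np.delete(cols, best_col)
    return rows, cols, True  # pragma: no cover - step cap


def addition(
    values: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    *,
    delta: float | None = None,
    parent_rows: np.ndarray | None = None,
    parent_cols: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow the region: repeatedly add every parent column, then every
    parent row, whose real-part score against the current region stays
    within the admission threshold; stops when a full pass adds nothing.
    Scores use real parts only, so shielded data neither attract nor repel
    additions.

    The threshold is the current region's real-part MSR when ``delta`` is
    None (the strict reading of the addition inequality), else
    ``max(MSR, delta)``: a candidate is admitted whenever it is coherent at
    the level the user already accepts for a delta-bicluster.  The two
    coincide in the regime the search was designed for (deletion stops with
    H at about delta); the floor matters when deletion lands on a region
    far more coherent than delta requires, where the strict rule would
    starve the addition phase of rows/columns that plainly belong."""
    n, m = values.shape
    if parent_rows is None:
        parent_rows = np.arange(n)
    if parent_cols is None:
        parent_cols = np.arange(m)
    real = values.real if np.iscomplexobj(values) else values
    floor = -np.inf if delta is None else delta

    max_passes = n + m
    for _ in range(max_passes):
        changed = False
        # column additions
        sub = _region(real, rows, cols)
        H = max(real_msr(sub), floor)
        cand = real[np.ix_(rows, parent_cols)]
        row_means = sub.mean(axis=1)
        resid = cand - row_means[:, None] - cand.mean(axis=0)[None, :] + sub.mean()
        col_scores = (resid * resid).mean(axis=0)
        in_region = np.isin(parent_cols, cols)
        take = (col_scores <= H) & ~in_region
        if take.any():
            cols = np.sort(np.concatenate([cols, parent_cols[take]]))
            changed = True
        # row additions
        sub = _region(real, rows, cols)
        H = max(real_msr(sub), floor)
        cand = real[np.ix_(parent_rows, cols)]
        col_means = sub.mean(axis=0)
        resid = cand - cand.mean(axis=1)[:, None] - col_means[None, :] + sub.mean()
        row_scores = (resid * resid).mean(axis=1)
        in_region = np.isin(parent_rows, rows)
        take = (row_scores <= H) & ~in_region
        if take.any():
            rows = np.sort(np.concatenate([rows, parent_rows[take]]))
            changed = True
        if not changed:
            break
    return rows, cols


def real_trim(
    values: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    *,
    delta: float,
    min_rows: int,
    min_cols: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Enforce the reporting contract ``real-part MSR <= delta`` after the
    addition phase by single-node deletion on the real-part scores.  The
    addition rule keeps H at or below its entry value in the typical case,
    so this rarely removes anything."""
    real = values.real if np.iscomplexobj(values) else values
    max_steps = values.shape[0] * values.shape[1]
    for _ in range(max_steps):
        sub = _region(real, rows, cols)
        if real_msr(sub) <= delta:
            return rows, cols, False
        best_row = best_col = None
        if len(rows) > min_rows:
            rs = real_row_scores(sub)
            best_row = int(np.argmax(rs))
        if len(cols) > min_cols:
            cs = real_col_scores(sub)
            best_col = int(np.argmax(cs))
        if best_row is None and best_col is None:
            return rows, cols, True
        if best_col is None or (best_row is not None and rs[best_row] >= cs[best_col]):
            rows = np.delete(rows, best_row)
        else:
            cols = np.delete(cols, best_col)
    return rows, cols, True  # pragma: no cover - step cap


def find_bicluster(
    values: np.ndarray,
    *,
    delta: float,
    alpha: float,
    min_rows: int,
    min_cols: int,
    min_dim: int,
    use_single_deletion: bool = True,
    addition_rule: str = "delta",
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One full inner search over the whole working matrix: multiple
    deletion, single deletion, then addition.  Returns the final index sets
    and a degeneracy flag (region stuck at minimum dimensions with
    ``H > delta``; such a region is not a valid delta-bicluster)."""
    rows = np.arange(values.shape[0])
    cols = np.arange(values.shape[1])
    rows, cols = multiple_deletion(
        values, rows, cols, delta=delta, alpha=alpha,
        min_rows=min_rows, min_cols=min_cols, min_dim=min_dim,
    )
    degenerate = False
    if use_single_deletion:
        rows, cols, degenerate = single_deletion(
            values, rows, cols, delta=delta, min_rows=min_rows, min_cols=min_cols
        )
    else:
        degenerate = overall_score(_region(values, rows, cols)) > delta
    if not degenerate:
        rows, cols = addition(
            values, rows, cols, delta=delta if addition_rule == "delta" else None
        )
        rows, cols, degenerate = real_trim(
            values, rows, cols, delta=delta, min_rows=min_rows, min_cols=min_cols
        )
    return rows, cols, degenerate
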