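"""Canonical Cheng-Church delta-bicluster search with random-number masking.

Each discovery iteration greedily deletes rows/columns from the full matrix
until the mean squared residue drops to ``delta`` (a fast collective
``alpha``-deletion phase followed by one-at-a-time deletion), then adds back
every row/column that does not raise the score, records the resulting
bicluster, and overwrites its footprint with uniform random numbers so the
next iteration does not rediscover it.

The random masking is the known weak point this package exists to replace:
masked values can by chance line up with real data and fabricate additive
coherence, so later iterations may report sub-matrices that are not genuine
biclusters, and genuinely overlapping biclusters are destroyed.  The
shielded variant in :mod:`shieldbic.enhanced` shares this module's inner
search engine but masks nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _search
from .core import (
    Bicluster,
    BiclusterSet,
    DegenerateRegionError,
    ExpressionMatrix,
    msr,
)

__all__ = [
    "SearchParams",
    "multiple_node_deletion",
    "single_node_deletion",
    "node_addition",
    "random_mask",
    "cc_discover",
]

logger = logging.getLogger(__name__)

#: axis sizes at or below which the collective alpha-deletion phase is
#: skipped (it exists to make large matrices tractable)
MULTIPLE_DELETION_MIN_DIM = 100


@dataclass(frozen=True)
class SearchParams:
    """Parameters of a bicluster search.

    delta
        MSR ceiling (expression units squared); a recorded bicluster always
        has real-part MSR <= delta.  Default 300, the customary threshold
        for the yeast benchmark's 0-800 expression scale.
    alpha
        Fast-deletion multiplier (> 1): during collective deletion every
        row/column scoring above ``alpha * H`` is dropped at once.
    n_biclusters
        Number of biclusters to discover (K).
    min_rows, min_cols
        Smallest admissible bicluster dimensions (>= 2).
    seed
        RNG seed governing masking and missing-value imputation.
    mask_range
        ``(low, high)`` for the baseline's uniform masking draws; ``None``
        uses the observed matrix range.
    multiple_deletion_min_dim
        Axis size above which the collective deletion phase is active.
    use_single_deletion
        Whether the one-at-a-time deletion phase runs (on by default).
    addition_rule
        Admission threshold of the addition phase: ``"delta"`` (default)
        admits a row/column whose real-part score is within
        ``max(current MSR, delta)`` -- anything coherent at the level the
        user already accepts for a delta-bicluster; ``"msr"`` is the strict
        current-MSR rule.  The two coincide when deletion stops with H
        near delta.
    max_attempts
        Cap on discovery iterations including degenerate ones; ``None``
        means ``2 * n_biclusters``.
    """

    delta: float = 300.0
    alpha: float = 1.2
    n_biclusters: int = 50
    min_rows: int = 2
    min_cols: int = 2
    seed: int = 0
    mask_range: tuple[float, float] | None = None
    multiple_deletion_min_dim: int = MULTIPLE_DELETION_MIN_DIM
    use_single_deletion: bool = True
    addition_rule: str = "delta"
    max_attempts: int | None = None

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1")
        if self.n_biclusters < 1:
            raise ValueError("n_biclusters must be >= 1")
        if self.min_rows < 2 or self.min_cols < 2:
            raise ValueError("min_rows and min_cols must be >= 2")

    @property
    def attempts_cap(self) -> int:
        return self.max_attempts if self.max_attempts is not None else 2 * self.n_biclusters

    def with_(self, **kw) -> "SearchParams":
        return replace(self, **kw)


def _index_arrays(rows, cols) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)


def multiple_node_deletion(values: np.ndarray, rows, cols, params: SearchParams):
    """Collective deletion of all rows/columns scoring above
    ``alpha * H``, repeated until ``H <= delta`` or nothing qualifies."""
    rows, cols = _index_arrays(rows, cols)
    return _search.multiple_deletion(
        np.asarray(values), rows, cols,
        delta=params.delta, alpha=params.alpha,
        min_rows=params.min_rows, min_cols=params.min_cols,
        min_dim=params.multiple_deletion_min_dim,
    )


def single_node_deletion(values: np.ndarray, rows, cols, params: SearchParams):
    """One-at-a-time deletion of the worst-scoring row or column until
    ``H <= delta``.  Raises :class:`DegenerateRegionError` when the region
    reaches the minimum dimensions while still above ``delta``."""
    rows, cols = _index_arrays(rows, cols)
    rows, cols, degenerate = _search.single_deletion(
        np.asarray(values), rows, cols,
        delta=params.delta, min_rows=params.min_rows, min_cols=params.min_cols,
    )
    if degenerate:
        raise DegenerateRegionError(
            "region reached minimum dimensions with MSR above delta",
            rows=rows, cols=cols,
        )
    return rows, cols


def node_addition(values: np.ndarray, rows, cols, parent_rows=None, parent_cols=None):
    """Grow a region by every parent column, then row, whose score does not
    exceed the region's MSR; repeats to a fixed point."""
    rows, cols = _index_arrays(rows, cols)
    return _search.addition(
        np.asarray(values), rows, cols,
        parent_rows=None if parent_rows is None else np.asarray(parent_rows, dtype=int),
        parent_cols=None if parent_cols is None else np.asarray(parent_cols, dtype=int),
    )


def random_mask(
    values: np.ndarray,
    bic: Bicluster,
    rng: np.random.Generator,
    mask_range: tuple[float, float],
) -> None:
    """Overwrite ``bic``'s footprint in place with i.i.d.
    Uniform(mask_range) draws -- the baseline's shielding step."""
    low, high = mask_range
    ix = np.ix_(np.asarray(bic.rows, dtype=int), np.asarray(bic.cols, dtype=int))
    values[ix] = rng.uniform(low, high, size=(bic.n_rows, bic.n_cols))


def _prepare(A: ExpressionMatrix, params: SearchParams) -> np.ndarray:
    """Working copy with missing entries imputed (uniform over the observed
    range, from a dedicated stream of the run's seed)."""
    if A.missing_sentinel is not None and A.missing_mask().any():
        A = A.imputed(np.random.default_rng([params.seed, 7]))
    return np.array(A.values, dtype=float, copy=True)


def cc_discover(A: ExpressionMatrix, params: SearchParams = SearchParams()) -> BiclusterSet:
    """Run the full baseline: K iterations of deletion, addition, recording
    and random masking.  Degenerate iterations (region stuck above delta at
    the minimum dimensions) are masked but not recorded, so every recorded
    bicluster satisfies ``msr <= delta`` on the values at discovery time."""
    if np.iscomplexobj(A.values) and np.any(np.asarray(A.values).imag != 0):
        raise TypeError("cc_discover expects a real-valued matrix")
    working = _prepare(A, params)
    rng = np.random.default_rng(params.seed)
    mask_range = params.mask_range
    if mask_range is None:
        mask_range = (float(working.min()), float(working.max()))
    result = BiclusterSet(params=params, method_tag="cc_baseline")
    attempts = 0
    while len(result) < params.n_biclusters and attempts < params.attempts_cap:
        attempts += 1
        rows, cols, degenerate = _search.find_bicluster(
            working,
            delta=params.delta, alpha=params.alpha,
            min_rows=params.min_rows, min_cols=params.min_cols,
            min_dim=params.multiple_deletion_min_dim,
            use_single_deletion=params.use_single_deletion,
            addition_rule=params.addition_rule,
        )
        region = working[np.ix_(rows, cols)]
        if degenerate:
            logger.warning(
                "iteration %d degenerate (%dx%d region above delta); skipped",
                attempts, len(rows), len(cols),
            )
            result.skipped.append((tuple(rows), tuple(cols)))
        else:
            bic = Bicluster(tuple(rows), tuple(cols), msr(region))
            result.biclusters.append(bic)
            logger.info(
                "iteration %d: %dx%d bicluster, MSR %.2f",
                attempts, bic.n_rows, bic.n_cols, bic.msr_real,
            )
        # mask the footprint either way so the search moves on
        footprint = Bicluster(tuple(rows), tuple(cols), 0.0)
        random_mask(working, footprint, rng, mask_range)
    if len(result) < params.n_biclusters:
        logger.warning(
            "matrix exhausted after %d attempts: %d of %d biclusters found",
            attempts, len(result), params.n_biclusters,
        )
    return result
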