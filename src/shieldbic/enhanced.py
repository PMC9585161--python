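"""Shielded bicluster discovery: the enhanced search that replaces random
masking with the complex shielding transform.

The loop mirrors the baseline -- deletion phases, addition phase, record --
but after each recording the discovered footprint is shielded in place
(:func:`shieldbic.shielding.shield_values`) instead of being overwritten
with random numbers.  Because shielding only adds an imaginary component:

* the magnitude-form deletion scores of shielded rows/columns are inflated,
  so earlier biclusters are expelled early in later searches (no
  rediscovery, no random-number interference), and
* the real parts -- the actual data -- survive untouched, so the real-part
  addition scores can pull previously clustered rows/columns into a new
  bicluster: overlapping biclusters remain discoverable, and every reported
  MSR is a statement about the original data.

The first iteration runs on the raw (purely real) matrix, where every score
reduces exactly to its classical form, so a single-bicluster run is
identical to the baseline without masking.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from . import _search
from .core import Bicluster, BiclusterSet, ExpressionMatrix
from .cc import SearchParams
from .shielding import ShieldParams, real_msr, shield_values

__all__ = ["shielded_discover", "report", "summarize", "filter_by_variance"]

logger = logging.getLogger(__name__)


def shielded_discover(
    A: ExpressionMatrix,
    params: SearchParams = SearchParams(),
    shield: ShieldParams = ShieldParams(),
    warm_start: Iterable[Bicluster] = (),
) -> BiclusterSet:
    """Discover up to ``params.n_biclusters`` possibly overlapping
    biclusters.

    ``A`` must be real-valued on entry.  ``warm_start`` biclusters are
    shielded into the working matrix before the loop begins (useful to
    resume a search or to study the effect of shielding specific
    footprints); they are not re-reported.

    Degenerate iterations (region stuck above delta at the minimum
    dimensions) are skipped with a warning; their footprint is still
    shielded so the search state advances.  Recorded biclusters always have
    ``msr_real <= delta``, computed on real parts and therefore valid for
    the original raw matrix.
    """
    if np.iscomplexobj(A.values) and np.any(np.asarray(A.values).imag != 0):
        raise TypeError("shielded_discover expects a real-valued matrix on entry")
    from .cc import _prepare  # shared imputation path

    working = _prepare(A, params).astype(complex)
    for bic in warm_start:
        shield_values(working, bic.rows, bic.cols, shield.phi, shield.zero_tol)
    result = BiclusterSet(params=params, method_tag="shielded")
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
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
        key = (tuple(rows), tuple(cols))
        duplicate = key in seen
        if degenerate:
            logger.warning(
                "iteration %d degenerate (%dx%d region above delta); skipped",
                attempts, len(rows), len(cols),
            )
            result.skipped.append(key)
        elif duplicate:
            logger.warning(
                "iteration %d re-derived an already reported bicluster; skipped",
                attempts,
            )
        else:
            region = working[np.ix_(rows, cols)]
            bic = Bicluster(key[0], key[1], real_msr(region))
            result.biclusters.append(bic)
            seen.add(key)
            logger.info(
                "iteration %d: %dx%d bicluster, MSR %.2f",
                attempts, bic.n_rows, bic.n_cols, bic.msr_real,
            )
        footprint = working[np.ix_(rows, cols)]
        if (degenerate or duplicate) and not np.any(footprint.imag == 0):
            # the endpoint is already fully shielded, so re-shielding is a
            # no-op (idempotence) and the state cannot advance: the matrix
            # holds no further discoverable structure
            logger.warning("search exhausted: endpoint already fully shielded")
            break
        shield_values(working, rows, cols, shield.phi, shield.zero_tol)
    if len(result) < params.n_biclusters:
        logger.warning(
            "stopped after %d attempts: %d of %d biclusters found",
            attempts, len(result), params.n_biclusters,
        )
    return result


def report(result: BiclusterSet) -> pd.DataFrame:
    """One record per bicluster: 1-based index, dimensions, size and
    real-part MSR."""
    records = [
        {
            "bicluster": k + 1,
            "n_rows": b.n_rows,
            "n_cols": b.n_cols,
            "size": b.size,
            "msr": b.msr_real,
        }
        for k, b in enumerate(result)
    ]
    return pd.DataFrame(records, columns=["bicluster", "n_rows", "n_cols", "size", "msr"])


def summarize(result: BiclusterSet) -> dict[str, float]:
    """Aggregate mean and (population) standard deviation of MSR and size
    across the set; zeros/NaNs for an empty set."""
    df = report(result)
    if df.empty:
        return {"n": 0, "msr_mean": float("nan"), "msr_std": float("nan"),
                "size_mean": float("nan"), "size_std": float("nan")}
    return {
        "n": int(len(df)),
        "msr_mean": float(df["msr"].mean()),
        "msr_std": float(df["msr"].std(ddof=0)),
        "size_mean": float(df["size"].mean()),
        "size_std": float(df["size"].std(ddof=0)),
    }


def filter_by_variance(
    result: BiclusterSet, A: ExpressionMatrix, min_variance: float
) -> BiclusterSet:
    """Optional post-filter dropping trivial (near-constant) biclusters
    whose sum of squared deviations from their overall mean falls below
    ``min_variance``.  Off by default; the search itself never uses it."""
    from .core import variance

    kept = [
        b for b in result
        if variance(np.asarray(A.values).real[np.ix_(b.rows, b.cols)]) >= min_variance
    ]
    out = BiclusterSet(kept, params=result.params, method_tag=result.method_tag)
    out.skipped = list(result.skipped)
    return out
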