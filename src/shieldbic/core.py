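"""Expression-matrix data model and mean-squared-residue (MSR) scores.

The MSR of a sub-matrix ``B_k = (S_k, F_k)`` of an expression matrix ``A``
is the average squared residue

    H_k = (1 / |S_k||F_k|) * sum_ij r_ij^2,
    r_ij = a_ij - mu_i(r) - mu_j(c) + mu,

where ``mu_i(r)``, ``mu_j(c)`` and ``mu`` are the row, column and overall
means of the sub-matrix.  ``H_k`` is zero exactly when the sub-matrix
follows an additive model ``a_ij = b + p_i + q_j``, which is the coherence
pattern a bicluster search targets.  A sub-matrix with ``H_k <= delta`` is
called a delta-bicluster.

Functions in this module are defined for real-valued regions only; the
complex (magnitude-form) generalisations used to score shielded data live
in :mod:`shieldbic.shielding`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateRegionError",
    "ExpressionMatrix",
    "Bicluster",
    "BiclusterSet",
    "means",
    "residues",
    "msr",
    "variance",
    "axis_msr",
]


class DegenerateRegionError(ValueError):
    """A region is empty or has shrunk below the admissible dimensions."""

    def __init__(self, message: str, rows=None, cols=None):
        super().__init__(message)
        self.rows = rows
        self.cols = cols


def _as_region(sub) -> np.ndarray:
    a = np.asarray(sub)
    if a.ndim != 2:
        raise ValueError(f"region must be 2-dimensional, got shape {a.shape}")
    if a.size == 0:
        raise DegenerateRegionError("empty region: degenerate bicluster")
    return a


def _require_real(a: np.ndarray, op: str) -> np.ndarray:
    if np.iscomplexobj(a):
        if np.any(a.imag != 0):
            raise TypeError(
                f"{op} is defined for real-valued regions only; for shielded "
                "(complex) data use the magnitude-form scores in "
                "shieldbic.shielding (overall_score / shielded_axis_score)."
            )
        a = a.real
    return a


@dataclass
class ExpressionMatrix:
    """A rectangular sample x feature expression matrix.

    Values may be real (raw data) or complex (a working matrix in which
    discovered biclusters have been shielded; the imaginary part is the
    shield, the real part is always the original data).

    Parameters
    ----------
    values
        2-d numeric array, ``n`` samples by ``m`` features.
    row_labels, col_labels
        Optional unique identifiers, lengths ``n`` and ``m``.
    missing_sentinel
        Optional value flagging missing entries (the yeast benchmark
        convention uses -1); imputation happens at search time.
    """

    values: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None
    missing_sentinel: float | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one row and one column")
        for labels, size, what in (
            (self.row_labels, n, "row"),
            (self.col_labels, m, "column"),
        ):
            if labels is not None:
                labels = list(labels)
                if len(labels) != size:
                    raise ValueError(
                        f"{what} labels have length {len(labels)}, expected {size}"
                    )
                if len(set(labels)) != len(labels):
                    raise ValueError(f"{what} labels are not unique")
        if self.row_labels is not None:
            self.row_labels = list(self.row_labels)
        if self.col_labels is not None:
            self.col_labels = list(self.col_labels)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def region(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        """Extract the sub-matrix indexed by ``rows`` x ``cols`` (a copy,
        entry values preserved bit-exactly)."""
        return self.values[np.ix_(np.asarray(rows, dtype=int), np.asarray(cols, dtype=int))]

    def bicluster_region(self, bic: "Bicluster") -> np.ndarray:
        return self.region(bic.rows, bic.cols)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.row_labels) if self.row_labels is not None else None,
            list(self.col_labels) if self.col_labels is not None else None,
            self.missing_sentinel,
        )

    def missing_mask(self) -> np.ndarray:
        if self.missing_sentinel is None:
            return np.zeros(self.shape, dtype=bool)
        return self.values == self.missing_sentinel

    def imputed(self, rng: np.random.Generator) -> "ExpressionMatrix":
        """Replace missing-sentinel entries with Uniform(min, max) draws over
        the observed (non-missing) range.  A no-op when nothing is missing."""
        mask = self.missing_mask()
        out = self.copy()
        if mask.any():
            observed = self.values[~mask]
            if observed.size == 0:
                raise ValueError("matrix contains only missing values")
            lo, hi = float(observed.real.min()), float(observed.real.max())
            out.values[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        return out


@dataclass(frozen=True)
class Bicluster:
    """A bicluster: index sets ``(S_k, F_k)`` into a parent matrix plus the
    MSR of the real parts of the data it selects."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    msr_real: float

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(int(i) for i in self.rows))
        object.__setattr__(self, "cols", tuple(int(j) for j in self.cols))
        if not self.rows or not self.cols:
            raise DegenerateRegionError("bicluster index sets must be non-empty")
        if self.msr_real < 0:
            raise ValueError("msr_real must be nonnegative")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    @property
    def size(self) -> int:
        return self.n_rows * self.n_cols

    def cells(self) -> set[tuple[int, int]]:
        """The element (cell) set of the footprint."""
        return {(i, j) for i in self.rows for j in self.cols}


@dataclass
class BiclusterSet:
    """Ordered collection of discovered biclusters with discovery metadata."""

    biclusters: list[Bicluster] = field(default_factory=list)
    params: object | None = None
    method_tag: str = ""
    #: regions where an iteration shrank below the minimum dimensions and was
    #: skipped (not recorded as biclusters)
    skipped: list[tuple[tuple[int, ...], tuple[int, ...]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, k) -> Bicluster:
        return self.biclusters[k]


# ---------------------------------------------------------------------------
# residue / MSR scores


def means(sub) -> tuple[np.ndarray, np.ndarray, float | complex]:
    """Row means, column means and overall mean of a region.

    Complex regions use complex arithmetic (needed by the shielding scores).
    """
    a = _as_region(sub)
    row_means = a.mean(axis=1)
    col_means = a.mean(axis=0)
    overall = a.mean()
    return row_means, col_means, overall


def residues(sub) -> np.ndarray:
    """Entrywise residues ``r_ij = a_ij - mu_i(r) - mu_j(c) + mu``.

    Linear in the input; identically zero on an additive region.
    """
    a = _as_region(sub)
    row_means, col_means, overall = means(a)
    return a - row_means[:, None] - col_means[None, :] + overall


def msr(sub) -> float:
    """Mean squared residue ``H_k`` of a real-valued region."""
    a = _require_real(_as_region(sub), "msr")
    r = residues(a)
    return float((r * r).mean())


def variance(sub) -> float:
    """Sum of squared deviations from the overall mean (an unnormalised
    sum; exposed for completeness, unused by the search)."""
    a = _require_real(_as_region(sub), "variance")
    d = a - a.mean()
    return float((d * d).sum())


def axis_msr(sub, axis: str, index: int) -> float:
    """MSR of a single row (``axis='row'``) or column (``axis='col'``) of a
    real region:  ``H_i(r) = (1/|F_k|) sum_j r_ij^2`` and the column
    analogue.  The equally weighted mean of all row (or column) scores
    equals :func:`msr`."""
    a = _require_real(_as_region(sub), "axis_msr")
    r = residues(a)
    if axis == "row":
        return float((r[index, :] ** 2).mean())
    if axis == "col":
        return float((r[:, index] ** 2).mean())
    raise ValueError("axis must be 'row' or 'col'")
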