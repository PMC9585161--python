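"""Complex-valued shielding of discovered biclusters and the scores that
operate on shielded (complex) data.

Instead of overwriting a discovered bicluster with random numbers -- which
can by chance fabricate coherence and lead the next search iteration to a
false bicluster -- the footprint of each discovered bicluster is *shielded*
in place: every entry ``a`` of the footprint becomes

    a <- (1 + phi * rho[Imag(a) == 0] * 1j) * a + phi * rho(a) * 1j

where ``phi >= 1`` is the shielding factor, ``1j`` the imaginary unit and
``rho`` the discrete unit impulse (1 at zero, 0 elsewhere).  The first
impulse detector leaves already-shielded entries (nonzero imaginary part)
untouched, so shielding is idempotent; the second rescues zero-valued
entries, which would otherwise gain no imaginary part, by mapping them to
``phi * 1j``.  The real part of every entry is preserved exactly, so the
original data remain available and later biclusters may overlap earlier
ones.

During the deletion phases of a shielded search, row/column scores take
the magnitude form

    H'_i(r) = (1/|F_k|) |sum_j r_ij^2|,

which reduces to the ordinary (real) row MSR on unshielded data and is
inflated by a factor ``1 + phi^2`` on fully shielded zero-free data, making
shielded rows and columns easy to delete.  The addition phase instead
scores only the real parts of the residues, which shielding never alters,
so rows and columns of earlier biclusters can rejoin a new one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Bicluster, DegenerateRegionError, ExpressionMatrix, _as_region, residues

__all__ = [
    "ShieldParams",
    "unit_impulse",
    "shield_region",
    "shield_values",
    "shielded_axis_score",
    "overall_score",
    "deletion_test",
    "addition_axis_score",
    "magnitude_row_scores",
    "magnitude_col_scores",
    "real_row_scores",
    "real_col_scores",
    "real_msr",
]

DEFAULT_PHI = 10.0
DEFAULT_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ShieldParams:
    """Shielding parameters.

    phi
        Shielding factor (dimensionless, ``phi >= 1``): how strongly the
        imaginary part inflates the magnitude-form deletion scores (a fully
        shielded zero-free region scores ``(1 + phi^2)`` times its real
        score).  Only needs to push shielded rows/columns past the deletion
        threshold; default 10 (inflation factor 101).
    zero_tol
        Nonnegative tolerance under which a value counts as zero in the
        impulse detectors.
    """

    phi: float = DEFAULT_PHI
    zero_tol: float = DEFAULT_ZERO_TOL

    def __post_init__(self):
        if not self.phi >= 1:
            raise ValueError(f"shielding factor phi must be >= 1, got {self.phi}")
        if not self.zero_tol >= 0:
            raise ValueError("zero_tol must be nonnegative")


def unit_impulse(x, zero_tol: float = DEFAULT_ZERO_TOL) -> int:
    """Discrete unit impulse: 1 when ``|x| <= zero_tol``, else 0."""
    return 1 if abs(x) <= zero_tol else 0


def shield_values(
    values: np.ndarray,
    rows,
    cols,
    phi: float = DEFAULT_PHI,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> None:
    """Shield the ``rows x cols`` footprint of a complex working matrix in
    place.  Entries with a nonzero imaginary part are left untouched."""
    if not np.iscomplexobj(values):
        raise TypeError("shield_values requires a complex working matrix")
    ix = np.ix_(np.asarray(rows, dtype=int), np.asarray(cols, dtype=int))
    sub = values[ix]
    unshielded = np.abs(sub.imag) <= zero_tol
    is_zero = np.abs(sub) <= zero_tol
    shielded = sub * (1 + phi * 1j) + (is_zero * phi) * 1j
    values[ix] = np.where(unshielded, shielded, sub)


def shield_region(
    A: ExpressionMatrix, bic: Bicluster, params: ShieldParams = ShieldParams()
) -> ExpressionMatrix:
    """Return a copy of ``A`` with ``bic``'s footprint shielded.

    Idempotent: re-shielding an already shielded footprint is a no-op, and
    the real part of every entry is preserved exactly.
    """
    if not bic.rows or not bic.cols:
        raise DegenerateRegionError("cannot shield an empty bicluster")
    out = A.copy()
    out.values = out.values.astype(complex)
    shield_values(out.values, bic.rows, bic.cols, params.phi, params.zero_tol)
    return out


# ---------------------------------------------------------------------------
# magnitude-form scores (deletion phases)


def magnitude_row_scores(sub) -> np.ndarray:
    """Vector of magnitude-form row scores ``(1/|F_k|) |sum_j r_ij^2|``."""
    r = residues(_as_region(sub))
    return np.abs((r * r).sum(axis=1)) / r.shape[1]


def magnitude_col_scores(sub) -> np.ndarray:
    """Vector of magnitude-form column scores ``(1/|S_k|) |sum_i r_ij^2|``."""
    r = residues(_as_region(sub))
    return np.abs((r * r).sum(axis=0)) / r.shape[0]


def shielded_axis_score(sub, axis: str, index: int) -> float:
    """Magnitude-form MSR of a single row or column of a (possibly complex)
    region.  Equals :func:`shieldbic.core.axis_msr` exactly on real data."""
    if axis == "row":
        return float(magnitude_row_scores(sub)[index])
    if axis == "col":
        return float(magnitude_col_scores(sub)[index])
    raise ValueError("axis must be 'row' or 'col'")


def overall_score(sub) -> float:
    """Magnitude-form MSR of a whole region, ``|sum_ij r_ij^2| / (|S||F|)``;
    reduces to the ordinary MSR on real data."""
    r = residues(_as_region(sub))
    return float(np.abs((r * r).sum()) / r.size)


def deletion_test(score: float, alpha: float, H_k: float) -> bool:
    """Fast-deletion criterion: delete when ``score > alpha * H_k``
    (strict)."""
    return bool(score > alpha * H_k)


# ---------------------------------------------------------------------------
# real-part scores (addition phase)


def _real_parts(sub) -> np.ndarray:
    a = _as_region(sub)
    return a.real if np.iscomplexobj(a) else a


def real_row_scores(sub) -> np.ndarray:
    """Row MSR of the real parts: ``(1/|F_k|) sum_j real(r_ij)^2``.  By
    linearity of the residue this is the score of the raw (unshielded)
    data, whatever shielding the region has received."""
    r = residues(_real_parts(sub))
    return (r * r).mean(axis=1)


def real_col_scores(sub) -> np.ndarray:
    r = residues(_real_parts(sub))
    return (r * r).mean(axis=0)


def real_msr(sub) -> float:
    """MSR of the real parts of a region."""
    r = residues(_real_parts(sub))
    return float((r * r).mean())


def addition_axis_score(sub, axis: str, index: int) -> float:
    """Real-part row/column score used by the addition phase."""
    if axis == "row":
        return float(real_row_scores(sub)[index])
    if axis == "col":
        return float(real_col_scores(sub)[index])
    raise ValueError("axis must be 'row' or 'col'")
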