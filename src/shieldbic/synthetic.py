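"""Synthetic expression matrices with implanted additive biclusters.

The generator emulates the standard implanted-bicluster benchmark: an
i.i.d. noise background (default Uniform(0, 800), the dynamic range of the
classic yeast microarray benchmark) into which K additive-model biclusters

    a_ij = b + p_i + q_j + N(0, sigma^2)

are written, optionally overlapping, with the ground-truth footprints
recorded.  The additive (shift) model is the pattern the mean-squared
residue detects exactly: a noiseless implant has MSR 0 and is a
delta-bicluster for every delta >= 0.

Also packaged here is a small worked example of random-number
interference: a matrix in which two entries (0 and 90) were clustered and
masked in a previous iteration, such that masking them with values near
(6, 9) makes a 3x3 sub-matrix that is *not* a real bicluster perfectly
additive -- the failure mode the shielded search removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Bicluster, ExpressionMatrix, msr

__all__ = [
    "ImplantSpec",
    "GroundTruth",
    "make_background",
    "implant",
    "make_dataset",
    "overlapping_pair_dataset",
    "table1_fixture",
    "Table1Fixture",
]

#: background laws understood by :func:`make_background`
_LAWS = ("uniform", "normal", "constant")

DEFAULT_BACKGROUND = ("uniform", (0.0, 800.0))


@dataclass
class ImplantSpec:
    """An additive bicluster to implant: footprint, base level ``b``, row
    effects ``p_i``, column effects ``q_j`` and within-implant noise SD."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    base: float
    row_effects: tuple[float, ...]
    col_effects: tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self):
        self.rows = tuple(int(i) for i in self.rows)
        self.cols = tuple(int(j) for j in self.cols)
        self.row_effects = tuple(float(p) for p in self.row_effects)
        self.col_effects = tuple(float(q) for q in self.col_effects)
        if len(self.row_effects) != len(self.rows):
            raise ValueError("row_effects must match the number of implant rows")
        if len(self.col_effects) != len(self.cols):
            raise ValueError("col_effects must match the number of implant columns")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.cols)

    def ideal_values(self) -> np.ndarray:
        """The noiseless additive block ``b + p_i + q_j`` (MSR exactly 0)."""
        p = np.asarray(self.row_effects)
        q = np.asarray(self.col_effects)
        return self.base + p[:, None] + q[None, :]

    def as_bicluster(self) -> Bicluster:
        return Bicluster(self.rows, self.cols, 0.0)


@dataclass
class GroundTruth:
    """What was implanted where, sufficient to regenerate the dataset."""

    implants: list[ImplantSpec]
    background_law: str = DEFAULT_BACKGROUND[0]
    background_params: tuple[float, ...] = DEFAULT_BACKGROUND[1]
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "background_law": self.background_law,
            "background_params": list(self.background_params),
            "seed": self.seed,
            "implants": [
                {
                    "rows": list(s.rows),
                    "cols": list(s.cols),
                    "base": s.base,
                    "row_effects": list(s.row_effects),
                    "col_effects": list(s.col_effects),
                    "noise_sd": s.noise_sd,
                }
                for s in self.implants
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            implants=[ImplantSpec(**s) for s in d["implants"]],
            background_law=d["background_law"],
            background_params=tuple(d["background_params"]),
            seed=d["seed"],
        )


def make_background(
    n: int,
    m: int,
    law: str = DEFAULT_BACKGROUND[0],
    params: Sequence[float] = DEFAULT_BACKGROUND[1],
    seed: int = 0,
) -> ExpressionMatrix:
    """An n x m matrix of i.i.d. background noise; deterministic in seed."""
    if n < 2 or m < 2:
        raise ValueError("background must be at least 2x2")
    rng = np.random.default_rng(seed)
    if law == "uniform":
        low, high = params
        if not high > low:
            raise ValueError("uniform law needs high > low")
        values = rng.uniform(low, high, size=(n, m))
    elif law == "normal":
        mean, sd = params
        if sd < 0:
            raise ValueError("normal law needs sd >= 0")
        values = rng.normal(mean, sd, size=(n, m))
    elif law == "constant":
        (c,) = params
        values = np.full((n, m), float(c))
    else:
        raise ValueError(f"unknown background law {law!r}; choose from {_LAWS}")
    return ExpressionMatrix(values)


def implant(A: ExpressionMatrix, spec: ImplantSpec, seed: int = 0) -> ExpressionMatrix:
    """Write an additive bicluster (plus Gaussian noise) onto ``A``'s
    footprint; returns a new matrix.  Overlapping implants are
    last-writer-wins on the overlap."""
    n, m = A.shape
    if max(spec.rows) >= n or max(spec.cols) >= m or min(spec.rows) < 0 or min(spec.cols) < 0:
        raise ValueError("implant footprint out of matrix bounds")
    out = A.copy()
    block = spec.ideal_values()
    if spec.noise_sd > 0:
        block = block + np.random.default_rng(seed).normal(0.0, spec.noise_sd, size=block.shape)
    out.values[np.ix_(spec.rows, spec.cols)] = block
    return out


def make_dataset(
    n: int,
    m: int,
    implants: Sequence[ImplantSpec],
    law: str = DEFAULT_BACKGROUND[0],
    params: Sequence[float] = DEFAULT_BACKGROUND[1],
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Background plus implants (written in order), with ground truth."""
    A = make_background(n, m, law, params, seed)
    for k, spec in enumerate(implants):
        A = implant(A, spec, seed=np.random.default_rng([seed, k]).integers(2**31))
    truth = GroundTruth(list(implants), law, tuple(params), seed)
    return A, truth


def _random_implant(
    rows: Sequence[int],
    cols: Sequence[int],
    rng: np.random.Generator,
    noise_sd: float,
) -> ImplantSpec:
    """Additive effects spanning a realistic share of the 0-800 dynamic
    range: base in (300, 500), row/column effects in (-200, 200)."""
    return ImplantSpec(
        rows=tuple(rows),
        cols=tuple(cols),
        base=float(rng.uniform(300.0, 500.0)),
        row_effects=tuple(rng.uniform(-200.0, 200.0, size=len(rows))),
        col_effects=tuple(rng.uniform(-200.0, 200.0, size=len(cols))),
        noise_sd=noise_sd,
    )


def overlapping_pair_dataset(
    seed: int = 0,
    n: int = 200,
    m: int = 50,
    noise_sd: float = 5.0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """The overlapping-implant benchmark: a 15x8 and a 12x6 additive
    bicluster sharing a 4x3 overlap (rows 11-14 x columns 5-7) in an
    n x m Uniform(0, 800) background; effects are redrawn per seed.

    The two additive models are made consistent on the overlap -- the
    second implant inherits the first's base and its effects on the shared
    rows and columns -- so each footprint is additive (a genuine
    delta-bicluster) despite the shared cells."""
    rng = np.random.default_rng([seed, 1])
    spec1 = _random_implant(range(0, 15), range(0, 8), rng, noise_sd)
    rows2, cols2 = tuple(range(11, 23)), tuple(range(5, 11))
    row_effects2 = tuple(
        spec1.row_effects[spec1.rows.index(i)] if i in spec1.rows
        else float(rng.uniform(-200.0, 200.0))
        for i in rows2
    )
    col_effects2 = tuple(
        spec1.col_effects[spec1.cols.index(j)] if j in spec1.cols
        else float(rng.uniform(-200.0, 200.0))
        for j in cols2
    )
    spec2 = ImplantSpec(rows2, cols2, spec1.base, row_effects2, col_effects2, noise_sd)
    return make_dataset(n, m, [spec1, spec2], seed=seed)


@dataclass
class Table1Fixture:
    """The random-number-interference worked example."""

    matrix: ExpressionMatrix
    #: 0-based (row, col) -> true value of the two previously clustered
    #: (masked) entries
    shaded_entries: dict[tuple[int, int], float]
    #: the masking draws that fabricate coherence
    replacements: tuple[float, float]
    #: the sub-matrix (rows {2,4,5} x cols {1,2,4}, 1-based) that masking
    #: makes look like a perfect bicluster although it is not one
    false_bicluster: Bicluster
    #: the known entries of the example, rows {2,4,5} x cols {1..4}
    known_rows: tuple[int, ...] = (1, 3, 4)
    known_cols: tuple[int, ...] = (0, 1, 2, 3)

    def masked_matrix(self) -> ExpressionMatrix:
        """The matrix after the baseline's masking step replaced the shaded
        entries with the fixture's replacement values."""
        out = self.matrix.copy()
        for (idx, value) in zip(sorted(self.shaded_entries), self.replacements):
            out.values[idx] = value
        return out


_TABLE1_KNOWN = np.array(
    [
        [1.0, 2.0, 0.0, 3.0],
        [4.0, 5.0, 10.0, 0.0],
        [7.0, 8.0, 15.0, 90.0],
    ]
)


def table1_fixture(seed: int = 0, n: int = 7, m: int = 5) -> Table1Fixture:
    """Build the interference example inside a seeded background matrix.

    Rows 2, 4, 5 x columns 1-4 (1-based) hold the known values; entries
    (4,4)=0 and (5,4)=90 are the shaded cells masked in a previous
    iteration with draws near (6, 9).  With those replacements the
    sub-matrix rows {2,4,5} x columns {1,2,4} becomes exactly additive
    (MSR 0) even though its true values have MSR ~ 349.8.
    """
    if n < 5 or m < 4:
        raise ValueError("fixture needs at least 5 rows and 4 columns")
    A = make_background(n, m, seed=seed)
    known_rows = (1, 3, 4)
    A.values[np.ix_(known_rows, (0, 1, 2, 3))] = _TABLE1_KNOWN
    false_rows, false_cols = (1, 3, 4), (0, 1, 3)
    false_true_msr = msr(A.values[np.ix_(false_rows, false_cols)])
    return Table1Fixture(
        matrix=A,
        shaded_entries={(3, 3): 0.0, (4, 3): 90.0},
        replacements=(6.0, 9.0),
        false_bicluster=Bicluster(false_rows, false_cols, false_true_msr),
    )
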