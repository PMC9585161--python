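"""File I/O for expression matrices and bicluster results, recovery
metrics against ground truth, and the method-comparison harness.

The matrix dialect is plain whitespace- or tab-delimited numeric text with
optional header row / row-label column (auto-detected), the format of the
classic yeast benchmark matrix (integers, -1 flagging missing values).
Human-readable output uses 1-based indices; everything in-memory and in the
machine-readable dumps is 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cc import SearchParams, cc_discover
from .core import Bicluster, BiclusterSet, ExpressionMatrix
from .enhanced import shielded_discover, summarize
from .shielding import ShieldParams
from .synthetic import GroundTruth, ImplantSpec, overlapping_pair_dataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_biclusters",
    "read_biclusters",
    "match_score",
    "RunConfig",
    "compare_methods",
]

logger = logging.getLogger(__name__)


class MatrixParseError(ValueError):
    pass


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix(
    path,
    header_row: bool | str = "auto",
    label_col: bool | str = "auto",
    missing_sentinel: float | None = -1.0,
) -> ExpressionMatrix:
    """Parse a delimited numeric matrix.

    ``header_row`` / ``label_col`` may be True, False or "auto"
    (non-numeric first row / first column is treated as labels).  Ragged or
    non-numeric content raises :class:`MatrixParseError` with the line
    number.
    """
    lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if tokens:
                lines.append((lineno, tokens))
    if not lines:
        raise MatrixParseError(f"{path}: no data")

    col_labels = None
    if header_row == "auto":
        first = lines[0][1]
        header_row = not all(_is_number(t) for t in first[1:])
    if header_row:
        col_labels = lines[0][1]
        lines = lines[1:]
        if not lines:
            raise MatrixParseError(f"{path}: header but no data rows")
    if label_col == "auto":
        label_col = not all(_is_number(tokens[0]) for _, tokens in lines)

    row_labels = [] if label_col else None
    rows = []
    width = None
    for lineno, tokens in lines:
        if label_col:
            row_labels.append(tokens[0])
            tokens = tokens[1:]
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise MatrixParseError(
                f"{path}:{lineno}: ragged row ({len(tokens)} values, expected {width})"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise MatrixParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    values = np.asarray(rows)
    if col_labels is not None and len(col_labels) == values.shape[1] + 1:
        # header line includes a label for the row-label column
        col_labels = col_labels[1:]
    if col_labels is not None and len(col_labels) != values.shape[1]:
        raise MatrixParseError(
            f"{path}: header has {len(col_labels)} labels for {values.shape[1]} columns"
        )
    return ExpressionMatrix(values, row_labels, col_labels, missing_sentinel)


def write_matrix(A: ExpressionMatrix, path) -> None:
    """Write the real parts in the same delimited dialect."""
    values = np.asarray(A.values).real
    with open(path, "w") as fh:
        if A.col_labels is not None:
            prefix = [""] if A.row_labels is not None else []
            fh.write("\t".join(prefix + list(A.col_labels)) + "\n")
        for i in range(A.n_rows):
            cells = [repr(float(v)) for v in values[i]]
            if A.row_labels is not None:
                cells = [A.row_labels[i]] + cells
            fh.write("\t".join(cells) + "\n")


def _row_name(A: ExpressionMatrix | None, i: int) -> str:
    if A is not None and A.row_labels is not None:
        return A.row_labels[i]
    return str(i + 1)


def _col_name(A: ExpressionMatrix | None, j: int) -> str:
    if A is not None and A.col_labels is not None:
        return A.col_labels[j]
    return str(j + 1)


def write_biclusters(
    result: BiclusterSet,
    out_dir,
    stem: str = "biclusters",
    matrix: ExpressionMatrix | None = None,
) -> tuple[Path, Path]:
    """Write a human-readable TSV summary (1-based labels) and a
    machine-readable JSON dump (0-based indices, params, seed) sufficient
    for exact reproduction.  Returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{stem}.tsv"
    json_path = out_dir / f"{stem}.json"

    with open(tsv_path, "w") as fh:
        fh.write("bicluster\tn_rows\tn_cols\tsize\tmsr\trows\tcols\n")
        for k, b in enumerate(result, start=1):
            fh.write(
                "\t".join(
                    [
                        str(k),
                        str(b.n_rows),
                        str(b.n_cols),
                        str(b.size),
                        f"{b.msr_real:.6f}",
                        ",".join(_row_name(matrix, i) for i in b.rows),
                        ",".join(_col_name(matrix, j) for j in b.cols),
                    ]
                )
                + "\n"
            )

    params = result.params
    payload = {
        "method_tag": result.method_tag,
        "params": dataclasses.asdict(params) if dataclasses.is_dataclass(params) else params,
        "skipped": [[list(r), list(c)] for r, c in result.skipped],
        "biclusters": [
            {"rows": list(b.rows), "cols": list(b.cols), "msr_real": b.msr_real}
            for b in result
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return tsv_path, json_path


def read_biclusters(json_path) -> BiclusterSet:
    """Round-trip loader for the JSON dump written by
    :func:`write_biclusters`."""
    d = json.loads(Path(json_path).read_text())
    params = d.get("params")
    if isinstance(params, dict):
        params = SearchParams(**{**params, "mask_range": tuple(params["mask_range"])
                                  if params.get("mask_range") else None})
    out = BiclusterSet(
        [Bicluster(tuple(b["rows"]), tuple(b["cols"]), b["msr_real"]) for b in d["biclusters"]],
        params=params,
        method_tag=d.get("method_tag", ""),
    )
    out.skipped = [(tuple(r), tuple(c)) for r, c in d.get("skipped", [])]
    return out


def match_score(found: Bicluster | ImplantSpec, truth: Bicluster | ImplantSpec) -> float:
    """Jaccard index of the two footprints' element (cell) sets: 1 for
    identical footprints, 0 for disjoint ones."""
    r1, c1 = set(found.rows), set(found.cols)
    r2, c2 = set(truth.rows), set(truth.cols)
    inter = len(r1 & r2) * len(c1 & c2)
    union = len(r1) * len(c1) + len(r2) * len(c2) - inter
    return inter / union if union else 0.0


def best_matches(result: BiclusterSet, truth: GroundTruth) -> list[float]:
    """For each ground-truth implant, the best Jaccard score over the
    discovered biclusters (0 when nothing was discovered)."""
    return [
        max((match_score(b, spec) for b in result), default=0.0)
        for spec in truth.implants
    ]


# ---------------------------------------------------------------------------
# comparison harness


@dataclass
class RunConfig:
    """A repeated cc-vs-shielded comparison.

    Either ``input_path`` (a matrix file, rerun under ``repetitions``
    seeds) or ``synthetic`` (currently ``"overlap"``: the
    overlapping-implant benchmark regenerated per seed) supplies the data.
    """

    input_path: str | None = None
    synthetic: str | None = "overlap"
    #: keyword overrides for the synthetic generator (n, m, noise_sd)
    synthetic_kwargs: dict = field(default_factory=dict)
    methods: tuple[str, ...] = ("cc", "shield")
    search: SearchParams = field(default_factory=SearchParams)
    shield: ShieldParams = field(default_factory=ShieldParams)
    repetitions: int = 10
    out_dir: str | None = None

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        unknown = set(self.methods) - {"cc", "shield"}
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic")
        if self.synthetic is not None and self.synthetic != "overlap":
            raise ValueError(f"unknown synthetic spec {self.synthetic!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "search" in d:
            d["search"] = SearchParams(**d["search"])
        if "shield" in d:
            d["shield"] = ShieldParams(**d["shield"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


def _run_method(method: str, A: ExpressionMatrix, config: RunConfig, seed: int) -> BiclusterSet:
    params = config.search.with_(seed=seed)
    if method == "cc":
        return cc_discover(A, params)
    return shielded_discover(A, params, config.shield)


def compare_methods(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured method for ``repetitions`` seeds and tabulate
    per-bicluster MSR and size, per-method aggregates, and (when ground
    truth exists) per-implant recovery scores.

    Returns a dict with keys ``per_bicluster``, ``summary`` and (synthetic
    data only) ``matches``.  A failing single run is logged and excluded.
    """
    per_rows: list[dict] = []
    match_rows: list[dict] = []
    for rep in range(config.repetitions):
        seed = config.search.seed + rep
        if config.synthetic is not None:
            A, truth = overlapping_pair_dataset(seed=seed, **config.synthetic_kwargs)
        else:
            A, truth = read_matrix(config.input_path), None
        for method in config.methods:
            try:
                result = _run_method(method, A, config, seed)
            except Exception:  # one bad run must not sink the table
                logger.exception("run failed (method=%s, rep=%d); excluded", method, rep)
                continue
            for k, b in enumerate(result, start=1):
                per_rows.append(
                    {"method": method, "rep": rep, "seed": seed, "bicluster": k,
                     "n_rows": b.n_rows, "n_cols": b.n_cols, "size": b.size,
                     "msr": b.msr_real}
                )
            if truth is not None:
                for t, score in enumerate(best_matches(result, truth), start=1):
                    match_rows.append(
                        {"method": method, "rep": rep, "seed": seed,
                         "implant": t, "jaccard": score}
                    )
    per = pd.DataFrame(
        per_rows,
        columns=["method", "rep", "seed", "bicluster", "n_rows", "n_cols", "size", "msr"],
    )
    if per.empty:
        summary = pd.DataFrame(columns=["method", "msr_mean", "msr_std", "size_mean", "size_std"])
    else:
        summary = (
            per.groupby("method")
            .agg(
                msr_mean=("msr", "mean"),
                msr_std=("msr", lambda s: s.std(ddof=0)),
                size_mean=("size", "mean"),
                size_std=("size", lambda s: s.std(ddof=0)),
            )
            .reset_index()
        )
    out = {"per_bicluster": per, "summary": summary}
    if match_rows:
        out["matches"] = pd.DataFrame(match_rows)
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return out
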