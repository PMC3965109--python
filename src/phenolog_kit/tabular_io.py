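"""Readers/writers for the tab-delimited formats the toolkit touches.

Two on-disk shapes exist:

* *matrix* files (XGAP-style): tab-delimited, cell (0,0) empty or a label,
  row 1 holds column ids, column 1 holds row ids.  Numeric matrices parse
  to floats with a configurable missing token (default ``"NA"``); genotype
  matrices parse against a declared symbol alphabet.
* *table* files: plain TSV with a mandatory header row.

All readers validate strictly and every parse error names the file, the
line and the offending token.  Files are UTF-8; both ``\\n`` and ``\\r\\n``
are accepted on read, ``\\n`` is written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_MISSING = "NA"


class FormatError(ValueError):
    """Structural problem in an input file (ragged row, bad header, unparseable cell)."""


class ValidationError(ValueError):
    """Well-formed file violating a content invariant (duplicate ids, bad symbol)."""


@dataclass
class MatrixFile:
    """Dense labelled matrix with an explicit missing marker.

    ``values`` is float for numeric matrices (missing = NaN) and an object
    array of strings for symbolic (genotype) matrices (missing = None).
    Missing cells are never coerced to 0.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids in matrix")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column ids in matrix")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )

    @property
    def is_symbolic(self) -> bool:
        return self.values.dtype == object

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def n_missing(self) -> int:
        if self.is_symbolic:
            return int(sum(v is None for v in self.values.ravel()))
        return int(np.isnan(self.values).sum())

    def transpose(self) -> "MatrixFile":
        return MatrixFile(list(self.col_ids), list(self.row_ids), self.values.T.copy(), self.label)


@dataclass
class TableFile:
    """Ordered-header TSV held as a list of dict records."""

    header: list[str]
    rows: list[dict] = field(default_factory=list)


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    # newline-tolerant: normalise CRLF, drop a single trailing newline
    text = text.replace("\r\n", "\n")
    if text.endswith("\n"):
        text = text[:-1]
    return text.split("\n") if text else []


def read_matrix(
    path: str | Path,
    missing_token: str = DEFAULT_MISSING,
    alphabet: Sequence[str] | None = None,
) -> MatrixFile:
    """Read an XGAP-style tab-delimited matrix.

    Parameters
    ----------
    path : file path
    missing_token : cell value treated as missing (default ``"NA"``)
    alphabet : if given, cells are symbols from this set (genotype mode);
        any symbol outside the alphabet is an error, not missing.
    """
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    label, col_ids = header[0], header[1:]
    if not col_ids:
        raise FormatError(f"{path}, line 1: matrix has no data columns")
    if any(c == "" for c in col_ids):
        raise FormatError(f"{path}, line 1: empty column id")
    if len(set(col_ids)) != len(col_ids):
        raise ValidationError(f"{path}, line 1: duplicate column ids")
    arity = len(header)

    row_ids: list[str] = []
    seen: set[str] = set()
    cells: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != arity:
            raise FormatError(
                f"{path}, line {lineno}: expected {arity} tab-separated fields, got {len(fields)}"
            )
        rid = fields[0]
        if not rid:
            raise FormatError(f"{path}, line {lineno}: empty row id")
        if rid in seen:
            raise ValidationError(f"{path}, line {lineno}: duplicated row id {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        cells.append(fields[1:])

    if alphabet is not None:
        allowed = set(alphabet)
        values = np.empty((len(row_ids), len(col_ids)), dtype=object)
        for i, row in enumerate(cells):
            for j, cell in enumerate(row):
                if cell == missing_token:
                    values[i, j] = None
                elif cell in allowed:
                    values[i, j] = cell
                else:
                    raise ValidationError(
                        f"{path}, line {i + 2}, column {col_ids[j]!r}: symbol {cell!r} "
                        f"not in genotype alphabet {sorted(allowed)}"
                    )
    else:
        values = np.empty((len(row_ids), len(col_ids)), dtype=float)
        for i, row in enumerate(cells):
            for j, cell in enumerate(row):
                if cell == missing_token:
                    values[i, j] = np.nan
                else:
                    try:
                        values[i, j] = float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}, line {i + 2}, column {col_ids[j]!r}: "
                            f"unparseable numeric cell {cell!r}"
                        ) from None
    return MatrixFile(row_ids, col_ids, values, label)


def write_matrix(
    matrix: MatrixFile, path: str | Path, missing_token: str = DEFAULT_MISSING
) -> Path:
    """Write a MatrixFile in the same dialect ``read_matrix`` accepts.

    Reals are written with 12 significant digits so read∘write round-trips
    to that precision; integral values are written without an exponent.
    """
    path = Path(path)

    def fmt(v) -> str:
        if v is None:
            return missing_token
        if isinstance(v, str):
            return v
        if isinstance(v, float) and math.isnan(v):
            return missing_token
        f = float(v)
        if f == int(f) and abs(f) < 1e15:
            return str(int(f))
        return repr(f)  # shortest representation that round-trips exactly

    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([matrix.label] + list(matrix.col_ids)) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write("\t".join([rid] + [fmt(v) for v in row]) + "\n")
    return path


def read_table(path: str | Path, required: Sequence[str] | None = None) -> TableFile:
    """Read a header-mandatory TSV into a TableFile.

    ``required`` columns must be present (a missing one is a FormatError);
    extra columns are kept.
    """
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file (header required)")
    header = lines[0].split("\t")
    if len(set(header)) != len(header):
        raise FormatError(f"{path}, line 1: duplicate column names")
    if required:
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}, line 1: missing mandatory column(s) {missing}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        rows.append(dict(zip(header, fields)))
    return TableFile(header, rows)


def write_table(table: TableFile, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(table.header) + "\n")
        for row in table.rows:
            fh.write("\t".join(str(row[c]) for c in table.header) + "\n")
    return path


RESULT_COLUMNS = [
    "term1_label",
    "term1_source",
    "term2_label",
    "term2_source",
    "n1",
    "n2",
    "k",
    "N",
    "p",
    "p_adjusted",
]


def write_results(results, path: str | Path) -> Path:
    """Write phenolog test results as TSV, one row per (term1, term2) pair.

    ``results`` must already be sorted by ascending p (the sweeps produce
    this order); an unsorted list is a contract violation, not silently
    re-sorted.  P-values are written in scientific notation with 4
    significant digits.
    """
    path = Path(path)
    ps = [r.p for r in results]
    if any(a > b for a, b in zip(ps, ps[1:])):
        raise ValidationError("results must be sorted by ascending p before writing")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            adj = "" if r.p_adjusted is None else f"{r.p_adjusted:.3e}"
            fh.write(
                "\t".join(
                    [
                        r.term1.label,
                        r.term1.source,
                        r.term2.label,
                        r.term2.source,
                        str(r.n1),
                        str(r.n2),
                        str(r.k),
                        str(r.N),
                        f"{r.p:.3e}",
                        adj,
                    ]
                )
                + "\n"
            )
    return path
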