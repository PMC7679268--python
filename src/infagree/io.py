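"""CSV readers/writers for contingency tables and agreement reports.

Agreement data has no standard bioinformatics interchange format; plain CSV
of the count grid is the canonical representation here.  The reader accepts
an optional header row / label column and an optional marginal-totals row
and column (auto-detected, validated against the recomputed sums, then
stripped), so tables can be pasted directly from typeset publications.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import asdict
from pathlib import Path
from typing import TextIO

import numpy as np

from .agreement import AgreementReport
from .types import ContingencyTable
from .util import round_half_away

__all__ = ["read_table", "write_table", "write_report", "parse_report"]


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _parse_int(cell: str, where: str) -> int:
    try:
        value = float(cell)
    except ValueError:
        raise ValueError(f"non-numeric cell {cell!r} at {where}") from None
    if value != int(value):
        raise ValueError(f"non-integer count {cell!r} at {where}")
    if value < 0:
        raise ValueError(f"negative count {cell!r} at {where}")
    return int(value)


def read_table(
    source: str | Path | TextIO, *, delimiter: str = ","
) -> ContingencyTable:
    """Read a square contingency table from CSV.

    Accepted layouts: a bare numeric grid; a grid with a header row and/or
    a leading label column; and either form with an appended marginal
    totals row/column, which is detected (it must equal the recomputed
    sums; the corner, if present, must equal N) and removed.  Ragged,
    non-square, negative, fractional or empty grids raise ``ValueError``
    with the offending location.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            rows = list(csv.reader(fh, delimiter=delimiter))
    else:
        rows = list(csv.reader(source, delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError("empty CSV: no table found")

    # optional header row: any non-numeric cell beyond a possible corner
    header: list[str] | None = None
    first = [c.strip() for c in rows[0]]
    if any(not _is_number(c) for c in first if c):
        header = first
        rows = rows[1:]
        if not rows:
            raise ValueError("CSV contains a header but no data rows")

    # optional label column: first cell of each data row non-numeric
    row_labels: list[str] | None = None
    firsts = [r[0].strip() if r else "" for r in rows]
    if all(f and not _is_number(f) for f in firsts):
        row_labels = firsts
        rows = [r[1:] for r in rows]
        if header is not None and len(header) == len(rows[0]) + 1:
            header = header[1:]

    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"ragged grid: row {i + 1} has {len(r)} cells, expected {width}")
    grid = np.array(
        [[_parse_int(c.strip(), f"row {i + 1}, column {j + 1}") for j, c in enumerate(r)]
         for i, r in enumerate(rows)],
        dtype=np.int64,
    )

    labels = None
    if row_labels is not None:
        labels = row_labels
    elif header is not None and len(header) == width:
        labels = header

    grid, labels = _strip_totals(grid, labels)
    if grid.shape[0] != grid.shape[1]:
        raise ValueError(f"table must be square, got {grid.shape[0]} rows x {grid.shape[1]} columns")
    return ContingencyTable(grid, labels)


def _strip_totals(grid: np.ndarray, labels):
    """Detect and remove appended marginal-totals row/column, validating them."""
    def trim_labels(lbls, k):
        return None if lbls is None else lbls[:k]

    r, c = grid.shape
    # totals row AND column (corner = grand total)
    if r >= 3 and c >= 3 and r == c:
        body = grid[:-1, :-1]
        if (
            np.array_equal(grid[-1, :-1], body.sum(axis=0))
            and np.array_equal(grid[:-1, -1], body.sum(axis=1))
            and grid[-1, -1] == body.sum()
        ):
            return body, trim_labels(labels, r - 1)
    # totals row only (one extra row)
    if r == c + 1:
        body = grid[:-1, :]
        if np.array_equal(grid[-1, :], body.sum(axis=0)):
            return body, trim_labels(labels, c)
        raise ValueError(
            f"extra row does not match the column totals {body.sum(axis=0).tolist()}"
        )
    # totals column only (one extra column)
    if c == r + 1:
        body = grid[:, :-1]
        if np.array_equal(grid[:, -1], body.sum(axis=1)):
            return body, trim_labels(labels, r)
        raise ValueError(
            f"extra column does not match the row totals {body.sum(axis=1).tolist()}"
        )
    # square with totals in last row+col but mismatching: report it
    if r == c and r >= 3:
        body = grid[:-1, :-1]
        looks_total_row = np.array_equal(grid[-1, :-1], body.sum(axis=0))
        looks_total_col = np.array_equal(grid[:-1, -1], body.sum(axis=1))
        if looks_total_row != looks_total_col:
            which = "column" if looks_total_row else "row"
            raise ValueError(f"marginal totals present but the {which} totals do not match")
    return grid, labels


def write_table(table: ContingencyTable, dest: str | Path | TextIO, *, delimiter: str = ",") -> None:
    """Write a table's counts (with labels, when present) as CSV."""
    def _write(fh):
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if table.labels is not None:
            w.writerow(["", *table.labels])
            for lbl, row in zip(table.labels, table.counts):
                w.writerow([lbl, *row.tolist()])
        else:
            for row in table.counts:
                w.writerow(row.tolist())

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            _write(fh)
    else:
        _write(dest)


_DISPLAY_FIELDS = ("h_row", "h_col", "h_cond", "mi", "p_o", "p_e", "kappa", "ia")


def write_report(report: AgreementReport, fmt: str = "text", precision: int = 3) -> str:
    """Render an :class:`AgreementReport`.

    ``fmt="text"`` is a human-readable block with values displayed at
    ``precision`` decimals; ``fmt="json"`` is a machine-readable rendering
    at full precision that :func:`parse_report` round-trips exactly.
    Undefined indexes are flagged, never printed as numbers.
    """
    if fmt == "json":
        return json.dumps(asdict(report))
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = [f"q = {report.q}   N = {report.n}   log base = {report.base:g}"]
    names = {
        "h_row": "H(row rater)",
        "h_col": "H(col rater)",
        "h_cond": "H(row/col)",
        "mi": "MI",
        "p_o": "p_o",
        "p_e": "p_e",
        "kappa": "kappa",
        "ia": "IA",
    }
    for fieldname in _DISPLAY_FIELDS:
        value = getattr(report, fieldname)
        label = names[fieldname]
        if value is None:
            reason = getattr(report, f"{fieldname}_undefined_reason")
            lines.append(f"{label:13s} undefined ({reason})")
        else:
            lines.append(f"{label:13s} {round_half_away(value, precision):.{precision}f}")
    if report.kappa_band is not None:
        lines.append(f"{'kappa band':13s} {report.kappa_band}")
    return "\n".join(lines)


def parse_report(text: str) -> AgreementReport:
    """Inverse of ``write_report(..., fmt="json")``."""
    return AgreementReport(**json.loads(text))
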