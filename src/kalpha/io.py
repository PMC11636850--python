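"""Reading, validating and summarizing reliability data matrices.

The input is a headerless delimited text file laid out items-by-raters:
one row per rated unit, one column per rater, comma or semicolon as the
delimiter (tabs are rejected), integer rates, and the literal token
``NA`` for a missing rating.  No header, footer or blank interior lines
are allowed, and in strict mode no whitespace may surround a token.

A relaxed mode (``relaxed=True``) is offered as a documented extension:
tokens are stripped of surrounding whitespace and decimal rates are
accepted, which is occasionally convenient for interval- or ratio-scale
data exported by other tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import DegenerateDataError, FormatError

#: Literal token denoting a missing rating.
NA_TOKEN = "NA"

_PERMITTED_DELIMITERS = (",", ";")
_INT_RE = re.compile(r"-?\d+\Z")

Rate = Optional[float]  # int in strict mode; None = missing


@dataclass(frozen=True)
class ReliabilityMatrix:
    """An items x raters grid of ratings with explicit missing cells.

    Rows are the rated units, columns are the raters, ``None`` marks a
    missing rating.  The grid must be rectangular with at least one unit
    and at least two raters; rates are numbers (integers under the
    strict file contract).
    """

    cells: tuple[tuple[Rate, ...], ...]

    def __post_init__(self) -> None:
        if len(self.cells) < 1:
            raise FormatError("matrix must contain at least one item row")
        width = len(self.cells[0])
        if width < 2:
            raise FormatError("matrix must contain at least two rater columns")
        for i, row in enumerate(self.cells):
            if len(row) != width:
                raise FormatError(
                    f"row {i + 1} has {len(row)} entries, expected {width}"
                )
            for j, v in enumerate(row):
                if v is None:
                    continue
                if isinstance(v, bool) or not isinstance(v, (int, float)):
                    raise FormatError(
                        f"rate at row {i + 1}, column {j + 1} is not a number: {v!r}"
                    )

    @property
    def n_items(self) -> int:
        return len(self.cells)

    @property
    def n_raters(self) -> int:
        return len(self.cells[0])

    def rows(self) -> list[list[Rate]]:
        """The cells as a mutable list of lists (a copy)."""
        return [list(row) for row in self.cells]

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[Rate]]) -> "ReliabilityMatrix":
        return cls(tuple(tuple(row) for row in rows))


@dataclass(frozen=True)
class DataSummary:
    """Validation report for a reliability matrix.

    ``n_valid_items`` counts units carrying at least two ratings (only
    those contribute pairable information) and ``n_pairable`` is the
    total number of ratings inside such units -- the grand total n.. of
    the rates-by-units tally.
    """

    n_raters: int
    n_items: int
    n_missing: int
    min_rate: float
    max_rate: float
    n_valid_items: int
    n_pairable: int


def detect_delimiter(raw_text: str) -> str:
    """Identify the delimiter of a reliability data file.

    Exactly one of comma or semicolon must split every non-empty line
    into the same number (>= 2) of fields.  Tab characters anywhere in
    the file are a format error, as is a file where both delimiters
    would give a consistent but different parse.
    """
    if not raw_text or not raw_text.strip():
        raise FormatError("input is empty")
    if "\t" in raw_text:
        raise FormatError("tab delimiters are not permitted; use ',' or ';'")

    lines = _split_lines(raw_text)

    def consistent(delim: str) -> bool:
        counts = {line.count(delim) + 1 for line in lines}
        return len(counts) == 1 and counts.pop() >= 2

    ok = [d for d in _PERMITTED_DELIMITERS if consistent(d)]
    if len(ok) == 2:
        raise FormatError(
            "ambiguous delimiter: both ',' and ';' give a consistent parse"
        )
    if len(ok) == 1:
        return ok[0]
    if any(d in raw_text for d in _PERMITTED_DELIMITERS):
        raise FormatError("ragged rows: lines have differing field counts")
    raise FormatError("no permitted delimiter found; need >= 2 rater columns")


def parse_reliability_csv(raw_text: str, *, relaxed: bool = False) -> ReliabilityMatrix:
    """Parse delimited text into a :class:`ReliabilityMatrix`.

    Strict mode (default) enforces the file contract: integer rates,
    ``NA`` for missing, no surrounding whitespace.  Relaxed mode trims
    whitespace and admits decimal rates.

    Raises :class:`FormatError` naming the offending row and column on
    any violation.
    """
    delim = detect_delimiter(raw_text)
    rows: list[list[Rate]] = []
    for i, line in enumerate(_split_lines(raw_text)):
        row: list[Rate] = []
        for j, tok in enumerate(line.split(delim)):
            row.append(_parse_token(tok, i, j, relaxed))
        rows.append(row)
    return ReliabilityMatrix.from_rows(rows)


def write_matrix(m: ReliabilityMatrix, delimiter: str = ",") -> str:
    """Serialize a matrix back to the file format (inverse of parsing)."""
    if delimiter not in _PERMITTED_DELIMITERS:
        raise FormatError(f"delimiter must be one of {_PERMITTED_DELIMITERS}")
    lines = []
    for row in m.cells:
        lines.append(delimiter.join(NA_TOKEN if v is None else _fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def summarize_matrix(m: ReliabilityMatrix) -> DataSummary:
    """Compute the validation report shown before any alpha calculation.

    Units with one or zero ratings are excluded from the valid-item and
    pairable counts; a matrix with no ratings at all is degenerate.
    """
    present = [v for row in m.cells for v in row if v is not None]
    if not present:
        raise DegenerateDataError("matrix contains no ratings at all")
    n_missing = m.n_items * m.n_raters - len(present)
    valid_rows = [
        row for row in m.cells if sum(v is not None for v in row) >= 2
    ]
    n_pairable = sum(sum(v is not None for v in row) for row in valid_rows)
    return DataSummary(
        n_raters=m.n_raters,
        n_items=m.n_items,
        n_missing=n_missing,
        min_rate=min(present),
        max_rate=max(present),
        n_valid_items=len(valid_rows),
        n_pairable=n_pairable,
    )


def _split_lines(raw_text: str) -> list[str]:
    # One trailing newline is tolerated; blank interior lines are errors.
    text = raw_text[:-1] if raw_text.endswith("\n") else raw_text
    lines = [line[:-1] if line.endswith("\r") else line for line in text.split("\n")]
    for i, line in enumerate(lines):
        if line.strip() == "":
            raise FormatError(f"blank line at row {i + 1}; empty lines are not allowed")
    return lines


def _parse_token(tok: str, i: int, j: int, relaxed: bool) -> Rate:
    where = f"row {i + 1}, column {j + 1}"
    if relaxed:
        tok = tok.strip()
    if tok == NA_TOKEN:
        return None
    if _INT_RE.match(tok):
        return int(tok)
    if relaxed:
        try:
            val = float(tok)
        except ValueError:
            raise FormatError(f"invalid rate {tok!r} at {where}") from None
        if val != val or val in (float("inf"), float("-inf")):
            raise FormatError(f"non-finite rate {tok!r} at {where}")
        return val
    if not tok or tok.strip() != tok:
        raise FormatError(f"empty or whitespace-padded field at {where}")
    raise FormatError(
        f"invalid rate {tok!r} at {where}: rates must be integers or {NA_TOKEN!r}"
    )


def _fmt(v: float) -> str:
    if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
        return str(int(v))
    return repr(v)
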