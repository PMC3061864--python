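"""Delimited-text input/output for time-resolved data matrices.

The interchange format is plain CSV/TSV: the first row carries the channel
(wavelength/pixel) axis, the first column the delay-time axis, and the body
the signal.  Lines starting with ``#`` are metadata comments of the form
``# key: value`` and survive a read/write round trip.  Numbers are written
with ``repr`` so that read ∘ write is byte-identical.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DataMatrix", "MatrixParseError", "read_matrix", "write_matrix"]

_DELIMS = {"csv": ",", "tsv": "\t"}


class MatrixParseError(ValueError):
    """Raised when a delimited data-matrix file cannot be parsed."""


@dataclass
class DataMatrix:
    """A delay-time × detection-channel signal array.

    Attributes
    ----------
    times : (m,) strictly increasing delay times (seconds unless declared
        otherwise in ``metadata``).
    channels : (n,) strictly monotone wavelength / pixel axis.
    values : (m, n) signal array; NaN marks masked cells.
    metadata : free-form string metadata written as ``#`` header comments.
    """

    times: np.ndarray
    channels: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.channels.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with axes "
                f"({self.times.size}, {self.channels.size})"
            )
        for name, ax in (("times", self.times), ("channels", self.channels)):
            if ax.size > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError(f"{name} axis must be strictly monotone")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.channels)):
            raise ValueError("axes must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "DataMatrix":
        return DataMatrix(
            self.times.copy(), self.channels.copy(), self.values.copy(), dict(self.metadata)
        )


def _parse_float(token: str, line_no: int) -> float:
    token = token.strip()
    if token == "":
        return float("nan")
    try:
        return float(token)
    except ValueError as exc:
        raise MatrixParseError(f"line {line_no}: non-numeric cell {token!r}") from exc


def read_matrix(path, dialect: str = "csv", transposed: bool | None = None) -> DataMatrix:
    """Read a delimited data matrix.

    Orientation is auto-detected: if the row axis is not strictly monotone
    but the column axis is, the matrix is transposed so that rows are time
    points.  ``transposed=True`` forces a transpose, ``False`` forbids it.
    """
    delim = _DELIMS[dialect]
    metadata: dict = {}
    rows: list[list[str]] = []
    line_nos: list[int] = []
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        if not line.strip():
            continue
        rows.append(next(csv.reader([line], delimiter=delim)))
        line_nos.append(i)
    if len(rows) < 2:
        raise MatrixParseError("file holds no data rows")
    width = len(rows[0])
    for r, ln in zip(rows, line_nos):
        if len(r) != width:
            raise MatrixParseError(f"line {ln}: ragged row ({len(r)} fields, expected {width})")
    header = [_parse_float(tok, line_nos[0]) for tok in rows[0][1:]]
    times, body = [], []
    for r, ln in zip(rows[1:], line_nos[1:]):
        times.append(_parse_float(r[0], ln))
        body.append([_parse_float(tok, ln) for tok in r[1:]])
    t = np.array(times)
    ch = np.array(header)
    vals = np.array(body)

    def _dups(ax, name, ln_hint):
        if np.unique(ax).size != ax.size:
            raise MatrixParseError(f"duplicated {name} value (near line {ln_hint})")

    _dups(t, "time-axis", line_nos[1])
    _dups(ch, "channel-axis", line_nos[0])

    if transposed is None:
        t_mono = t.size < 2 or np.all(np.diff(t) > 0)
        ch_mono = ch.size < 2 or np.all(np.diff(ch) > 0)
        transposed = (not t_mono) and ch_mono
    if transposed:
        t, ch, vals = ch, t, vals.T
    return DataMatrix(t, ch, vals, metadata)


def write_matrix(data: DataMatrix, path, dialect: str = "csv") -> None:
    """Write ``data``; inverse of :func:`read_matrix` (byte-stable formatting)."""
    if data.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    delim = _DELIMS[dialect]
    buf = _stdio.StringIO()
    for k, v in data.metadata.items():
        buf.write(f"# {k}: {v}\n")
    fmt = lambda x: "" if np.isnan(x) else repr(float(x))  # noqa: E731
    buf.write("time" + delim + delim.join(fmt(c) for c in data.channels) + "\n")
    for t, row in zip(data.times, data.values):
        buf.write(fmt(t) + delim + delim.join(fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())
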