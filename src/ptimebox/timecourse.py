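"""Time-course matrices: reading, writing, validation and filtering.

A :class:`TimeCourseSet` holds ``N`` labeled expression time courses sampled
at ``T`` shared time points. Missing measurements are carried as NaN in the
value matrix and exposed through :attr:`TimeCourseSet.missing_mask`. Time
labels are cosmetic metadata; every algorithm in this package operates on the
integer index axis ``1..T``.

The on-disk format is a delimited text matrix: first row holds the time
labels, first column the course identifiers, and missing values are written
as a configurable NA token. Values are printed at full ``repr`` precision so
a write/read round trip is exact.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyFilterError, MatrixFormatError, ValidationError

__all__ = [
    "TimeCourseSet",
    "read_matrix",
    "write_matrix",
    "filter_courses",
    "data_range",
]


@dataclass
class TimeCourseSet:
    """``N`` labeled time courses over ``T`` shared time points.

    Parameters
    ----------
    ids
        Unique, non-empty string labels, one per course.
    times
        Strictly increasing real time labels, one per column. Cosmetic only.
    values
        ``N x T`` float matrix; NaN marks a missing measurement.
    """

    ids: list[str]
    times: list[float]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.times = [float(t) for t in self.times]
        self.values = np.asarray(self.values, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n, t = len(self.ids), len(self.times)
        if n < 1:
            raise ValidationError("a TimeCourseSet needs at least one course")
        if t < 1:
            raise ValidationError("a TimeCourseSet needs at least one time point")
        if any(i == "" for i in self.ids):
            raise ValidationError("course ids must be non-empty strings")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate course ids: {dupes}")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("time labels must be strictly increasing")
        if self.values.ndim != 2 or self.values.shape != (n, t):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} ids x {t} time points"
            )
        if np.isinf(self.values).any():
            raise ValidationError("non-missing values must be finite")
        observed = ~np.isnan(self.values)
        for i, row_ok in enumerate(observed.any(axis=1)):
            if not row_ok:
                raise ValidationError(
                    f"time course '{self.ids[i]}' has no non-missing values"
                )

    # -- derived views -----------------------------------------------------

    @property
    def n_courses(self) -> int:
        return len(self.ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def missing_mask(self) -> np.ndarray:
        """``N x T`` boolean matrix, True where the measurement is absent."""
        return np.isnan(self.values)

    def course(self, ident: str) -> np.ndarray:
        """Return the value row (with NaNs) for a course id."""
        return self.values[self.ids.index(ident)]

    def data_range(self) -> tuple[float, float]:
        """Minimum and maximum over all non-missing entries."""
        return float(np.nanmin(self.values)), float(np.nanmax(self.values))


def data_range(tcs: TimeCourseSet) -> tuple[float, float]:
    """Functional alias for :meth:`TimeCourseSet.data_range`."""
    return tcs.data_range()


def read_matrix(
    path: str | Path,
    *,
    delimiter: str = "\t",
    na_token: str = "NA",
) -> TimeCourseSet:
    """Read a delimited expression matrix into a validated TimeCourseSet.

    The first row must hold the time labels (the top-left cell is ignored),
    the first column the course ids. Cells equal to ``na_token`` become
    missing values.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if len(rows) < 2:
        raise MatrixFormatError(f"{path}: need a header row and at least one course")
    header = rows[0]
    if len(header) < 2:
        raise MatrixFormatError(f"{path}: header must name at least one time point")
    try:
        times = [float(c) for c in header[1:]]
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric time label in header: {exc}") from None
    width = len(header)
    ids: list[str] = []
    values = np.empty((len(rows) - 1, width - 1), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixFormatError(
                f"{path}: line {r} has {len(row)} fields, expected {width} (ragged row)"
            )
        ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            if cell == na_token:
                values[r - 2, c] = math.nan
            else:
                try:
                    values[r - 2, c] = float(cell)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: line {r}, column {c + 2}: cannot parse value {cell!r}"
                    ) from None
    return TimeCourseSet(ids=ids, times=times, values=values)


def write_matrix(
    tcs: TimeCourseSet,
    path: str | Path,
    *,
    delimiter: str = "\t",
    na_token: str = "NA",
) -> None:
    """Write a TimeCourseSet so that :func:`read_matrix` reproduces it exactly.

    Re-validates the set first; nothing is written if validation fails.
    """
    tcs._validate()
    path = Path(path)
    lines = [delimiter.join(["id"] + [repr(t) for t in tcs.times])]
    for ident, row in zip(tcs.ids, tcs.values):
        cells = [ident] + [na_token if math.isnan(v) else repr(float(v)) for v in row]
        lines.append(delimiter.join(cells))
    path.write_text("\n".join(lines) + "\n")


def filter_courses(
    tcs: TimeCourseSet,
    max_missing_fraction: float = 0.25,
    min_range: float = 1.0,
) -> TimeCourseSet:
    """Drop courses with too many missing values or too little dynamic range.

    A course is retained iff its missing fraction is <= ``max_missing_fraction``
    and the spread (max - min) of its non-missing values is >= ``min_range``.
    The default thresholds are arbitrary conventions for log-scale data and
    should be tuned per data set. Order is preserved; idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValidationError("max_missing_fraction must lie in [0, 1]")
    if min_range < 0:
        raise ValidationError("min_range must be >= 0")
    miss_frac = np.isnan(tcs.values).mean(axis=1)
    spread = np.nanmax(tcs.values, axis=1) - np.nanmin(tcs.values, axis=1)
    keep = (miss_frac <= max_missing_fraction) & (spread >= min_range)
    if not keep.any():
        raise EmptyFilterError(
            "empty after filtering: no course passes "
            f"max_missing_fraction={max_missing_fraction}, min_range={min_range}"
        )
    ids = [i for i, k in zip(tcs.ids, keep) if k]
    return TimeCourseSet(ids=ids, times=list(tcs.times), values=tcs.values[keep])
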