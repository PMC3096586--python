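"""Timeboxes and query specifications.

A timebox is a rectangle in (time-index, value) space. Its time coordinates
are continuous on the index axis (a box may start at t=1.5) but value
constraints and emissions are only ever evaluated at integer time points;
continuous geometry parameterizes expected durations in the compiled model.

Query consistency rules enforced here:

* boxes must be at least 1.0 wide in time (one expected time unit),
* boxes must have nonzero height,
* boxes must lie within ``[1, T]``,
* boxes must have disjoint interiors in time (abutting edges are legal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .errors import QueryValidationError

__all__ = [
    "DETERMINISTIC",
    "PROBABILISTIC",
    "Timebox",
    "QuerySpec",
    "validate_query",
    "parse_query",
]

DETERMINISTIC = "deterministic"
PROBABILISTIC = "probabilistic"


@dataclass(frozen=True)
class Timebox:
    """One query rectangle ``[t_lo, t_hi] x [x_lo, x_hi]``."""

    t_lo: float
    t_hi: float
    x_lo: float
    x_hi: float

    @property
    def duration(self) -> float:
        return self.t_hi - self.t_lo

    def covered_timepoints(self) -> range:
        """Integer (1-based) time points whose index falls inside the box."""
        return range(math.ceil(self.t_lo), math.floor(self.t_hi) + 1)

    def __str__(self) -> str:  # used in validation messages
        return f"[{self.t_lo}, {self.t_hi}] x [{self.x_lo}, {self.x_hi}]"


@dataclass(frozen=True)
class QuerySpec:
    """An ordered list of time-disjoint boxes plus mode and stringency."""

    boxes: tuple[Timebox, ...]
    mode: str = PROBABILISTIC
    stringency_m: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))


def validate_query(spec: QuerySpec, T: float) -> QuerySpec:
    """Check all query invariants against a data set with ``T`` time points.

    Returns the canonical spec (boxes sorted by ``t_lo``). Pass
    ``T = math.inf`` to run only the data-independent checks.

    Raises
    ------
    QueryValidationError
        naming the offending box(es) for: degenerate height, sub-unit
        duration, out-of-range coordinates, overlapping boxes, or a missing
        or non-positive stringency in probabilistic mode.
    """
    if spec.mode not in (DETERMINISTIC, PROBABILISTIC):
        raise QueryValidationError(f"unknown query mode {spec.mode!r}")
    if len(spec.boxes) < 1:
        raise QueryValidationError("a query needs at least one timebox")
    for b in spec.boxes:
        if not all(math.isfinite(v) for v in (b.t_lo, b.t_hi, b.x_lo, b.x_hi)):
            raise QueryValidationError(f"non-finite coordinate in box {b}")
        if b.x_lo >= b.x_hi:
            raise QueryValidationError(f"degenerate height: box {b} has x_lo >= x_hi")
        if b.duration < 1.0:
            raise QueryValidationError(
                f"sub-unit duration: box {b} is {b.duration} wide; "
                "boxes must span at least 1.0 time units"
            )
        if b.t_lo < 1.0 or b.t_hi > T:
            raise QueryValidationError(f"out of range: box {b} exceeds [1, {T}]")
    boxes = tuple(sorted(spec.boxes, key=lambda b: b.t_lo))
    for a, b in zip(boxes, boxes[1:]):
        if a.t_hi > b.t_lo:
            raise QueryValidationError(f"overlapping boxes: {a} and {b}")
    if spec.mode == PROBABILISTIC:
        m = spec.stringency_m
        if m is None:
            raise QueryValidationError("probabilistic mode requires a stringency m")
        if not isinstance(m, int) or isinstance(m, bool) or m < 1:
            raise QueryValidationError(f"stringency m must be an integer >= 1, got {m!r}")
    return replace(spec, boxes=boxes)


def _require(condition: bool, where: str, message: str) -> None:
    if not condition:
        raise QueryValidationError(f"{where}: {message}")


def parse_query(path: str | Path) -> QuerySpec:
    """Parse a query document (JSON or YAML) into a validated QuerySpec.

    Schema::

        {"mode": "probabilistic" | "deterministic",
         "m": <int, required in probabilistic mode>,
         "boxes": [{"t_lo": .., "t_hi": .., "x_lo": .., "x_hi": ..}, ...]}

    Data-independent invariants are checked here; bounds against the actual
    ``T`` are re-checked when the query is run.
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise QueryValidationError(f"{path}: cannot parse query document: {exc}") from None
    _require(isinstance(doc, dict), str(path), "top level must be a mapping")
    _require("mode" in doc, str(path), "missing field 'mode'")
    _require("boxes" in doc, str(path), "missing field 'boxes'")
    _require(isinstance(doc["boxes"], list), f"{path}: boxes", "must be a list")
    boxes = []
    for i, entry in enumerate(doc["boxes"]):
        where = f"{path}: boxes[{i}]"
        _require(isinstance(entry, dict), where, "each box must be a mapping")
        for key in ("t_lo", "t_hi", "x_lo", "x_hi"):
            _require(key in entry, f"{where}.{key}", "missing field")
            _require(
                isinstance(entry[key], (int, float)) and not isinstance(entry[key], bool),
                f"{where}.{key}",
                f"must be a number, got {entry[key]!r}",
            )
        boxes.append(
            Timebox(
                t_lo=float(entry["t_lo"]),
                t_hi=float(entry["t_hi"]),
                x_lo=float(entry["x_lo"]),
                x_hi=float(entry["x_hi"]),
            )
        )
    m = doc.get("m")
    if m is not None:
        _require(
            isinstance(m, int) and not isinstance(m, bool),
            f"{path}: m",
            f"must be an integer, got {m!r}",
        )
    spec = QuerySpec(boxes=tuple(boxes), mode=str(doc["mode"]), stringency_m=m)
    return validate_query(spec, math.inf)
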