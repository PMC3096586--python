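"""The classic deterministic timebox query.

A course satisfies a box iff at every integer time point inside the box's
time span its value is present and lies in the closed interval
``[x_lo, x_hi]``; a multi-box query is the intersection of the per-box
memberships. A missing value inside a box fails the box — this brittleness
(one outlier or gap excludes a course) is exactly what the probabilistic
engine is meant to fix, and is kept here as the comparison baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import QueryValidationError
from .timebox import DETERMINISTIC, QuerySpec, Timebox, validate_query
from .timecourse import TimeCourseSet

__all__ = ["DeterministicResult", "satisfies_box", "run_deterministic"]


@dataclass(frozen=True)
class DeterministicResult:
    """Membership set of a deterministic query, in input order."""

    member_ids: tuple[str, ...]

    def __contains__(self, ident: str) -> bool:
        return ident in self.member_ids

    def __len__(self) -> int:
        return len(self.member_ids)


def satisfies_box(values: np.ndarray, box: Timebox) -> bool:
    """True iff every integer time point covered by ``box`` is present and
    inside ``[x_lo, x_hi]``.

    ``values`` is a single course's value row (1-based time point ``t`` at
    index ``t - 1``), with NaN for missing. A box covering no integer time
    point is vacuously satisfied.
    """
    for t in box.covered_timepoints():
        v = values[t - 1]
        if math.isnan(v) or not (box.x_lo <= v <= box.x_hi):
            return False
    return True


def run_deterministic(spec: QuerySpec, tcs: TimeCourseSet) -> DeterministicResult:
    """Evaluate a deterministic multi-box query: intersection over all boxes."""
    if spec.mode != DETERMINISTIC:
        raise QueryValidationError(
            f"run_deterministic requires mode={DETERMINISTIC!r}, got {spec.mode!r}"
        )
    spec = validate_query(spec, tcs.n_times)
    members = tuple(
        ident
        for ident, row in zip(tcs.ids, tcs.values)
        if all(satisfies_box(row, b) for b in spec.boxes)
    )
    return DeterministicResult(member_ids=members)
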