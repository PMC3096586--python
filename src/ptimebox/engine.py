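"""Probabilistic query evaluation: score all courses, return the top m.

The model is compiled once per query; every course is then scored with the
forward algorithm (total cost O(N*K*T)) and the ``m`` highest-scoring courses
are returned in descending log-likelihood order. Ties are broken by input
order so results are reproducible; ``-inf``-scored courses (impossible under
the model) appear only when needed to pad the result up to ``m``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import QueryValidationError
from .hmm import compile_hmm, forward_loglik
from .timebox import PROBABILISTIC, QuerySpec, validate_query
from .timecourse import TimeCourseSet

__all__ = ["RankedResult", "score_table", "run_probabilistic"]


@dataclass(frozen=True)
class RankedResult:
    """Top-m query result: (id, log-likelihood) pairs, best first."""

    entries: tuple[tuple[str, float], ...]
    m_requested: int
    n_scored: int

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ident for ident, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def score_table(
    spec: QuerySpec,
    tcs: TimeCourseSet,
    *,
    support_pad: float = 0.0,
) -> list[tuple[str, float]]:
    """Log-likelihood of every course under the compiled query model,
    in input order."""
    hmm = compile_hmm(spec, tcs, support_pad=support_pad)
    return [(ident, forward_loglik(hmm, row)) for ident, row in zip(tcs.ids, tcs.values)]


def run_probabilistic(
    spec: QuerySpec,
    tcs: TimeCourseSet,
    *,
    m: int | None = None,
    support_pad: float = 0.0,
) -> RankedResult:
    """Score all courses and return the ``m`` best.

    ``m`` defaults to the spec's stringency. Requesting more courses than
    exist returns everything with a warning.
    """
    if spec.mode != PROBABILISTIC:
        raise QueryValidationError(
            f"run_probabilistic requires mode={PROBABILISTIC!r}, got {spec.mode!r}"
        )
    spec = validate_query(spec, tcs.n_times)
    if m is None:
        m = spec.stringency_m
    if m is None or m < 1:
        raise QueryValidationError(f"stringency m must be >= 1, got {m!r}")
    table = score_table(spec, tcs, support_pad=support_pad)
    n = len(table)
    if m > n:
        warnings.warn(f"m={m} exceeds the {n} available courses; returning all", stacklevel=2)
    ranked = sorted(table, key=lambda e: -e[1])  # stable: ties keep input order
    top = ranked[: min(m, n)]
    if any(math.isinf(ll) for _, ll in top):
        warnings.warn(
            "result padded with courses scoring -inf (impossible under the model)",
            stacklevel=2,
        )
    return RankedResult(entries=tuple(top), m_requested=m, n_scored=n)
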