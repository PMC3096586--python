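"""Linear hidden Markov models compiled from timebox queries.

Each user box becomes one state with a normal emission: the mean is the box's
vertical midpoint, the standard deviation a quarter of the box height (so the
box spans mu +/- 2 sigma, about 95.5% of the emission mass), and the box
width is the state's expected duration. Durations are geometric: a state with
expected duration ``d`` has self-transition probability ``p = 1 - 1/d``.

Time spans not covered by any box — gaps between boxes and the margins
before the first and after the last box — get waiting states with a uniform
emission over the data's value range. After assembly all expected durations
are rescaled so they sum to ``T``, with a floor of 1.0 per state
(clamp-and-redistribute, iterated to a fixed point).

The topology is a left-to-right chain: from state ``k`` only self-transitions
(probability ``p_k``) and advances to ``k+1`` (probability ``1 - p_k``) are
possible; state 1 is the unique start state and state ``K`` the unique end
state. ``forward_loglik`` returns the forward mass that sits in state ``K``
at the final time point, computed entirely in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CompileError, ValidationError
from .timebox import PROBABILISTIC, QuerySpec, Timebox, validate_query
from .timecourse import TimeCourseSet

__all__ = [
    "NORMAL",
    "UNIFORM",
    "HmmState",
    "LinearHMM",
    "box_to_state",
    "compile_hmm",
    "emission_logdensity",
    "forward_loglik",
    "forward_eval_count",
    "reset_forward_eval_count",
]

NORMAL = "normal"
UNIFORM = "uniform"

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Count of forward_loglik invocations; used to verify the O(N·K·T) scaling
# contract by counting work instead of timing it.
_FORWARD_EVALS = 0


def forward_eval_count() -> int:
    return _FORWARD_EVALS


def reset_forward_eval_count() -> None:
    global _FORWARD_EVALS
    _FORWARD_EVALS = 0


@dataclass(frozen=True)
class HmmState:
    """One state of the chain: geometric duration plus an emission density."""

    kind: str
    expected_duration: float
    self_prob: float
    mu: float | None = None
    sigma: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NORMAL, UNIFORM):
            raise ValidationError(f"unknown state kind {self.kind!r}")
        if not 0.0 <= self.self_prob < 1.0:
            raise ValidationError(f"self_prob must lie in [0, 1), got {self.self_prob}")
        if self.expected_duration < 1.0 - 1e-12:
            raise ValidationError(
                f"expected_duration must be >= 1.0, got {self.expected_duration}"
            )
        if abs(self.self_prob - (1.0 - 1.0 / self.expected_duration)) > 1e-9:
            raise ValidationError(
                "self_prob and expected_duration are inconsistent: "
                f"p={self.self_prob} vs 1 - 1/d={1.0 - 1.0 / self.expected_duration}"
            )
        if self.kind == NORMAL:
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValidationError("normal states need mu and sigma > 0")
        else:
            if self.lo is None or self.hi is None or self.lo >= self.hi:
                raise ValidationError("uniform states need lo < hi")

    def log_density(self, x: float) -> float:
        return emission_logdensity(self, x)

    def log_density_array(self, xs: np.ndarray) -> np.ndarray:
        """Vectorized log emission density; missing (NaN) entries get 0."""
        xs = np.asarray(xs, dtype=float)
        missing = np.isnan(xs)
        if self.kind == NORMAL:
            z = (np.where(missing, self.mu, xs) - self.mu) / self.sigma
            out = -math.log(self.sigma) - _LOG_SQRT_2PI - 0.5 * z * z
        else:
            inside = (xs >= self.lo) & (xs <= self.hi)
            out = np.where(inside, -math.log(self.hi - self.lo), -math.inf)
        return np.where(missing, 0.0, out)


def emission_logdensity(state: HmmState, x: float | None) -> float:
    """Log emission density at ``x``; a missing observation contributes
    log(1) = 0 (marginalized out)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return 0.0
    if state.kind == NORMAL:
        z = (x - state.mu) / state.sigma
        return -math.log(state.sigma) - _LOG_SQRT_2PI - 0.5 * z * z
    if state.lo <= x <= state.hi:
        return -math.log(state.hi - state.lo)
    return -math.inf


def _duration_to_self_prob(d: float) -> float:
    return 1.0 - 1.0 / d


def box_to_state(box: Timebox) -> HmmState:
    """Translate one timebox into a normal-emission state.

    mean = box vertical midpoint; sigma = quarter of the box height;
    expected duration = box width; self_prob = 1 - 1/duration.
    """
    d = box.duration
    return HmmState(
        kind=NORMAL,
        expected_duration=d,
        self_prob=_duration_to_self_prob(d),
        mu=0.5 * (box.x_lo + box.x_hi),
        sigma=0.25 * (box.x_hi - box.x_lo),
    )


@dataclass(frozen=True)
class LinearHMM:
    """A left-to-right chain of states with self- and successor-transitions."""

    states: tuple[HmmState, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 1:
            raise ValidationError("a LinearHMM needs at least one state")
        for a, b in zip(self.states, self.states[1:]):
            if a.kind == UNIFORM and b.kind == UNIFORM:
                raise ValidationError("two adjacent uniform states are not allowed")

    @property
    def K(self) -> int:
        return len(self.states)

    def total_expected_duration(self) -> float:
        return sum(s.expected_duration for s in self.states)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for s in self.states:
            entry: dict = {
                "kind": s.kind,
                "expected_duration": s.expected_duration,
                "self_prob": s.self_prob,
            }
            if s.kind == NORMAL:
                entry.update(mu=s.mu, sigma=s.sigma)
            else:
                entry.update(lo=s.lo, hi=s.hi)
            out.append(entry)
        return {"states": out}

    @classmethod
    def from_dict(cls, doc: dict) -> "LinearHMM":
        states = tuple(HmmState(**entry) for entry in doc["states"])
        return cls(states=states)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LinearHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _normalize_durations(raw: Sequence[float], T: float, tol: float = 1e-9) -> np.ndarray:
    """Rescale durations to sum to ``T`` with a floor of 1.0 per state.

    A single global rescale can push short states below the 1.0 floor; those
    are clamped to 1.0 and the remaining budget is redistributed over the
    free states, iterating until stable.
    """
    d = np.asarray(raw, dtype=float).copy()
    k = len(d)
    if k > T + tol:
        raise CompileError(f"{k} states cannot fit {T} time points at >= 1.0 duration each")
    free = np.ones(k, dtype=bool)
    while free.any():
        budget = T - float((~free).sum())  # clamped states hold 1.0 each
        if budget <= 0:
            raise CompileError("duration normalization ran out of budget")
        scale = budget / d[free].sum()
        scaled = d[free] * scale
        low = scaled < 1.0 - tol
        if low.any():
            idx = np.flatnonzero(free)[low]
            d[idx] = 1.0
            free[idx] = False
        else:
            d[free] = np.maximum(scaled, 1.0)
            break
    if abs(d.sum() - T) > tol * max(T, 1.0):
        raise CompileError(f"duration normalization failed: sum {d.sum()} != {T}")
    return d


def compile_hmm(
    spec: QuerySpec,
    tcs: TimeCourseSet,
    *,
    support_pad: float = 0.0,
) -> LinearHMM:
    """Compile an ordered probabilistic timebox query into a LinearHMM.

    Each box yields a normal state; positive time gaps between consecutive
    boxes, and margins before the first / after the last box, yield uniform
    waiting states supported on the data's value range (optionally widened by
    ``support_pad`` on each side). Durations are then normalized to sum to
    ``T`` and self-transition probabilities recomputed.
    """
    if spec.mode != PROBABILISTIC:
        raise CompileError(f"compile_hmm requires mode={PROBABILISTIC!r}, got {spec.mode!r}")
    spec = validate_query(spec, tcs.n_times)
    T = float(tcs.n_times)
    if support_pad < 0:
        raise CompileError("support_pad must be >= 0")
    lo, hi = tcs.data_range()
    lo -= support_pad
    hi += support_pad
    if hi <= lo:  # constant data: give the uniform a token support
        lo -= 0.5
        hi += 0.5

    kinds: list[str] = []
    params: list[tuple[float, float]] = []  # (mu, sigma) or (lo, hi)
    raw: list[float] = []

    def add_uniform(duration: float) -> None:
        kinds.append(UNIFORM)
        params.append((lo, hi))
        raw.append(max(duration, 1.0))  # a state must emit at least once

    boxes = spec.boxes
    if boxes[0].t_lo > 1.0:
        add_uniform(boxes[0].t_lo - 1.0)
    for j, b in enumerate(boxes):
        kinds.append(NORMAL)
        params.append((0.5 * (b.x_lo + b.x_hi), 0.25 * (b.x_hi - b.x_lo)))
        raw.append(b.duration)
        if j + 1 < len(boxes):
            gap = boxes[j + 1].t_lo - b.t_hi
            if gap > 0:
                add_uniform(gap)
    if boxes[-1].t_hi < T:
        add_uniform(T - boxes[-1].t_hi)

    durations = _normalize_durations(raw, T)
    states = []
    for kind, (a, b), d in zip(kinds, params, durations):
        d = float(d)
        p = _duration_to_self_prob(d)
        if kind == NORMAL:
            states.append(HmmState(NORMAL, d, p, mu=a, sigma=b))
        else:
            states.append(HmmState(UNIFORM, d, p, lo=a, hi=b))
    return LinearHMM(states=tuple(states))


def forward_loglik(hmm: LinearHMM, values: np.ndarray) -> float:
    """Log-likelihood of one course under the chain, forward algorithm.

    Paths start in state 1 and must occupy state ``K`` at the final time
    point; courses that cannot reach the end state score ``-inf``. Missing
    observations contribute an emission factor of 1. O(K*T) time, all in log
    space (log-sum-exp), so no underflow for any realistic ``T``.
    """
    global _FORWARD_EVALS
    _FORWARD_EVALS += 1
    values = np.asarray(values, dtype=float)
    T = values.shape[0]
    if T < 1:
        raise ValidationError("cannot score an empty course")
    K = hmm.K
    log_e = np.stack([s.log_density_array(values) for s in hmm.states])  # K x T
    p = np.array([s.self_prob for s in hmm.states])
    with np.errstate(divide="ignore"):
        log_self = np.log(p)
    log_adv = np.log1p(-p)
    alpha = np.full(K, -np.inf)
    alpha[0] = log_e[0, 0]
    for t in range(1, T):
        stay = alpha + log_self
        move = np.full(K, -np.inf)
        move[1:] = alpha[:-1] + log_adv[:-1]
        alpha = log_e[:, t] + np.logaddexp(stay, move)
    return float(alpha[-1])
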