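"""Independent oracles used to cross-check the package implementation.

These deliberately avoid the package's own code paths: emissions come from
scipy.stats, likelihoods from exhaustive path enumeration in plain
probability space, and deterministic membership from a naive double loop.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def oracle_emission_pdf(state, x: float) -> float:
    """Emission density via scipy.stats; missing observations contribute 1."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return 1.0
    if state.kind == "normal":
        return float(stats.norm.pdf(x, loc=state.mu, scale=state.sigma))
    return float(stats.uniform.pdf(x, loc=state.lo, scale=state.hi - state.lo))


def forward_by_enumeration(hmm, values) -> float:
    """log P(o | model) by summing over every monotone state path 1..K that
    ends in the final state, in plain probability space."""
    values = np.asarray(values, dtype=float)
    T = len(values)
    K = len(hmm.states)
    if K > T:
        return -math.inf
    total = 0.0
    # A path is determined by the K-1 time steps at which it advances.
    for advances in itertools.combinations(range(1, T), K - 1):
        state_at = np.zeros(T, dtype=int)
        for a in advances:
            state_at[a:] += 1
        prob = 1.0
        for t in range(T):
            s = hmm.states[state_at[t]]
            prob *= oracle_emission_pdf(s, float(values[t]))
            if t < T - 1:
                if state_at[t + 1] == state_at[t]:
                    prob *= s.self_prob
                else:
                    prob *= 1.0 - s.self_prob
        total += prob
    return math.log(total) if total > 0.0 else -math.inf


def brute_force_members(boxes, ids, values_matrix) -> list[str]:
    """Deterministic membership by a naive (course, time point) double loop."""
    T = values_matrix.shape[1]
    out = []
    for ident, row in zip(ids, values_matrix):
        ok = True
        for b in boxes:
            for t in range(1, T + 1):
                if b.t_lo <= t <= b.t_hi:
                    v = row[t - 1]
                    if math.isnan(v) or v < b.x_lo or v > b.x_hi:
                        ok = False
        if ok:
            out.append(ident)
    return out


def random_linear_hmm(rng: np.random.Generator, max_states: int = 4):
    """A random valid chain (no two adjacent uniform states)."""
    from ptimebox.hmm import NORMAL, UNIFORM, HmmState, LinearHMM

    K = int(rng.integers(1, max_states + 1))
    states = []
    prev_uniform = False
    for _ in range(K):
        kind = NORMAL if prev_uniform else (NORMAL if rng.random() < 0.6 else UNIFORM)
        d = float(rng.uniform(1.0, 4.0))
        p = 1.0 - 1.0 / d
        if kind == NORMAL:
            states.append(
                HmmState(NORMAL, d, p, mu=float(rng.normal(0, 2)), sigma=float(rng.uniform(0.3, 2)))
            )
            prev_uniform = False
        else:
            lo = float(rng.normal(-3, 1))
            states.append(HmmState(UNIFORM, d, p, lo=lo, hi=lo + float(rng.uniform(1, 6))))
            prev_uniform = True
    return LinearHMM(states=tuple(states))


def random_course(rng: np.random.Generator, T: int, missing_prob: float = 0.1) -> np.ndarray:
    values = rng.normal(0.0, 2.5, size=T)
    if missing_prob > 0:
        mask = rng.random(T) < missing_prob
        if mask.all():  # keep at least one observation
            mask[int(rng.integers(T))] = False
        values[mask] = np.nan
    return values
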