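"""Synthetic time-course generator for testing and demonstrations.

Signal courses follow a piecewise-constant template (a sequence of
(length, level) segments) distorted by the phenomena that break deterministic
box queries on real data: an integer phase shift, per-segment speed jitter,
i.i.d. Gaussian noise, and sporadic large-magnitude outliers. Background
courses are pure Gaussian noise around the template mean. The generator is
fully deterministic for a fixed seed.

``template_query`` builds the matched ground-truth query for a config: one
box per segment, centered on the segment level, spanning the segment's time
range, with abutting edges at segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .timebox import PROBABILISTIC, QuerySpec, Timebox
from .timecourse import TimeCourseSet

__all__ = ["GeneratorConfig", "generate", "template_query", "write_truth", "read_truth"]

SIGNAL = "signal"
BACKGROUND = "background"


@dataclass(frozen=True)
class GeneratorConfig:
    n_signal: int = 30
    n_background: int = 70
    T: int = 8
    segment_means: tuple[tuple[int, float], ...] = ((4, 2.0), (4, -2.0))
    noise_sd: float = 0.5
    outlier_prob: float = 0.05
    outlier_magnitude: float = 3.0
    max_shift: int = 1
    speed_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "segment_means", tuple((int(l), float(v)) for l, v in self.segment_means)
        )
        if self.n_signal < 0 or self.n_background < 0 or self.n_signal + self.n_background < 1:
            raise ValidationError("need at least one course")
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if any(l < 1 for l, _ in self.segment_means):
            raise ValidationError("segment lengths must be >= 1")
        if sum(l for l, _ in self.segment_means) != self.T:
            raise ValidationError(
                f"segment lengths sum to {sum(l for l, _ in self.segment_means)}, expected T={self.T}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValidationError("outlier_prob must lie in [0, 1]")
        if self.max_shift < 0 or self.speed_jitter < 0:
            raise ValidationError("max_shift and speed_jitter must be >= 0")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.segment_means)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l for l, _ in self.segment_means)


def _template_series(lengths: tuple[int, ...], levels: tuple[float, ...], T: int) -> np.ndarray:
    series = np.repeat(levels, lengths).astype(float)
    if len(series) >= T:
        return series[:T]
    return np.concatenate([series, np.full(T - len(series), levels[-1])])


def _jittered_lengths(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[int, ...]:
    if cfg.speed_jitter == 0 or len(cfg.lengths) == 1:
        return cfg.lengths
    for _ in range(200):  # redraw until every segment keeps positive length
        deltas = rng.integers(-cfg.speed_jitter, cfg.speed_jitter + 1, size=len(cfg.lengths))
        lengths = tuple(int(l + d) for l, d in zip(cfg.lengths, deltas))
        if all(l >= 1 for l in lengths):
            return lengths
    return cfg.lengths


def _shift(series: np.ndarray, s: int) -> np.ndarray:
    """Shift in time with edge padding; s > 0 delays the pattern."""
    if s == 0:
        return series
    if s > 0:
        return np.concatenate([np.full(s, series[0]), series[:-s]])
    return np.concatenate([series[-s:], np.full(-s, series[-1])])


def generate(cfg: GeneratorConfig) -> tuple[TimeCourseSet, dict[str, str]]:
    """Draw a synthetic TimeCourseSet plus per-id truth labels.

    Returns ``(tcs, labels)`` where ``labels[id]`` is ``"signal"`` or
    ``"background"``. Signal courses precede background courses.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.T
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: dict[str, str] = {}

    for i in range(cfg.n_signal):
        lengths = _jittered_lengths(cfg, rng)
        series = _template_series(lengths, cfg.levels, T)
        if cfg.max_shift > 0:
            series = _shift(series, int(rng.integers(-cfg.max_shift, cfg.max_shift + 1)))
        series = series + rng.normal(0.0, cfg.noise_sd, size=T)
        if cfg.outlier_prob > 0:
            hit = rng.random(T) < cfg.outlier_prob
            signs = rng.choice([-1.0, 1.0], size=T)
            series = series + hit * signs * cfg.outlier_magnitude
        ident = f"sig_{i:04d}"
        ids.append(ident)
        labels[ident] = SIGNAL
        rows.append(series)

    levels = np.array(cfg.levels)
    bg_mean = float(_template_series(cfg.lengths, cfg.levels, T).mean())
    bg_sd = max(cfg.noise_sd, float(levels.max() - levels.min()), 1e-6)
    for i in range(cfg.n_background):
        ident = f"bg_{i:04d}"
        ids.append(ident)
        labels[ident] = BACKGROUND
        rows.append(rng.normal(bg_mean, bg_sd, size=T))

    tcs = TimeCourseSet(ids=ids, times=list(range(1, T + 1)), values=np.vstack(rows))
    return tcs, labels


def template_query(
    cfg: GeneratorConfig,
    box_halfheight: float,
    *,
    mode: str = PROBABILISTIC,
    m: int | None = None,
) -> QuerySpec:
    """The ground-truth query for a config: one box per template segment.

    Boxes abut at segment boundaries (edge at the midpoint between the last
    time point of one segment and the first of the next), are centered on the
    segment level and 2*box_halfheight tall. ``m`` defaults to ``n_signal``.
    """
    if box_halfheight <= 0:
        raise ValidationError("box_halfheight must be > 0")
    edges = np.cumsum(cfg.lengths)
    boxes = []
    for j, (length, level) in enumerate(cfg.segment_means):
        t_lo = 1.0 if j == 0 else float(edges[j - 1]) + 0.5
        t_hi = float(cfg.T) if j == len(cfg.segment_means) - 1 else float(edges[j]) + 0.5
        boxes.append(
            Timebox(t_lo=t_lo, t_hi=t_hi, x_lo=level - box_halfheight, x_hi=level + box_halfheight)
        )
    return QuerySpec(
        boxes=tuple(boxes),
        mode=mode,
        stringency_m=(m if m is not None else cfg.n_signal) if mode == PROBABILISTIC else None,
    )


def write_truth(labels: dict[str, str], path: str | Path) -> None:
    lines = ["id\tlabel"] + [f"{ident}\t{label}" for ident, label in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> dict[str, str]:
    lines = Path(path).read_text().splitlines()
    out: dict[str, str] = {}
    for line in lines[1:]:
        ident, label = line.split("\t")
        out[ident] = label
    return out
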