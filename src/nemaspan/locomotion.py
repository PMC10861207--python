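"""Locomotion-derived frailty metrics from worm centroid trajectories.

Converts time-stamped 2-D centroid tracks into the behavioral readouts
used for healthspan phenotyping: instantaneous crawl speeds, directional
shifts (reversal events, which increase with aging and proteotoxic
neurodegeneration), a paralysis call, and the group-level direction
rescue index that normalizes treated shift counts against the untreated
control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Track",
    "TrackMetrics",
    "ParalysisRule",
    "RescueIndexResult",
    "instantaneous_speeds",
    "count_directional_shifts",
    "classify_paralysis",
    "direction_rescue_index",
    "fraction_not_paralyzed",
    "compute_track_metrics",
]

#: default noise floor below which a displacement does not define a heading (mm)
DEFAULT_MIN_STEP = 0.005


@dataclass(frozen=True)
class Track:
    """Centroid trajectory of one worm: strictly increasing timestamps (s)
    and x/y positions (mm), with the nominal frame rate as metadata."""

    worm_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.worm_id!r}: timestamps must be strictly increasing")


@dataclass(frozen=True)
class ParalysisRule:
    """A worm is paralyzed when more than ``slow_fraction_threshold`` of its
    instantaneous speeds fall below ``speed_threshold`` (strict '>' by
    default, so exactly 80% slow frames leaves the worm motile)."""

    speed_threshold: float = 0.015  # mm/s
    slow_fraction_threshold: float = 0.80
    strict: bool = True

    def __post_init__(self):
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be positive")
        if not 0 < self.slow_fraction_threshold < 1:
            raise ValueError("slow_fraction_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class TrackMetrics:
    worm_id: str
    speeds: np.ndarray
    mean_speed: float
    n_direction_shifts: int
    paralyzed: bool
    frac_slow: float


@dataclass(frozen=True)
class RescueIndexResult:
    """Direction rescue index = N_below-mean / N_total: the fraction of
    treated worms whose shift count falls strictly below the untreated
    control group's mean."""

    control_mean: float
    n_below: int
    n_total: int
    index: float


def instantaneous_speeds(track: Track, smooth: bool = False) -> np.ndarray:
    """Per-interval speeds: Euclidean displacement over elapsed time.

    ``smooth=True`` applies a window-3 rolling median to damp tracker
    jitter; off by default so raw and smoothed pipelines are both
    available.
    """
    if len(track.t) < 2:
        raise ValueError("at least two samples required")
    dt = np.diff(track.t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps")
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    speeds = disp / dt
    if smooth and len(speeds) >= 3:
        pad = np.concatenate([speeds[:1], speeds, speeds[-1:]])
        speeds = np.array([np.median(pad[i:i + 3]) for i in range(len(speeds))])
    return speeds


def count_directional_shifts(
    track: Track,
    angle_threshold: float = 90.0,
    min_step: float = DEFAULT_MIN_STEP,
) -> int:
    """Count heading changes sharper than ``angle_threshold`` degrees.

    Headings are taken from consecutive displacement vectors; steps
    shorter than ``min_step`` (the noise floor) neither define a heading
    nor reset the previous one, so a pause does not mask a reversal.
    """
    if len(track.t) < 3:
        raise ValueError("at least three samples required")
    dx, dy = np.diff(track.x), np.diff(track.y)
    lengths = np.hypot(dx, dy)
    cos_thresh = np.cos(np.radians(angle_threshold))

    shifts = 0
    prev = None
    for i in range(len(dx)):
        if lengths[i] < min_step:
            continue
        cur = (dx[i] / lengths[i], dy[i] / lengths[i])
        if prev is not None:
            if prev[0] * cur[0] + prev[1] * cur[1] < cos_thresh:
                shifts += 1
        prev = cur
    return shifts


def classify_paralysis(speeds, rule: ParalysisRule = ParalysisRule()) -> tuple[bool, float]:
    """Apply the paralysis rule to a vector of instantaneous speeds."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("speeds must be non-empty")
    frac_slow = float(np.mean(speeds < rule.speed_threshold))
    if rule.strict:
        paralyzed = frac_slow > rule.slow_fraction_threshold
    else:
        paralyzed = frac_slow >= rule.slow_fraction_threshold
    return bool(paralyzed), frac_slow


def direction_rescue_index(treated_shifts, control_shifts) -> RescueIndexResult:
    """Fraction of treated worms with shift counts strictly below the
    control group's mean shift count."""
    treated = np.asarray(treated_shifts, dtype=float)
    control = np.asarray(control_shifts, dtype=float)
    if treated.size == 0:
        raise ValueError("treated group must be non-empty")
    if control.size == 0:
        raise ValueError("control group must be non-empty")
    control_mean = float(np.mean(control))
    n_below = int(np.sum(treated < control_mean))
    return RescueIndexResult(
        control_mean=control_mean, n_below=n_below,
        n_total=treated.size, index=n_below / treated.size,
    )


def fraction_not_paralyzed(metrics: list[TrackMetrics]) -> float:
    """1 - paralyzed count / total over a list of per-worm metrics."""
    if not metrics:
        raise ValueError("at least one worm required")
    return 1.0 - sum(m.paralyzed for m in metrics) / len(metrics)


def compute_track_metrics(
    track: Track,
    rule: ParalysisRule = ParalysisRule(),
    angle_threshold: float = 90.0,
    min_step: float = DEFAULT_MIN_STEP,
    smooth: bool = False,
) -> TrackMetrics:
    """All per-worm metrics in one pass over a track."""
    speeds = instantaneous_speeds(track, smooth=smooth)
    paralyzed, frac_slow = classify_paralysis(speeds, rule)
    return TrackMetrics(
        worm_id=track.worm_id,
        speeds=speeds,
        mean_speed=float(np.mean(speeds)),
        n_direction_shifts=count_directional_shifts(track, angle_threshold, min_step),
        paralyzed=paralyzed,
        frac_slow=frac_slow,
    )
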