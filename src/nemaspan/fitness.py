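"""Composite "total fitness" scoring over five locomotory/size metrics.

Each treated group is normalized metric-by-metric against the control
(ratios M_t / M_c for body size, crawl speed, direction score, swim
speed and thrash frequency) and the five ratios are averaged into a
single total-fitness score; the control scores 1.0 by construction.
All five metrics are oriented so that larger means fitter — raw
directional-shift counts rise with frailty, so the panel stores a
rescue-oriented direction score (direction rescue index, or an inverted
shift ratio) rather than the raw count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "METRIC_ORDER",
    "FitnessPanel",
    "TotalFitnessResult",
    "normalize_metrics",
    "total_fitness",
    "score_panel",
    "radar_export",
]

METRIC_ORDER = (
    "body_size",
    "crawl_speed",
    "direction_index",
    "swim_speed",
    "thrash_freq",
)


@dataclass(frozen=True)
class FitnessPanel:
    """Per-group values of the five fitness metrics.

    ``metrics`` maps each name in :data:`METRIC_ORDER` to a positive
    scalar; ``n_worms`` optionally records per-metric sample sizes.
    Extra keys are carried along but excluded from total-fitness scoring.
    """

    group: str
    metrics: dict[str, float]
    n_worms: dict[str, int] = field(default_factory=dict)
    direction_mode: str = "rescue_index"  # or "inverse_shift_ratio"

    def __post_init__(self):
        missing = [m for m in METRIC_ORDER if m not in self.metrics]
        if missing:
            raise ValueError(f"panel {self.group!r} missing metrics: {missing}")


@dataclass(frozen=True)
class TotalFitnessResult:
    group: str
    ratios: dict[str, float]
    total_fitness: float
    baseline: float = 1.0


def normalize_metrics(treated: FitnessPanel, control: FitnessPanel) -> dict[str, float]:
    """Elementwise treated/control ratios in fixed metric order."""
    ratios = {}
    for m in METRIC_ORDER:
        c = control.metrics[m]
        if c <= 0:
            raise ValueError(f"control metric {m!r} must be positive, got {c}")
        ratios[m] = treated.metrics[m] / c
    return ratios


def total_fitness(ratios) -> float:
    """Arithmetic mean of the five treated/control ratios.

    Accepts the dict from :func:`normalize_metrics` or any sequence of
    exactly five ratios.
    """
    vals = list(ratios.values()) if isinstance(ratios, dict) else list(ratios)
    if len(vals) != len(METRIC_ORDER):
        raise ValueError(f"expected {len(METRIC_ORDER)} ratios, got {len(vals)}")
    return sum(float(v) for v in vals) / len(vals)


def score_panel(treated: FitnessPanel, control: FitnessPanel) -> TotalFitnessResult:
    """Normalize a treated panel against control and score it."""
    ratios = normalize_metrics(treated, control)
    return TotalFitnessResult(group=treated.group, ratios=ratios,
                              total_fitness=total_fitness(ratios))


def radar_export(panels: list[FitnessPanel], control: FitnessPanel) -> pd.DataFrame:
    """Long-format (group, metric, ratio) table for radar plotting."""
    rows = []
    for panel in panels:
        for m, r in normalize_metrics(panel, control).items():
            rows.append({"group": panel.group, "metric": m, "ratio": r})
    return pd.DataFrame(rows, columns=["group", "metric", "ratio"])
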