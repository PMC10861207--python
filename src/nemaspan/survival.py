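"""Survival-resilience statistics over Kaplan-Meier curves.

The central quantity is the S/L ratio: the area under the survival curve
(AUC) of a stress-exposed cohort divided by the AUC of an unstressed
control cohort followed over its full life span.  Because the AUC of a
fully observed survival curve equals mean survival time, S/L compares the
cumulative "stress span" to the normal life span: S/L < 1 marks a loss of
survival resilience (curve shifted left), S/L > 1 a gain.

The treated variant replaces the numerator with the AUC of the stressed
cohort that received a candidate protective treatment, so treatments are
scored against the same life-span denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "EventTable",
    "SurvivalCurve",
    "ResilienceResult",
    "DoseStudyRecord",
    "km_estimate",
    "curve_auc",
    "s_over_l",
    "delta_auc_pct",
    "logrank_test",
    "dose_resilience_profile",
]

#: tolerance band around S/L = 1 inside which a ratio is called "neutral"
TIE_TOL = 1e-9


@dataclass(frozen=True)
class EventTable:
    """Subject-level survival data for one or more experimental groups.

    Parameters
    ----------
    subject_id : array-like of str
        Opaque per-animal labels.
    group : array-like of str
        Condition label for each subject (e.g. ``"control"``,
        ``"paraquat"``, ``"paraquat+peptide"``).
    time : array-like of float
        Nonnegative death or censoring time.  All groups being compared
        must share one unit (hours or days); the unit is recorded in
        ``time_unit`` and checked when curves are combined.
    event : array-like of int
        1 if death was observed at ``time``, 0 if the subject was censored.
    time_unit : str
        Declared time unit, metadata only ("days" by default).
    """

    subject_id: np.ndarray
    group: np.ndarray
    time: np.ndarray
    event: np.ndarray
    time_unit: str = "days"

    def __post_init__(self):
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id, dtype=object))
        object.__setattr__(self, "group", np.asarray(self.group, dtype=object))
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        n = len(self.subject_id)
        if not (len(self.group) == len(self.time) == len(self.event) == n):
            raise ValueError("EventTable columns must have equal length")
        if n == 0:
            raise ValueError("EventTable must contain at least one subject")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("times must be finite")
        if np.any(self.time < 0):
            raise ValueError("times must be nonnegative")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def restrict(self, group: str) -> "EventTable":
        """Return the sub-table for one group."""
        mask = self.group == group
        if not mask.any():
            raise ValueError(f"group {group!r} not present in table")
        return EventTable(
            self.subject_id[mask], self.group[mask], self.time[mask],
            self.event[mask], self.time_unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_id, "group": self.group,
             "time": self.time, "event": self.event}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_unit: str = "days") -> "EventTable":
        return cls(
            df["subject_id"].to_numpy(), df["group"].to_numpy(),
            df["time"].to_numpy(), df["event"].to_numpy(), time_unit,
        )


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function.

    ``surv[i]`` is S(t) for ``times[i] <= t < times[i+1]``; before the
    first event time S = 1.  ``fully_observed`` is True iff the curve
    reaches zero at or before ``t_end`` (no residual censored mass).
    """

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: np.ndarray
    t_end: float
    fully_observed: bool
    time_unit: str = "days"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "surv", np.asarray(self.surv, dtype=float))
        object.__setattr__(self, "n_at_risk", np.asarray(self.n_at_risk, dtype=int))
        t, s = self.times, self.surv
        if len(t) != len(s) or len(t) != len(self.n_at_risk):
            raise ValueError("times, surv, n_at_risk must align")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(s) and (np.any(s < -1e-12) or np.any(s > 1 + 1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if len(s) and np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def evaluate(self, t: float) -> float:
        """S(t) with right-continuous step convention."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


@dataclass(frozen=True)
class ResilienceResult:
    """S/L point estimate with optional bootstrap interval."""

    auc_stress: float
    auc_life: float
    s_over_l: float
    classification: str
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class DoseStudyRecord:
    """One literature study: mean stress span and mean life span at a dose.

    When only mean spans (not full curves) are reported, S/L reduces to
    mean_stress / mean_lifespan because the AUC of a fully observed
    survival curve equals mean survival.
    """

    study_id: str
    dose: float
    stress_mean_span: float
    control_mean_lifespan: float
    s_over_l: float = field(init=False)

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.control_mean_lifespan <= 0:
            raise ValueError(
                f"study {self.study_id!r}: control mean lifespan must be > 0"
            )
        object.__setattr__(
            self, "s_over_l", self.stress_mean_span / self.control_mean_lifespan
        )


def km_estimate(events: EventTable) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate for a single-group table.

    Ties between deaths and censorings at the same time are resolved
    deaths-first: a subject censored at t is still at risk for a death
    at t.  The returned curve records risk-set sizes at each distinct
    event time and whether survival reached zero within follow-up.
    """
    if len(set(events.groups)) > 1:
        raise ValueError("km_estimate expects a single-group table; use restrict()")
    t, d = events.time, events.event
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = len(t)

    event_times = np.unique(t[d == 1])
    surv_vals, risk_sizes = [], []
    s = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))  # deaths-first: censored-at-et counted at risk
        deaths = int(np.sum((t == et) & (d == 1)))
        s *= 1.0 - deaths / at_risk
        surv_vals.append(s)
        risk_sizes.append(at_risk)

    t_end = float(t[-1])
    fully = bool(len(surv_vals) and surv_vals[-1] <= 1e-12)
    return SurvivalCurve(
        times=np.asarray(event_times, dtype=float),
        surv=np.asarray(surv_vals, dtype=float),
        n_at_risk=np.asarray(risk_sizes, dtype=int),
        t_end=t_end,
        fully_observed=fully,
        time_unit=events.time_unit,
    )


def curve_auc(curve: SurvivalCurve, t_max: float | None = None) -> float:
    """Area under a KM step curve by exact rectangle integration.

    Integrates S(t) from 0 to ``min(t_max, effective_end)``, where the
    effective end is the time survival reaches zero for fully observed
    curves, and the last observed time otherwise (restricted-mean
    convention).  Rectangle sums are exact for step functions.
    """
    if t_max is not None and t_max < 0:
        raise ValueError("t_max must be nonnegative")
    if curve.fully_observed:
        end = float(curve.times[np.nonzero(curve.surv <= 1e-12)[0][0]])
    else:
        end = curve.t_end
    if t_max is not None:
        end = min(end, t_max)
    if end <= 0:
        return 0.0

    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for ti, si in zip(curve.times, curve.surv):
        if ti >= end:
            break
        area += prev_s * (ti - prev_t)
        prev_t, prev_s = ti, si
    area += prev_s * (end - prev_t)
    return float(area)


def _classify(ratio: float, tie_tol: float = TIE_TOL) -> str:
    if ratio < 1.0 - tie_tol:
        return "loss"
    if ratio > 1.0 + tie_tol:
        return "gain"
    return "neutral"


def s_over_l(
    stress: SurvivalCurve,
    control_lifespan: SurvivalCurve,
    n_boot: int = 1000,
    seed: int | None = None,
    source_events: tuple[EventTable, EventTable] | None = None,
) -> ResilienceResult:
    """Survival resilience: AUC(stress span) / AUC(life span).

    A percentile bootstrap CI is attached when the subject-level tables
    behind the two curves are supplied: subjects are resampled with
    replacement within each group and the ratio recomputed per replicate.
    Without ``source_events`` the CI fields are left empty.
    """
    if stress.time_unit != control_lifespan.time_unit:
        raise ValueError(
            f"time-unit mismatch: {stress.time_unit!r} vs {control_lifespan.time_unit!r}"
        )
    auc_s = curve_auc(stress)
    auc_l = curve_auc(control_lifespan)
    if auc_l <= 0:
        raise ValueError("control life-span AUC must be positive")
    ratio = auc_s / auc_l

    ci_low = ci_high = None
    used_boot = 0
    if source_events is not None and n_boot > 0:
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        ev_s, ev_c = source_events
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = _resampled_ratio(ev_s, ev_c, rng)
        ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
        ci_low, ci_high = float(ci_low), float(ci_high)
        used_boot = n_boot

    return ResilienceResult(
        auc_stress=auc_s, auc_life=auc_l, s_over_l=ratio,
        classification=_classify(ratio),
        ci_low=ci_low, ci_high=ci_high, n_boot=used_boot, seed=seed,
    )


def _resampled_ratio(ev_s: EventTable, ev_c: EventTable, rng) -> float:
    def resample(ev: EventTable) -> EventTable:
        idx = rng.integers(0, len(ev), size=len(ev))
        return EventTable(ev.subject_id[idx], ev.group[idx], ev.time[idx],
                          ev.event[idx], ev.time_unit)

    num = curve_auc(km_estimate(resample(ev_s)))
    den = curve_auc(km_estimate(resample(ev_c)))
    return num / den if den > 0 else np.nan


def delta_auc_pct(treated, control) -> float:
    """Relative total survival gain, dAUC% = 100 (AUC_t - AUC_c) / AUC_c.

    Accepts either ``SurvivalCurve`` objects (AUCs are computed) or bare
    scalar AUC values: when two resilience ratios share the same life-span
    denominator, their percent change equals the percent change of the
    underlying AUCs, so printed S/L pairs can be fed in directly.
    """
    auc_t = curve_auc(treated) if isinstance(treated, SurvivalCurve) else float(treated)
    auc_c = curve_auc(control) if isinstance(control, SurvivalCurve) else float(control)
    if auc_c <= 0:
        raise ValueError("control AUC must be positive")
    return 100.0 * (auc_t - auc_c) / auc_c


def logrank_test(g1: EventTable, g2: EventTable) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test: chi-square statistic, p-value.

    Observed-minus-expected deaths over pooled risk sets, 1 degree of
    freedom, no continuity correction.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    if g1.event.sum() + g2.event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(g1.time, g2.time, event_observed_A=g1.event,
                      event_observed_B=g2.event)
    return float(res.test_statistic), float(res.p_value)


def dose_resilience_profile(
    records: list[DoseStudyRecord], dose_bins: np.ndarray
) -> pd.DataFrame:
    """Per-dose-bin summary of literature S/L ratios.

    Bins are half-open ``[lo, hi)`` except the last, which is closed.
    Each record is classified loss (S/L < 1) or gain (S/L >= 1, the
    maintain-or-promote convention).  Returns one row per non-empty bin
    with median, quartiles and loss/gain counts.
    """
    if not records:
        raise ValueError("at least one record required")
    edges = np.asarray(dose_bins, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("dose_bins must be increasing with >= 2 edges")
    doses = np.array([r.dose for r in records])
    if doses.min() < edges[0] or doses.max() > edges[-1]:
        raise ValueError("bins do not cover the observed dose range")

    ratios = np.array([r.s_over_l for r in records])
    which = np.clip(np.searchsorted(edges, doses, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = ratios[which == b]
        if sel.size == 0:
            continue
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1], "n": sel.size,
            "median_sl": float(np.median(sel)),
            "q1_sl": float(np.percentile(sel, 25)),
            "q3_sl": float(np.percentile(sel, 75)),
            "n_loss": int(np.sum(sel < 1.0)),
            "n_gain": int(np.sum(sel >= 1.0)),
        })
    return pd.DataFrame(rows)
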