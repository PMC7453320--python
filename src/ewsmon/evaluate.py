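"""Alert performance against ground-truth early-warning episodes.

Because neither alerts nor clinically documented worsening come with a
natural unit of analysis, the default evaluation partitions each
participant's observation span into consecutive fixed-length windows
(7 days): a window is positive if it overlaps any episode (the whole
prodrome counts - the point of the method is pre-relapse detection), and a
fired alert anywhere in the window claims it.  An episode-level sensitivity
(at least one alert inside the episode, optionally with a lead margin) is
offered as an alternative unit.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

from .engine import AlertRecord
from .simulate import RelapseEvent

__all__ = [
    "EpisodeWindow",
    "EvaluationReport",
    "episodes_from_events",
    "evaluate_alerts",
    "episode_sensitivity",
    "ppv_from_rates",
]

UTC = dt.timezone.utc


@dataclass(frozen=True)
class EpisodeWindow:
    """A ground-truth early-warning episode: [start, end), prodrome through relapse day."""

    participant_id: str
    start: dt.datetime
    end: dt.datetime
    source: str = "simulated"  # or "annotated" (chart-review gold standard)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("episode start must precede end")


@dataclass(frozen=True)
class EvaluationReport:
    unit: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    prevalence: float

    @property
    def n_windows(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def episodes_from_events(events: list[RelapseEvent]) -> list[EpisodeWindow]:
    """Episode = prodrome onset through the end of the relapse day."""
    return [
        EpisodeWindow(
            participant_id=ev.participant_id,
            start=ev.prodrome_start,
            end=ev.relapse_day + dt.timedelta(days=1),
            source="simulated",
        )
        for ev in events
    ]


def _safe_rate(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def evaluate_alerts(
    alerts: list[AlertRecord],
    episodes: list[EpisodeWindow],
    span: tuple[dt.datetime, dt.datetime],
    window_days: int = 7,
    participant_ids: list[str] | None = None,
) -> EvaluationReport:
    """Window-based confusion counts and the derived sensitivity/specificity/PPV.

    ``span`` is the common observation interval ``[start, end)``; every
    participant contributes ``ceil(span / window_days)`` windows, so
    participants with neither alerts nor episodes still supply true
    negatives.  Pass ``participant_ids`` explicitly to include them
    (otherwise the cohort is inferred from the alerts and episodes).
    Undefined rates (zero denominator) come back as NaN, never 0.
    """
    start, end = span
    if start >= end:
        raise ValueError("observation span start must precede end")
    for ep in episodes:
        if not (start <= ep.start and ep.end <= end):
            raise ValueError(
                f"episode for {ep.participant_id} at {ep.start.isoformat()} "
                "falls outside the observation span"
            )
    by_pid_ep: dict[str, list[EpisodeWindow]] = {}
    for ep in sorted(episodes, key=lambda e: (e.participant_id, e.start)):
        prev = by_pid_ep.setdefault(ep.participant_id, [])
        if prev and ep.start < prev[-1].end:
            raise ValueError(f"overlapping episodes for participant {ep.participant_id}")
        prev.append(ep)
    by_pid_alert: dict[str, list[dt.datetime]] = {}
    for a in alerts:
        by_pid_alert.setdefault(a.participant_id, []).append(a.alert_time)

    if participant_ids is None:
        participant_ids = sorted(set(by_pid_ep) | set(by_pid_alert))
    if not participant_ids:
        raise ValueError("no participants to evaluate")

    total_days = (end - start).total_seconds() / 86400
    n_windows = math.ceil(total_days / window_days)
    tp = fp = fn = tn = 0
    for pid in participant_ids:
        eps = by_pid_ep.get(pid, [])
        times = by_pid_alert.get(pid, [])
        for k in range(n_windows):
            w_start = start + dt.timedelta(days=k * window_days)
            w_end = min(start + dt.timedelta(days=(k + 1) * window_days), end)
            positive = any(ep.start < w_end and ep.end > w_start for ep in eps)
            alerted = any(w_start <= t < w_end for t in times)
            if positive and alerted:
                tp += 1
            elif positive:
                fn += 1
            elif alerted:
                fp += 1
            else:
                tn += 1
    return EvaluationReport(
        unit="episode_window",
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_safe_rate(tp, tp + fn),
        specificity=_safe_rate(tn, tn + fp),
        ppv=_safe_rate(tp, tp + fp),
        prevalence=_safe_rate(tp + fn, tp + fp + fn + tn),
    )


def episode_sensitivity(
    alerts: list[AlertRecord],
    episodes: list[EpisodeWindow],
    lead_margin: dt.timedelta = dt.timedelta(0),
) -> float:
    """Fraction of episodes with >= 1 alert in [start - lead_margin, end)."""
    if not episodes:
        return math.nan
    by_pid: dict[str, list[dt.datetime]] = {}
    for a in alerts:
        by_pid.setdefault(a.participant_id, []).append(a.alert_time)
    hit = 0
    for ep in episodes:
        times = by_pid.get(ep.participant_id, [])
        if any(ep.start - lead_margin <= t < ep.end for t in times):
            hit += 1
    return hit / len(episodes)


def ppv_from_rates(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value from sensitivity, specificity, and prevalence.

    The Bayes identity ``PPV = se*pi / (se*pi + (1-sp)*(1-pi))``: a
    consistency check for any reported (sensitivity, specificity, PPV)
    triple once the episode prevalence is known.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    if denom == 0:
        raise ZeroDivisionError("no positive calls at these rates: PPV undefined")
    return sensitivity * prevalence / denom
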