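"""Per-participant and group-level EMA adherence and retention metrics.

Adherence is counted at the prompt level: a completed prompt is one answered
item set.  Classes are strict: acceptable means responding to *more than* a
third of issued prompts, good means more than half.  Retention is defined
operationally as having at least one completed prompt in the final week of
the monitoring period.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from fractions import Fraction

from .symptoms import ObservationStream

__all__ = ["AdherenceSummary", "summarize_adherence", "group_adherence"]

UTC = dt.timezone.utc

ACCEPTABLE_THRESHOLD = Fraction(1, 3)
GOOD_THRESHOLD = Fraction(1, 2)


@dataclass(frozen=True)
class AdherenceSummary:
    participant_id: str
    prompts_issued: int
    prompts_completed: int
    response_rate: float
    adherence_class: str  # "none" | "acceptable" | "good"
    retained_at_end: bool


def summarize_adherence(stream: ObservationStream, study_length_days: int = 84) -> AdherenceSummary:
    """Classify one participant's adherence over the monitoring period."""
    issued = len(stream.prompts)
    if issued == 0:
        raise ValueError(f"participant {stream.participant_id}: zero issued prompts")
    completed = stream.completed_prompts()
    n_completed = len(completed)
    # exact rational comparison so a rate of exactly 1/3 or 1/2 never
    # crosses the strict threshold through floating-point rounding
    rate = Fraction(n_completed, issued)
    if rate > GOOD_THRESHOLD:
        adherence_class = "good"
    elif rate > ACCEPTABLE_THRESHOLD:
        adherence_class = "acceptable"
    else:
        adherence_class = "none"
    start = dt.datetime.combine(stream.study_start, dt.time.min, tzinfo=UTC)
    final_week_start = start + dt.timedelta(days=study_length_days - 7)
    study_end = start + dt.timedelta(days=study_length_days)
    retained = any(final_week_start <= p.prompt_time < study_end for p in completed)
    return AdherenceSummary(
        participant_id=stream.participant_id,
        prompts_issued=issued,
        prompts_completed=n_completed,
        response_rate=float(rate),
        adherence_class=adherence_class,
        retained_at_end=retained,
    )


def group_adherence(summaries: list[AdherenceSummary]) -> dict[str, float]:
    """Cohort proportions per adherence class plus the retention proportion.

    "acceptable" counts everyone above the acceptable threshold, including
    the good adherers, so the acceptable proportion is always >= the good
    proportion.
    """
    if not summaries:
        raise ValueError("no adherence summaries to aggregate")
    n = len(summaries)
    n_good = sum(1 for s in summaries if s.adherence_class == "good")
    n_acceptable = sum(1 for s in summaries if s.adherence_class in ("acceptable", "good"))
    n_retained = sum(1 for s in summaries if s.retained_at_end)
    return {
        "n_participants": n,
        "prop_acceptable": n_acceptable / n,
        "prop_good": n_good / n,
        "prop_none": (n - n_acceptable) / n,
        "prop_retained": n_retained / n,
    }
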