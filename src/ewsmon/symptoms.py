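"""Symptom-item catalogue, EMA prompt records, and the semi-random prompt scheduler.

An ecological momentary assessment (EMA) study issues audio-cued prompts a few
times a day; at each prompt the participant rates a short set of branching
symptom items on an ordinal severity slider.  This module defines the item
catalogue (with parent/child branching), the raw observation records, the
stratified-uniform ("semi-random") prompt scheduler, and a content validator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymptomItem",
    "ItemResponse",
    "PromptRecord",
    "ObservationStream",
    "Catalogue",
    "ScheduleConfigError",
    "BranchingError",
    "generate_schedule",
    "apply_branching",
    "validate_stream",
    "default_catalogue",
]

UTC = dt.timezone.utc

PROMPT_STATUSES = ("completed", "missed", "partial")
DOMAIN_TAGS = ("psychotic", "dysphoric")


class ScheduleConfigError(ValueError):
    """Prompt window / spacing configuration that cannot be satisfied."""


class BranchingError(ValueError):
    """Ratings inconsistent with the catalogue's branching structure."""


@dataclass(frozen=True)
class SymptomItem:
    """One item of the EMA questionnaire.

    Branch children are only presented when the parent's rating reaches
    ``branch_threshold`` (default: anything above the scale minimum).
    """

    item_id: str
    label: str
    domain_tag: str
    branch_parent: str | None = None
    branch_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"domain_tag must be one of {DOMAIN_TAGS}, got {self.domain_tag!r}")


@dataclass(frozen=True)
class ItemResponse:
    """A single rated item at one prompt.

    Ratings live on a fixed ordinal scale (default 1-7, mirroring PANSS item
    scoring).  The instrument is a continuous slider, so non-integer ratings
    are accepted as long as they stay within the scale bounds.
    """

    item_id: str
    rating: float
    timestamp: dt.datetime


@dataclass
class PromptRecord:
    prompt_time: dt.datetime
    status: str
    responses: list[ItemResponse] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in PROMPT_STATUSES:
            raise ValueError(f"status must be one of {PROMPT_STATUSES}, got {self.status!r}")

    def ratings(self) -> dict[str, float]:
        return {r.item_id: r.rating for r in self.responses}


class Catalogue:
    """An ordered set of symptom items with an ordinal rating scale."""

    def __init__(self, items: list[SymptomItem], scale_min: float = 1, scale_max: float = 7):
        if not 12 <= len(items) <= 14:
            # the deployed questionnaires used 12-14 branching items; other
            # sizes are allowed for testing but flagged on validation
            pass
        if scale_min >= scale_max:
            raise ValueError("scale_min must be < scale_max")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in catalogue")
        by_id = {it.item_id: it for it in items}
        for it in items:
            if it.branch_parent is not None and it.branch_parent not in by_id:
                raise ValueError(f"branch_parent {it.branch_parent!r} of {it.item_id!r} not in catalogue")
        self._check_acyclic(by_id)
        self.items = list(items)
        self.by_id = by_id
        self.scale_min = scale_min
        self.scale_max = scale_max

    @staticmethod
    def _check_acyclic(by_id: dict[str, SymptomItem]) -> None:
        for start in by_id:
            seen = set()
            cur: str | None = start
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"branching cycle involving {start!r}")
                seen.add(cur)
                cur = by_id[cur].branch_parent

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def root_items(self) -> list[SymptomItem]:
        return [it for it in self.items if it.branch_parent is None]

    def branch_threshold_of(self, item: SymptomItem) -> float:
        """Minimum parent rating at which a branch child is presented."""
        if item.branch_threshold is not None:
            return item.branch_threshold
        return self.scale_min + 1

    def __len__(self) -> int:
        return len(self.items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalogue):
            return NotImplemented
        return (
            self.items == other.items
            and self.scale_min == other.scale_min
            and self.scale_max == other.scale_max
        )


@dataclass
class ObservationStream:
    """One participant's complete EMA record for the monitoring period."""

    participant_id: str
    catalogue: Catalogue
    prompts: list[PromptRecord]
    study_start: dt.date

    def completed_prompts(self) -> list[PromptRecord]:
        return [p for p in self.prompts if p.status == "completed"]


def generate_schedule(
    n_days: int,
    prompts_per_day: int,
    window: tuple[dt.time, dt.time] = (dt.time(9, 0), dt.time(21, 0)),
    min_gap: dt.timedelta = dt.timedelta(hours=2),
    seed: int | np.random.Generator = 0,
    start_date: dt.date = dt.date(2020, 1, 1),
) -> list[dt.datetime]:
    """Semi-random prompt schedule: one uniform draw per equal time bin.

    Each day's prompting window is split into ``prompts_per_day`` equal bins
    and one instant is drawn uniformly inside each bin; a day whose draws
    violate the ``min_gap`` spacing is redrawn.  This stratified-uniform
    scheme is standard EMA practice: coverage of the whole day is guaranteed
    while prompt times stay unpredictable.

    Returns ``n_days * prompts_per_day`` timezone-aware UTC instants.
    """
    if not 2 <= prompts_per_day <= 4:
        raise ScheduleConfigError("prompts_per_day must be between 2 and 4")
    if n_days < 1:
        raise ScheduleConfigError("n_days must be >= 1")
    w_start = dt.datetime.combine(start_date, window[0], tzinfo=UTC)
    w_end = dt.datetime.combine(start_date, window[1], tzinfo=UTC)
    span = (w_end - w_start).total_seconds()
    if span <= 0:
        raise ScheduleConfigError("window end must be after window start")
    bin_width = span / prompts_per_day
    gap = min_gap.total_seconds()
    if gap > bin_width:
        raise ScheduleConfigError(
            f"min_gap {min_gap} exceeds the bin width ({bin_width / 3600:.2f} h); "
            "shorten the gap, widen the window, or reduce prompts_per_day"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    instants: list[dt.datetime] = []
    for day in range(n_days):
        day_start = dt.datetime.combine(start_date + dt.timedelta(days=day), window[0], tzinfo=UTC)
        for _ in range(10_000):
            offsets = (np.arange(prompts_per_day) + rng.random(prompts_per_day)) * bin_width
            if gap == 0 or np.all(np.diff(offsets) >= gap):
                break
        else:  # pragma: no cover - unreachable when gap <= bin_width
            raise ScheduleConfigError("could not satisfy min_gap; configuration too tight")
        instants.extend(day_start + dt.timedelta(seconds=float(o)) for o in offsets)
    return instants


def apply_branching(
    catalogue: Catalogue, ratings: dict[str, float]
) -> tuple[dict[str, float], list[str]]:
    """Filter a full ratings map down to the items actually presented.

    Returns ``(presented, skipped)``: branch children whose parent rating is
    below the branch threshold are dropped from the map and listed in
    ``skipped`` (skipping encodes symptom absence - it is *not* a minimum
    rating).  A child whose parent was never rated is a branching error.
    """
    missing_roots = [it.item_id for it in catalogue.root_items if it.item_id not in ratings]
    if missing_roots:
        raise BranchingError(f"ratings missing for root items: {missing_roots}")

    for item in catalogue.items:
        if (
            item.branch_parent is not None
            and item.item_id in ratings
            and item.branch_parent not in ratings
        ):
            raise BranchingError(
                f"child {item.item_id!r} rated but parent {item.branch_parent!r} has no rating"
            )
    shown = presented_items(catalogue, ratings)
    presented: dict[str, float] = {}
    skipped: list[str] = []
    for item in catalogue.items:
        if item.item_id in shown:
            if item.item_id in ratings:
                presented[item.item_id] = ratings[item.item_id]
        else:
            skipped.append(item.item_id)
    return presented, skipped


def presented_items(catalogue: Catalogue, ratings: dict[str, float]) -> set[str]:
    """Item ids that branching rules present, given the ratings at hand."""
    out: set[str] = set()
    for item in catalogue.items:
        if item.branch_parent is None:
            out.add(item.item_id)
        elif (
            item.branch_parent in out
            and item.branch_parent in ratings
            and ratings[item.branch_parent] >= catalogue.branch_threshold_of(item)
        ):
            out.add(item.item_id)
    return out


def validate_stream(stream: ObservationStream) -> list[str]:
    """Check every stream invariant; returns one message per violation.

    Never raises on content: a validator that throws cannot report more than
    one problem at a time.
    """
    violations: list[str] = []
    cat = stream.catalogue
    prev_time: dt.datetime | None = None
    for k, prompt in enumerate(stream.prompts):
        tag = f"prompt {k} at {prompt.prompt_time.isoformat()}"
        if prev_time is not None and prompt.prompt_time <= prev_time:
            violations.append(f"{tag}: prompt times not strictly increasing")
        prev_time = prompt.prompt_time
        if prompt.status == "missed" and prompt.responses:
            violations.append(f"{tag}: missed prompt has responses")
        ratings = prompt.ratings()
        if len(ratings) != len(prompt.responses):
            violations.append(f"{tag}: duplicate item responses")
        for resp in prompt.responses:
            if resp.item_id not in cat.by_id:
                violations.append(f"{tag}: unknown item {resp.item_id!r}")
            elif not cat.scale_min <= resp.rating <= cat.scale_max:
                violations.append(
                    f"{tag}: rating {resp.rating} for {resp.item_id!r} outside "
                    f"[{cat.scale_min}, {cat.scale_max}]"
                )
        known = {i for i in ratings if i in cat.by_id}
        if known:
            expected = presented_items(cat, ratings)
            for item_id in known - expected:
                violations.append(f"{tag}: response for branch-skipped item {item_id!r}")
            if prompt.status == "completed":
                for item_id in sorted(expected - known):
                    violations.append(f"{tag}: completed prompt missing item {item_id!r}")
        elif prompt.status == "completed":
            violations.append(f"{tag}: completed prompt has no responses")
    return violations


def default_catalogue() -> Catalogue:
    """A 12-item illustrative catalogue (7 psychotic, 5 dysphoric).

    The deployed questionnaire's item list was never published; these items
    cover the same ground (positive psychotic symptoms, anxiety, mood) and
    carry two branch children, but the wording is illustrative only.
    """
    items = [
        SymptomItem("suspicious", "I feel suspicious of other people", "psychotic"),
        SymptomItem("persecution", "I feel that others intend me harm", "psychotic", branch_parent="suspicious"),
        SymptomItem("voices", "I hear voices other people cannot hear", "psychotic"),
        SymptomItem("voices_distress", "The voices are distressing", "psychotic", branch_parent="voices"),
        SymptomItem("unusual_thoughts", "My thoughts feel strange or not my own", "psychotic"),
        SymptomItem("grandiosity", "I have special powers or abilities", "psychotic"),
        SymptomItem("perception", "Things around me look or sound unusual", "psychotic"),
        SymptomItem("anxious", "I feel anxious", "dysphoric"),
        SymptomItem("sad", "I feel sad or low", "dysphoric"),
        SymptomItem("stressed", "I feel stressed or under pressure", "dysphoric"),
        SymptomItem("hopeless", "I feel hopeless about the future", "dysphoric"),
        SymptomItem("irritable", "I feel irritable", "dysphoric"),
    ]
    return Catalogue(items)
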