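"""Synthetic EMA symptom-trajectory simulator with ground-truth relapse prodromes.

No raw trial data are released with monitoring studies of this kind, so the
alert engine, adherence metrics, and evaluation module are exercised on
simulated cohorts.  Each participant's latent item severities follow a
mean-reverting AR(1) process around per-item baselines, clipped to the
ordinal scale and rounded to integers at observation time.  A relapse
prodrome is an additive linear ramp on the item means: dysphoric items
(anxious mood, low mood) begin rising at prodrome onset, attenuated
psychotic items follow after a configurable lead of a day or more, and both
peak on the relapse day.  Prodromes last 1-5 days.  Prompts follow the
semi-random schedule, and each prompt is completed with probability
``p_resp`` (completely at random by default; an optional severity-linked
decrement makes missingness informative).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .engine import EWSProfile
from .symptoms import (
    Catalogue,
    ItemResponse,
    ObservationStream,
    PromptRecord,
    default_catalogue,
    generate_schedule,
    presented_items,
)

__all__ = [
    "TrajectoryConfig",
    "RelapseEvent",
    "SimulationConfigError",
    "UnreachableScoreError",
    "simulate_cohort",
    "scripted_stream",
]

UTC = dt.timezone.utc


class SimulationConfigError(ValueError):
    """Trajectory configuration that cannot produce a valid cohort."""


class UnreachableScoreError(ValueError):
    """A scripted target score cannot be realized within the rating scale."""


@dataclass(frozen=True)
class RelapseEvent:
    """Ground truth for one simulated relapse: the detection target."""

    participant_id: str
    prodrome_start: dt.datetime
    relapse_day: dt.datetime
    affected_items: tuple[str, ...]


@dataclass
class TrajectoryConfig:
    """Cohort-level simulation settings.

    Defaults emulate a 12-week monitoring period with twice-daily prompts.
    ``relapse_rate`` is the Poisson mean number of prodrome/relapse events
    per participant over the whole period; 0.5 puts roughly 40% of
    participants through at least one episode, in line with the one-in-three
    to one-in-two early-warning-sign frequencies community teams document
    over 12 weeks.  Amplitudes are in rating-scale units at the prodrome
    peak.
    """

    n_participants: int = 12
    n_days: int = 84
    prompts_per_day: int = 2
    window: tuple[dt.time, dt.time] = (dt.time(9, 0), dt.time(21, 0))
    min_gap: dt.timedelta = dt.timedelta(hours=2)
    catalogue: Catalogue = field(default_factory=default_catalogue)
    item_means: dict[str, float] | float = 2.0
    rho: float = 0.6
    innovation_sd: float = 0.5
    relapse_rate: float = 0.5
    prodrome_len_min: int = 1
    prodrome_len_max: int = 5
    dysphoric_lead_days: int = 1
    dysphoric_amplitude: float = 1.5
    psychotic_amplitude: float = 2.5
    p_resp: float = 0.75
    severity_missingness: float = 0.0
    study_start: dt.date = dt.date(2020, 1, 1)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.rho < 1:
            raise SimulationConfigError(f"rho must be in [0, 1), got {self.rho}")
        if not 0 < self.p_resp <= 1:
            raise SimulationConfigError(f"p_resp must be in (0, 1], got {self.p_resp}")
        if not 1 <= self.prodrome_len_min <= self.prodrome_len_max <= 5:
            raise SimulationConfigError("prodrome length bounds must satisfy 1 <= min <= max <= 5")
        if self.dysphoric_lead_days > self.prodrome_len_max:
            raise SimulationConfigError(
                f"dysphoric lead ({self.dysphoric_lead_days} d) exceeds the maximum prodrome "
                f"length ({self.prodrome_len_max} d): the psychotic ramp could never start"
            )
        if self.innovation_sd < 0 or self.relapse_rate < 0:
            raise SimulationConfigError("innovation_sd and relapse_rate must be non-negative")

    def mean_of(self, item_id: str) -> float:
        if isinstance(self.item_means, dict):
            return self.item_means[item_id]
        return float(self.item_means)


def _draw_events(
    cfg: TrajectoryConfig, participant_id: str, rng: np.random.Generator
) -> list[RelapseEvent]:
    """Poisson number of non-overlapping prodrome/relapse episodes.

    Episodes are kept clear of the first week so the personal baseline is
    event-free; overlapping draws are rejected (up to a cap, then dropped).
    """
    n_events = rng.poisson(cfg.relapse_rate)
    start0 = dt.datetime.combine(cfg.study_start, dt.time.min, tzinfo=UTC)
    taken: list[tuple[int, int]] = []
    events: list[RelapseEvent] = []
    affected = tuple(it.item_id for it in cfg.catalogue.items)
    earliest_relapse = max(7, cfg.prodrome_len_max + 1)
    if cfg.n_days <= earliest_relapse:
        return []
    for _ in range(n_events):
        for _ in range(100):
            length = int(rng.integers(cfg.prodrome_len_min, cfg.prodrome_len_max + 1))
            relapse = int(rng.integers(earliest_relapse, cfg.n_days))
            onset = relapse - length
            if all(onset > hi + 1 or relapse < lo - 1 for lo, hi in taken):
                taken.append((onset, relapse))
                events.append(
                    RelapseEvent(
                        participant_id=participant_id,
                        prodrome_start=start0 + dt.timedelta(days=onset),
                        relapse_day=start0 + dt.timedelta(days=relapse),
                        affected_items=affected,
                    )
                )
                break
    events.sort(key=lambda e: e.prodrome_start)
    return events


def _ramp(cfg: TrajectoryConfig, events: list[RelapseEvent], item_domain: str, t_days: float) -> float:
    """Additive mean shift at fractional day ``t_days`` from the active prodrome, if any."""
    day0 = dt.datetime.combine(cfg.study_start, dt.time.min, tzinfo=UTC)
    for ev in events:
        onset = (ev.prodrome_start - day0).total_seconds() / 86400
        relapse = (ev.relapse_day - day0).total_seconds() / 86400
        if not onset <= t_days <= relapse + 1:
            continue
        if item_domain == "dysphoric":
            ramp_start, amp = onset, cfg.dysphoric_amplitude
        else:
            ramp_start = min(onset + cfg.dysphoric_lead_days, relapse)
            amp = cfg.psychotic_amplitude
        if t_days < ramp_start:
            return 0.0
        if t_days > relapse:  # relapse day itself stays at peak; after it, signal ends
            return amp if t_days <= relapse + 1 else 0.0
        denom = relapse - ramp_start
        return amp if denom == 0 else amp * (t_days - ramp_start) / denom
    return 0.0


def simulate_cohort(
    config: TrajectoryConfig,
) -> tuple[list[ObservationStream], list[RelapseEvent]]:
    """Simulate a full cohort of EMA streams plus ground-truth relapse events.

    Fully reproducible from ``config.seed``; schedule, latent dynamics, and
    missingness draw from independent substreams so changing one setting
    does not scramble the others.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams: list[ObservationStream] = []
    all_events: list[RelapseEvent] = []
    cat = config.catalogue
    day0 = dt.datetime.combine(config.study_start, dt.time.min, tzinfo=UTC)
    for idx in range(config.n_participants):
        pid = f"P{idx + 1:03d}"
        seq_sched, seq_event, seq_dyn, seq_miss = root.spawn(4)
        schedule = generate_schedule(
            config.n_days,
            config.prompts_per_day,
            window=config.window,
            min_gap=config.min_gap,
            seed=np.random.default_rng(seq_sched),
            start_date=config.study_start,
        )
        events = _draw_events(config, pid, np.random.default_rng(seq_event))
        rng_dyn = np.random.default_rng(seq_dyn)
        rng_miss = np.random.default_rng(seq_miss)

        deviations = {it.item_id: 0.0 for it in cat.items}
        prompts: list[PromptRecord] = []
        for t in schedule:
            t_days = (t - day0).total_seconds() / 86400
            latent: dict[str, float] = {}
            shift_total = 0.0
            for item in cat.items:
                d = config.rho * deviations[item.item_id]
                if config.innovation_sd > 0:
                    d += rng_dyn.normal(0.0, config.innovation_sd)
                deviations[item.item_id] = d
                shift = _ramp(config, events, item.domain_tag, t_days)
                shift_total += shift
                latent[item.item_id] = config.mean_of(item.item_id) + shift + d
            p_complete = config.p_resp
            if config.severity_missingness > 0:
                p_complete = max(
                    0.05, config.p_resp - config.severity_missingness * shift_total / len(cat)
                )
            if rng_miss.random() >= p_complete:
                prompts.append(PromptRecord(prompt_time=t, status="missed"))
                continue
            full = {
                i: float(np.clip(round(v), cat.scale_min, cat.scale_max))
                for i, v in latent.items()
            }
            presented = presented_items(cat, full)
            responses = [
                ItemResponse(item_id=i, rating=full[i], timestamp=t)
                for i in cat.item_ids
                if i in presented
            ]
            prompts.append(PromptRecord(prompt_time=t, status="completed", responses=responses))
        streams.append(
            ObservationStream(
                participant_id=pid,
                catalogue=cat,
                prompts=prompts,
                study_start=config.study_start,
            )
        )
        all_events.extend(events)
    return streams, all_events


def scripted_stream(
    scores: list[float],
    profile: EWSProfile,
    catalogue: Catalogue | None = None,
    carrier_item: str | None = None,
    study_start: dt.date = dt.date(2020, 1, 1),
    spacing: dt.timedelta = dt.timedelta(hours=12),
    first_prompt: dt.time = dt.time(9, 0),
) -> ObservationStream:
    """Deterministic stream whose composite score equals ``scores`` exactly.

    All items sit at the scale minimum except one designated root carrier
    item, whose rating is solved from the target score by inverting the
    weighting.  Useful for engineering exact threshold-crossing
    trajectories.
    """
    cat = catalogue if catalogue is not None else default_catalogue()
    weights = profile.weights
    if carrier_item is None:
        roots = {it.item_id for it in cat.root_items}
        candidates = [(w, i) for i, w in weights.items() if w > 0 and i in roots]
        if not candidates:
            raise UnreachableScoreError("no weighted root item available as carrier")
        carrier_item = max(candidates)[1]
    w_c = weights.get(carrier_item, 0.0)
    if w_c <= 0:
        raise UnreachableScoreError(f"carrier item {carrier_item!r} has zero weight")
    if cat.by_id[carrier_item].branch_parent is not None:
        raise UnreachableScoreError("carrier item must be a root item")
    rest = sum(w for i, w in weights.items() if i != carrier_item) * cat.scale_min

    prompts: list[PromptRecord] = []
    t = dt.datetime.combine(study_start, first_prompt, tzinfo=UTC)
    for target in scores:
        r = (target - rest) / w_c
        if not cat.scale_min <= r <= cat.scale_max:
            raise UnreachableScoreError(
                f"target score {target} needs carrier rating {r:.3f}, outside "
                f"[{cat.scale_min}, {cat.scale_max}]"
            )
        full = {it.item_id: float(cat.scale_min) for it in cat.root_items}
        full[carrier_item] = r
        for item in cat.items:  # children presented by a high carrier answer at minimum
            if item.branch_parent is not None and item.item_id in presented_items(cat, full):
                full[item.item_id] = float(cat.scale_min)
        shown = presented_items(cat, full)
        responses = [
            ItemResponse(item_id=i, rating=full[i], timestamp=t)
            for i in cat.item_ids
            if i in shown
        ]
        prompts.append(PromptRecord(prompt_time=t, status="completed", responses=responses))
        t = t + spacing
    return ObservationStream(
        participant_id=profile.participant_id,
        catalogue=cat,
        prompts=prompts,
        study_start=study_start,
    )
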