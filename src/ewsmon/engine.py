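"""Personalized early-warning-sign (EWS) scoring and threshold alerting.

Each participant's relapse signature is encoded by a care coordinator as a
relevance score 0-3 per symptom item.  Relevance tiers carry fixed shares of
the total EWS score - tier 1 items collectively 20%, tier 2 items 30%, tier 3
items 50% - shared equally within a tier, so the composite score at a prompt
is a convex combination of that prompt's ratings and stays on the rating
scale.  The personal baseline is the mean composite score over the first
days of recording (default 3), and an alert fires when the score rises to
40% above baseline at a single datapoint, or 25% above baseline at two
consecutive datapoints.

The :class:`EWSDetector` estimator wraps the whole procedure in a
scikit-learn-style ``fit``/``predict`` pair: ``fit`` derives the weights and
freezes the baseline from a participant's stream, ``predict`` emits alerts.
"""

from __future__ import annotations

import datetime as dt
import inspect
from dataclasses import dataclass, field

from .symptoms import ObservationStream, PromptRecord, presented_items

__all__ = [
    "DEFAULT_TIER_SHARES",
    "EWSProfile",
    "ScorePoint",
    "AlertRecord",
    "NoMonitorableItemsError",
    "ScoringError",
    "InsufficientBaselineError",
    "compute_weights",
    "score_stream",
    "compute_baseline",
    "detect_alerts",
    "EWSDetector",
]

UTC = dt.timezone.utc

DEFAULT_TIER_SHARES: dict[int, float] = {1: 0.20, 2: 0.30, 3: 0.50}


class NoMonitorableItemsError(ValueError):
    """Every item has relevance 0: there is nothing to weight."""


class ScoringError(ValueError):
    """A completed prompt cannot be scored (a weighted item is unexplainably absent)."""


class InsufficientBaselineError(ValueError):
    """No completed scores fall inside the baseline window."""


@dataclass
class EWSProfile:
    """A participant's EWS personalization: relevance map, thresholds, baseline window."""

    participant_id: str
    relevance: dict[str, int]
    tier_shares: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TIER_SHARES))
    single_point_rise: float = 0.40
    consecutive_rise: float = 0.25
    baseline_days: int = 3

    def __post_init__(self) -> None:
        self.weights: dict[str, float] = compute_weights(self.relevance, self.tier_shares)


@dataclass(frozen=True)
class ScorePoint:
    prompt_time: dt.datetime
    score: float


@dataclass(frozen=True)
class AlertRecord:
    participant_id: str
    alert_time: dt.datetime
    rule: str  # "single_point" | "two_consecutive"
    score: float
    baseline: float


def compute_weights(
    relevance: dict[str, int], tier_shares: dict[int, float] | None = None
) -> dict[str, float]:
    """Derive per-item weights from 0-3 relevance scores.

    Tier ``t``'s items share ``tier_shares[t]`` equally.  When a tier is
    unoccupied its share is redistributed proportionally across the occupied
    tiers, so the weights always sum to 1.  Relevance-0 items are still rated
    by the participant but carry weight 0.
    """
    shares = dict(DEFAULT_TIER_SHARES) if tier_shares is None else dict(tier_shares)
    bad = {i: r for i, r in relevance.items() if r not in (0, 1, 2, 3)}
    if bad:
        raise ValueError(f"relevance scores must be in {{0,1,2,3}}: {bad}")
    tiers: dict[int, list[str]] = {t: [] for t in shares}
    for item_id, r in relevance.items():
        if r > 0:
            tiers[r].append(item_id)
    occupied = {t: members for t, members in tiers.items() if members}
    if not occupied:
        raise NoMonitorableItemsError("all items have relevance 0; no monitorable items")
    total_share = sum(shares[t] for t in occupied)
    weights = {item_id: 0.0 for item_id in relevance}
    for t, members in occupied.items():
        w = shares[t] / total_share / len(members)
        for item_id in members:
            weights[item_id] = w
    return weights


def score_stream(
    stream: ObservationStream, profile: EWSProfile, include_partial: bool = False
) -> list[ScorePoint]:
    """Weighted composite severity at every scorable prompt.

    The composite is ``sum_i weight_i * rating_i`` over the weighted items.
    Branch children that were skipped because the parent rated low are imputed
    at the scale minimum (skipping encodes absence of the symptom).  Missed
    prompts produce no score; partial prompts are excluded unless
    ``include_partial`` is set.
    """
    cat = stream.catalogue
    points: list[ScorePoint] = []
    for prompt in stream.prompts:
        if prompt.status == "missed":
            continue
        if prompt.status == "partial" and not include_partial:
            continue
        ratings = prompt.ratings()
        shown = presented_items(cat, ratings)
        total = 0.0
        for item_id, w in profile.weights.items():
            if w == 0.0:
                continue
            if item_id in ratings:
                total += w * ratings[item_id]
            elif item_id in cat.by_id and item_id not in shown:
                total += w * cat.scale_min  # branch-skipped: symptom absent
            else:
                raise ScoringError(
                    f"prompt at {prompt.prompt_time.isoformat()}: weighted item "
                    f"{item_id!r} unanswered and not branch-skipped"
                )
        points.append(ScorePoint(prompt.prompt_time, total))
    return points


def _as_utc_start(study_start: dt.date | dt.datetime) -> dt.datetime:
    if isinstance(study_start, dt.datetime):
        return study_start if study_start.tzinfo else study_start.replace(tzinfo=UTC)
    return dt.datetime.combine(study_start, dt.time.min, tzinfo=UTC)


def compute_baseline(
    points: list[ScorePoint], baseline_days: int, study_start: dt.date | dt.datetime
) -> float:
    """Mean composite score over the first ``baseline_days`` calendar days.

    The window is calendar-time, ``[study_start, study_start + baseline_days)``,
    not a fixed count of datapoints.  An empty window is an error; callers who
    want a longer window must opt in explicitly rather than have the baseline
    silently drift.
    """
    start = _as_utc_start(study_start)
    end = start + dt.timedelta(days=baseline_days)
    in_window = [p.score for p in points if start <= p.prompt_time < end]
    if not in_window:
        raise InsufficientBaselineError(
            f"no completed scores in the baseline window [{start.isoformat()}, {end.isoformat()})"
        )
    return sum(in_window) / len(in_window)


def detect_alerts(
    points: list[ScorePoint],
    baseline: float,
    profile: EWSProfile,
    refractory: dt.timedelta | None = dt.timedelta(hours=24),
    max_gap: dt.timedelta = dt.timedelta(hours=24),
) -> list[AlertRecord]:
    """Apply the two threshold rules to a time-ordered score series.

    single_point:    S(t) >= (1 + single_point_rise) * baseline
    two_consecutive: S(t) and the immediately preceding completed score are
                     both >= (1 + consecutive_rise) * baseline and no more
                     than ``max_gap`` apart.

    Thresholds are attained with ``>=`` ("rose to 40% higher" reads as
    attainment).  When both rules fire at the same point, the single-point
    rule is recorded.  After an alert, further alerts are suppressed for the
    refractory period (pass ``None`` to disable).  ``points`` must already
    exclude the baseline window: baseline-window datapoints define the
    baseline, they do not alert against it.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    hi = baseline * (1.0 + profile.single_point_rise)
    lo = baseline * (1.0 + profile.consecutive_rise)
    alerts: list[AlertRecord] = []
    last_alert: dt.datetime | None = None
    prev: ScorePoint | None = None
    for p in points:
        suppressed = (
            refractory is not None
            and last_alert is not None
            and p.prompt_time < last_alert + refractory
        )
        rule = None
        if p.score >= hi:
            rule = "single_point"
        elif (
            p.score >= lo
            and prev is not None
            and prev.score >= lo
            and p.prompt_time - prev.prompt_time <= max_gap
        ):
            rule = "two_consecutive"
        if rule is not None and not suppressed:
            alerts.append(AlertRecord(profile.participant_id, p.prompt_time, rule, p.score, baseline))
            last_alert = p.prompt_time
        prev = p
    return alerts


class EWSDetector:
    """Personalized early-warning alert detector with a fit/predict interface.

    Parameters
    ----------
    relevance : dict
        Item id -> relevance 0-3, the participant's relapse signature as set
        by their care coordinator.
    tier_shares : dict, optional
        Share of the total score carried by each relevance tier
        (default ``{1: 0.20, 2: 0.30, 3: 0.50}``).
    single_point_rise, consecutive_rise : float
        Fractional rises over baseline for the two alert rules (0.40, 0.25).
    baseline_days : int
        Calendar days of recording that define the personal baseline (3).
    refractory_hours : float or None
        Suppression period after an alert; ``None`` disables.
    max_gap_hours : float
        Maximum spacing for two datapoints to count as consecutive.
    include_partial : bool
        Score partially completed prompts too.

    Attributes (after ``fit``)
    --------------------------
    weights_ : dict            per-item weights summing to 1
    baseline_ : float          frozen personal baseline
    baseline_end_ : datetime   end of the baseline window (exclusive)
    n_baseline_points_ : int   completed datapoints the baseline averaged
    """

    def __init__(
        self,
        relevance: dict[str, int] | None = None,
        tier_shares: dict[int, float] | None = None,
        single_point_rise: float = 0.40,
        consecutive_rise: float = 0.25,
        baseline_days: int = 3,
        refractory_hours: float | None = 24.0,
        max_gap_hours: float = 24.0,
        include_partial: bool = False,
    ):
        self.relevance = relevance
        self.tier_shares = tier_shares
        self.single_point_rise = single_point_rise
        self.consecutive_rise = consecutive_rise
        self.baseline_days = baseline_days
        self.refractory_hours = refractory_hours
        self.max_gap_hours = max_gap_hours
        self.include_partial = include_partial

    # -- sklearn-compatible parameter plumbing ------------------------------
    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params) -> "EWSDetector":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for EWSDetector")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items() if v is not None)
        return f"EWSDetector({args})"

    # -- estimator API -------------------------------------------------------
    def _profile(self, participant_id: str) -> EWSProfile:
        if self.relevance is None:
            raise ValueError("relevance map is required; set `relevance=` before fitting")
        return EWSProfile(
            participant_id=participant_id,
            relevance=self.relevance,
            tier_shares=dict(DEFAULT_TIER_SHARES) if self.tier_shares is None else self.tier_shares,
            single_point_rise=self.single_point_rise,
            consecutive_rise=self.consecutive_rise,
            baseline_days=self.baseline_days,
        )

    def fit(self, stream: ObservationStream, y=None) -> "EWSDetector":
        """Derive weights and freeze the baseline from the stream's opening days."""
        profile = self._profile(stream.participant_id)
        points = score_stream(stream, profile, include_partial=self.include_partial)
        start = _as_utc_start(stream.study_start)
        end = start + dt.timedelta(days=self.baseline_days)
        self.baseline_ = compute_baseline(points, self.baseline_days, stream.study_start)
        self.n_baseline_points_ = sum(1 for p in points if start <= p.prompt_time < end)
        self.baseline_end_ = end
        self.weights_ = profile.weights
        self._fitted_profile = profile
        return self

    def score_points(self, stream: ObservationStream) -> list[ScorePoint]:
        """Composite score at every scorable prompt (baseline window included)."""
        self._check_fitted()
        return score_stream(stream, self._fitted_profile, include_partial=self.include_partial)

    def predict(self, stream: ObservationStream) -> list[AlertRecord]:
        """Alerts over the post-baseline portion of the stream."""
        self._check_fitted()
        points = [p for p in self.score_points(stream) if p.prompt_time >= self.baseline_end_]
        refractory = (
            None if self.refractory_hours is None else dt.timedelta(hours=self.refractory_hours)
        )
        return detect_alerts(
            points,
            self.baseline_,
            self._fitted_profile,
            refractory=refractory,
            max_gap=dt.timedelta(hours=self.max_gap_hours),
        )

    def fit_predict(self, stream: ObservationStream, y=None) -> list[AlertRecord]:
        return self.fit(stream).predict(stream)

    def _check_fitted(self) -> None:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("EWSDetector is not fitted; call fit(stream) first")
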