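"""Readers and writers for the package's plain-text artifact formats.

All timestamps are stored as UTC ISO-8601; all CSVs are comma-separated,
UTF-8, header-required (RFC 4180).  The long-format stream CSV has columns
``participant_id, prompt_time, prompt_status, item_id, rating``; a missed
prompt appears as a single row with empty item and rating.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import asdict
from pathlib import Path

from .adherence import AdherenceSummary
from .engine import AlertRecord, EWSProfile, ScorePoint
from .evaluate import EvaluationReport
from .simulate import RelapseEvent
from .symptoms import (
    Catalogue,
    ItemResponse,
    ObservationStream,
    PromptRecord,
    SymptomItem,
    validate_stream,
)

__all__ = [
    "StreamParseError",
    "read_stream_csv",
    "write_stream_csv",
    "read_catalogue_json",
    "write_catalogue_json",
    "read_profile_json",
    "write_profile_json",
    "write_alerts_csv",
    "read_alerts_csv",
    "write_events_csv",
    "read_events_csv",
    "write_scores_csv",
    "write_adherence_csv",
    "write_report_json",
]

UTC = dt.timezone.utc

STREAM_COLUMNS = ["participant_id", "prompt_time", "prompt_status", "item_id", "rating"]


class StreamParseError(ValueError):
    """A stream CSV row that cannot be interpreted; the message names the row."""


def _parse_instant(text: str, row: int) -> dt.datetime:
    try:
        t = dt.datetime.fromisoformat(text)
    except ValueError as exc:
        raise StreamParseError(f"row {row}: malformed timestamp {text!r}") from exc
    return t.replace(tzinfo=UTC) if t.tzinfo is None else t.astimezone(UTC)


def _format_instant(t: dt.datetime) -> str:
    return t.astimezone(UTC).isoformat().replace("+00:00", "Z")


def _format_rating(r: float) -> str:
    return str(int(r)) if float(r).is_integer() else repr(float(r))


def read_stream_csv(
    path: str | Path,
    catalogue: Catalogue,
    study_start: dt.date | None = None,
    validate: bool = True,
) -> list[ObservationStream]:
    """Parse a long-format stream CSV into per-participant streams.

    Streams are grouped by participant and sorted by prompt time; invariants
    are checked automatically unless ``validate=False``.  ``study_start``
    defaults to each participant's first prompt date.
    """
    grouped: dict[str, dict[dt.datetime, PromptRecord]] = {}
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != STREAM_COLUMNS:
            raise StreamParseError(
                f"header must be {','.join(STREAM_COLUMNS)}, got {reader.fieldnames}"
            )
        for row_no, row in enumerate(reader, start=2):
            pid = row["participant_id"]
            t = _parse_instant(row["prompt_time"], row_no)
            status = row["prompt_status"]
            item_id = row["item_id"] or ""
            key = (pid, row["prompt_time"], item_id)
            if key in seen:
                raise StreamParseError(
                    f"row {row_no}: duplicate (participant, prompt_time, item) {key}"
                )
            seen.add(key)
            prompts = grouped.setdefault(pid, {})
            if t not in prompts:
                prompts[t] = PromptRecord(prompt_time=t, status=status)
            record = prompts[t]
            if record.status != status:
                raise StreamParseError(f"row {row_no}: conflicting status for prompt at {t}")
            if item_id:
                if item_id not in catalogue.by_id:
                    raise StreamParseError(f"row {row_no}: unknown item {item_id!r}")
                try:
                    rating = float(row["rating"])
                except (TypeError, ValueError) as exc:
                    raise StreamParseError(
                        f"row {row_no}: unparseable rating {row['rating']!r}"
                    ) from exc
                if not catalogue.scale_min <= rating <= catalogue.scale_max:
                    raise StreamParseError(
                        f"row {row_no}: rating {rating:g} outside "
                        f"[{catalogue.scale_min:g}, {catalogue.scale_max:g}]"
                    )
                record.responses.append(ItemResponse(item_id=item_id, rating=rating, timestamp=t))
            elif row["rating"]:
                raise StreamParseError(f"row {row_no}: rating without item_id")

    streams = []
    for pid in sorted(grouped):
        prompts = [grouped[pid][t] for t in sorted(grouped[pid])]
        start = study_start if study_start is not None else prompts[0].prompt_time.date()
        stream = ObservationStream(
            participant_id=pid, catalogue=catalogue, prompts=prompts, study_start=start
        )
        if validate:
            violations = validate_stream(stream)
            if violations:
                raise StreamParseError(
                    f"participant {pid}: invalid stream: " + "; ".join(violations[:5])
                )
        streams.append(stream)
    return streams


def write_stream_csv(streams: list[ObservationStream], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STREAM_COLUMNS)
        for stream in streams:
            for prompt in stream.prompts:
                t = _format_instant(prompt.prompt_time)
                if not prompt.responses:
                    writer.writerow([stream.participant_id, t, prompt.status, "", ""])
                    continue
                for resp in prompt.responses:
                    writer.writerow(
                        [stream.participant_id, t, prompt.status, resp.item_id, _format_rating(resp.rating)]
                    )


def read_catalogue_json(path: str | Path) -> Catalogue:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    items = [
        SymptomItem(
            item_id=d["item_id"],
            label=d.get("label", d["item_id"]),
            domain_tag=d["domain_tag"],
            branch_parent=d.get("branch_parent"),
            branch_threshold=d.get("branch_threshold"),
        )
        for d in payload["items"]
    ]
    return Catalogue(items, scale_min=payload.get("scale_min", 1), scale_max=payload.get("scale_max", 7))


def write_catalogue_json(catalogue: Catalogue, path: str | Path) -> None:
    payload = {
        "scale_min": catalogue.scale_min,
        "scale_max": catalogue.scale_max,
        "items": [asdict(it) for it in catalogue.items],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_profile_json(path: str | Path) -> EWSProfile:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    thresholds = payload.get("thresholds", {})
    kwargs = {}
    if "tier_shares" in payload:
        kwargs["tier_shares"] = {int(t): s for t, s in payload["tier_shares"].items()}
    return EWSProfile(
        participant_id=payload["participant_id"],
        relevance={i: int(r) for i, r in payload["relevance"].items()},
        single_point_rise=thresholds.get("single_point_rise", 0.40),
        consecutive_rise=thresholds.get("consecutive_rise", 0.25),
        baseline_days=payload.get("baseline_days", 3),
        **kwargs,
    )


def write_profile_json(profile: EWSProfile, path: str | Path) -> None:
    payload = {
        "participant_id": profile.participant_id,
        "relevance": profile.relevance,
        "thresholds": {
            "single_point_rise": profile.single_point_rise,
            "consecutive_rise": profile.consecutive_rise,
        },
        "baseline_days": profile.baseline_days,
        "tier_shares": profile.tier_shares,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_alerts_csv(alerts: list[AlertRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "alert_time", "rule", "score", "baseline"])
        for a in alerts:
            writer.writerow(
                [a.participant_id, _format_instant(a.alert_time), a.rule, repr(a.score), repr(a.baseline)]
            )


def read_alerts_csv(path: str | Path) -> list[AlertRecord]:
    alerts = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row_no, row in enumerate(csv.DictReader(fh), start=2):
            alerts.append(
                AlertRecord(
                    participant_id=row["participant_id"],
                    alert_time=_parse_instant(row["alert_time"], row_no),
                    rule=row["rule"],
                    score=float(row["score"]),
                    baseline=float(row["baseline"]),
                )
            )
    return alerts


def write_events_csv(events: list[RelapseEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "prodrome_start", "relapse_day", "affected_items"])
        for ev in events:
            writer.writerow(
                [
                    ev.participant_id,
                    _format_instant(ev.prodrome_start),
                    _format_instant(ev.relapse_day),
                    ";".join(ev.affected_items),
                ]
            )


def read_events_csv(path: str | Path) -> list[RelapseEvent]:
    events = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row_no, row in enumerate(csv.DictReader(fh), start=2):
            events.append(
                RelapseEvent(
                    participant_id=row["participant_id"],
                    prodrome_start=_parse_instant(row["prodrome_start"], row_no),
                    relapse_day=_parse_instant(row["relapse_day"], row_no),
                    affected_items=tuple(row["affected_items"].split(";")) if row["affected_items"] else (),
                )
            )
    return events


def write_scores_csv(participant_id: str, points: list[ScorePoint], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "prompt_time", "score"])
        for p in points:
            writer.writerow([participant_id, _format_instant(p.prompt_time), repr(p.score)])


def write_adherence_csv(summaries: list[AdherenceSummary], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "participant_id",
                "prompts_issued",
                "prompts_completed",
                "response_rate",
                "adherence_class",
                "retained_at_end",
            ]
        )
        for s in summaries:
            writer.writerow(
                [
                    s.participant_id,
                    s.prompts_issued,
                    s.prompts_completed,
                    repr(s.response_rate),
                    s.adherence_class,
                    s.retained_at_end,
                ]
            )


def write_report_json(report: EvaluationReport, path: str | Path) -> None:
    payload = asdict(report)
    payload = {k: (None if isinstance(v, float) and v != v else v) for k, v in payload.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
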