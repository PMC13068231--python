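"""Event-log and table I/O.

Event streams are JSONL — one self-describing record per line, tagged by
``record`` kind (``diary``, ``app_event``, ``questionnaire``,
``notification``) and carrying its ``user_id`` — because notification and
diary streams are append-only in a deployed system and line-oriented logs
stay diagnosable. Demographics travel as a CSV table. Timestamps are
ISO-8601 UTC strings on disk; internally all times are integer minute
offsets from the trial epoch (2020-01-06T00:00Z, a Monday, so day % 7
lands weekends on days 5 and 6).
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable

from .persona import DEFAULT_CONFIG, PersonaConfig, build_persona, feature_registry
from .records import (
    MINUTES_PER_DAY,
    AppEvent,
    Demographics,
    DiaryEntry,
    EventKind,
    Gender,
    NotificationCategory,
    NotificationRecord,
    QuestionnaireResponse,
    ServiceBranch,
    UserHistory,
)

__all__ = [
    "EPOCH",
    "minute_to_iso",
    "iso_to_minute",
    "write_events",
    "read_events",
    "write_histories",
    "read_histories",
    "write_demographics",
    "read_demographics",
    "export_personas",
]

EPOCH = datetime(2020, 1, 6, tzinfo=timezone.utc)  # a Monday


def minute_to_iso(minute: int) -> str:
    return (EPOCH + timedelta(minutes=int(minute))).strftime("%Y-%m-%dT%H:%M:%SZ")


def iso_to_minute(stamp: str) -> int:
    dt = datetime.strptime(stamp, "%Y-%m-%dT%H:%M:%SZ").replace(tzinfo=timezone.utc)
    return int((dt - EPOCH).total_seconds() // 60)


def day_to_iso(day: int) -> str:
    return (EPOCH + timedelta(days=int(day))).strftime("%Y-%m-%d")


def iso_to_day(stamp: str) -> int:
    dt = datetime.strptime(stamp, "%Y-%m-%d").replace(tzinfo=timezone.utc)
    return int((dt - EPOCH).days)


_VALID_KINDS = {"diary", "app_event", "questionnaire", "notification"}


def _record_to_json(user_id: str, obj) -> dict:
    if isinstance(obj, DiaryEntry):
        return {
            "record": "diary",
            "user_id": user_id,
            "date": day_to_iso(obj.day),
            "units": obj.units,
        }
    if isinstance(obj, AppEvent):
        return {
            "record": "app_event",
            "user_id": user_id,
            "timestamp": minute_to_iso(obj.minute),
            "kind": obj.kind.value,
            "duration_s": obj.duration_s,
        }
    if isinstance(obj, QuestionnaireResponse):
        return {
            "record": "questionnaire",
            "user_id": user_id,
            "week_index": obj.week_index,
            "depression": obj.depression,
            "anxiety": obj.anxiety,
            "loneliness": obj.loneliness,
        }
    if isinstance(obj, NotificationRecord):
        return {
            "record": "notification",
            "user_id": user_id,
            "timestamp": minute_to_iso(obj.minute),
            "category": obj.category.value,
            "segment_id": obj.segment_id,
            "engaged_within_1h": obj.engaged_within_1h,
            "bct_tag": obj.bct_tag,
        }
    raise TypeError(f"unserializable record type: {type(obj)!r}")


def _record_from_json(doc: dict, line_no: int):
    kind = doc.get("record")
    if kind not in _VALID_KINDS:
        raise ValueError(f"line {line_no}: unknown record kind {kind!r}")
    user_id = doc["user_id"]
    if kind == "diary":
        return user_id, DiaryEntry(day=iso_to_day(doc["date"]), units=float(doc["units"]))
    if kind == "app_event":
        return user_id, AppEvent(
            minute=iso_to_minute(doc["timestamp"]),
            kind=EventKind(doc["kind"]),
            duration_s=float(doc.get("duration_s", 0.0)),
        )
    if kind == "questionnaire":
        return user_id, QuestionnaireResponse(
            week_index=int(doc["week_index"]),
            depression=float(doc["depression"]),
            anxiety=float(doc["anxiety"]),
            loneliness=float(doc["loneliness"]),
        )
    return user_id, NotificationRecord(
        minute=iso_to_minute(doc["timestamp"]),
        category=NotificationCategory(doc["category"]),
        segment_id=doc.get("segment_id"),
        engaged_within_1h=bool(doc.get("engaged_within_1h", False)),
        bct_tag=doc.get("bct_tag"),
    )


def write_events(records: Iterable[tuple[str, object]], path: str | Path) -> None:
    """Write (user_id, record) pairs as JSONL, order preserved."""
    with open(path, "w") as fh:
        for user_id, obj in records:
            fh.write(json.dumps(_record_to_json(user_id, obj)) + "\n")


def read_events(path: str | Path) -> list[tuple[str, object]]:
    """Read a JSONL event log; malformed lines raise with their line number."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {i}: malformed JSON: {exc}") from exc
            out.append(_record_from_json(doc, i))
    return out


_DEMO_FIELDS = [
    "user_id",
    "signup",
    "age",
    "gender",
    "service_branch",
    "service_length",
    "prior_alcohol_treatment",
    "is_veteran",
    "complete",
]


def write_demographics(histories: Iterable[UserHistory], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_DEMO_FIELDS)
        writer.writeheader()
        for h in histories:
            d = h.demographics
            writer.writerow(
                {
                    "user_id": h.user_id,
                    "signup": minute_to_iso(h.signup_minute),
                    "age": d.age,
                    "gender": d.gender.value,
                    "service_branch": d.service_branch.value,
                    "service_length": d.service_length,
                    "prior_alcohol_treatment": int(d.prior_alcohol_treatment),
                    "is_veteran": int(d.is_veteran),
                    "complete": int(d.complete),
                }
            )


def read_demographics(path: str | Path) -> dict[str, UserHistory]:
    histories: dict[str, UserHistory] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            demo = Demographics(
                age=float(row["age"]),
                gender=Gender(row["gender"]),
                service_branch=ServiceBranch(row["service_branch"]),
                service_length=float(row["service_length"]),
                prior_alcohol_treatment=bool(int(row["prior_alcohol_treatment"])),
                is_veteran=bool(int(row["is_veteran"])),
                complete=bool(int(row["complete"])),
            )
            histories[row["user_id"]] = UserHistory(
                user_id=row["user_id"],
                signup_minute=iso_to_minute(row["signup"]),
                demographics=demo,
            )
    return histories


def write_histories(
    histories: Iterable[UserHistory], events_path: str | Path, demographics_path: str | Path
) -> None:
    """Emit the simulator's standard outputs: JSONL events + demographics CSV."""
    histories = list(histories)
    write_demographics(histories, demographics_path)
    pairs: list[tuple[str, object]] = []
    for h in histories:
        for entry in h.diary:
            pairs.append((h.user_id, entry))
        for ev in h.events:
            pairs.append((h.user_id, ev))
        for q in h.questionnaires:
            pairs.append((h.user_id, q))
        for nr in h.notifications:
            pairs.append((h.user_id, nr))
    write_events(pairs, events_path)


def read_histories(events_path: str | Path, demographics_path: str | Path) -> dict[str, UserHistory]:
    histories = read_demographics(demographics_path)
    for user_id, obj in read_events(events_path):
        if user_id not in histories:
            raise ValueError(f"event for unknown user {user_id!r}")
        h = histories[user_id]
        if isinstance(obj, DiaryEntry):
            h.diary.append(obj)
        elif isinstance(obj, AppEvent):
            h.events.append(obj)
        elif isinstance(obj, QuestionnaireResponse):
            h.questionnaires.append(obj)
        elif isinstance(obj, NotificationRecord):
            h.notifications.append(obj)
    return histories


def export_personas(
    histories: Iterable[UserHistory],
    as_of: int,
    path: str | Path,
    config: PersonaConfig = DEFAULT_CONFIG,
) -> None:
    """One CSV row per user: the full persona vector at ``as_of``."""
    names = feature_registry(config)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user_id", "as_of", "available", *names])
        for h in histories:
            p = build_persona(h, as_of, config)
            writer.writerow([h.user_id, minute_to_iso(as_of), int(p.available), *p.values])
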