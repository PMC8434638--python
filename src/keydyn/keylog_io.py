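"""Readers and writers for anonymized keystroke study files.

Three plain-text formats:

* **event log** — CSV, one row per key event, header
  ``timestamp_ms,key_class,slot_id,event_type,capital`` (``capital`` in
  {0,1,NA});
* **sidecar** — JSON with the session's user id, opinion-boundary
  timestamps, and SAM self-reports;
* **feature table** — CSV, one row per opinion segment: ``user_id``,
  ``opinion_kind``, then the 51 canonical feature columns.

All serialization is privacy-preserving by construction: the formats have no
field that could carry a letter or digit identity.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .types import (
    EventType,
    KeyClass,
    KeyEvent,
    OpinionKind,
    OpinionSegment,
    SelfReport,
    Session,
)

EVENT_LOG_COLUMNS = ("timestamp_ms", "key_class", "slot_id", "event_type", "capital")


class ParseError(ValueError):
    """A malformed input file; message carries the offending line number."""


def _parse_capital(raw: str) -> bool | None:
    if raw in ("", "NA"):
        return None
    if raw in ("0", "1"):
        return raw == "1"
    raise ValueError(f"capital must be 0, 1 or NA, got {raw!r}")


def read_event_log(
    path: str | Path,
    sidecar_path: str | Path | None = None,
    monotone_tolerance_ms: int = 0,
) -> Session:
    """Read an event-log CSV (and optional sidecar JSON) into a Session.

    Rows must be time-ordered: a timestamp that steps back by more than
    ``monotone_tolerance_ms`` raises :class:`ParseError`; smaller jitters are
    repaired by a stable sort.  Malformed rows raise with their line number
    rather than being dropped.  UP events whose slot has no pending DOWN are
    retained but flagged in ``Session.warnings`` (the pairing stage decides
    what to do with them).
    """
    path = Path(path)
    events: list[KeyEvent] = []
    warnings: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if tuple(h.strip() for h in header) != EVENT_LOG_COLUMNS:
            raise ParseError(
                f"{path}:1: bad header {header!r}, expected {','.join(EVENT_LOG_COLUMNS)}"
            )
        prev_ts: int | None = None
        open_slots: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            try:
                ts = int(row[0])
                key_class = KeyClass(row[1])
                slot_id = row[2]
                event_type = EventType(row[3])
                capital = _parse_capital(row[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if prev_ts is not None and ts < prev_ts - monotone_tolerance_ms:
                raise ParseError(
                    f"{path}:{lineno}: timestamp {ts} precedes {prev_ts} beyond "
                    f"tolerance {monotone_tolerance_ms} ms"
                )
            prev_ts = max(prev_ts, ts) if prev_ts is not None else ts
            if event_type is EventType.UP and slot_id not in open_slots:
                warnings.append(
                    f"{path}:{lineno}: UP for slot {slot_id} with no preceding DOWN"
                )
            elif event_type is EventType.DOWN:
                open_slots.add(slot_id)
            if event_type is EventType.UP:
                open_slots.discard(slot_id)
            events.append(KeyEvent(ts, key_class, slot_id, event_type, capital))

    events.sort(key=lambda e: e.timestamp_ms)  # stable: repairs tolerated jitter only

    user_id, boundaries, reports = path.stem, [], []
    if sidecar_path is not None:
        user_id, boundaries, reports = _read_sidecar(sidecar_path)
    return Session(
        user_id=user_id,
        events=events,
        boundaries=boundaries,
        reports=reports,
        warnings=warnings,
    )


def _read_sidecar(path: str | Path):
    with Path(path).open(encoding="utf-8") as fh:
        doc = json.load(fh)
    boundaries = [(int(b["t_ms"]), OpinionKind(b["opinion_kind"])) for b in doc["boundaries"]]
    reports = [
        SelfReport(
            time_point=int(r["time_point"]),
            pleasure=int(r["pleasure"]),
            arousal=int(r["arousal"]),
            dominance=int(r["dominance"]),
        )
        for r in doc.get("reports", [])
    ]
    return str(doc["user_id"]), boundaries, reports


def write_event_log(session: Session, path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a session back to the event-log CSV (and optional sidecar)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_LOG_COLUMNS)
        for e in session.events:
            cap = "NA" if e.capital is None else str(int(e.capital))
            writer.writerow([e.timestamp_ms, e.key_class.value, e.slot_id, e.event_type.value, cap])
    if sidecar_path is not None:
        doc = {
            "user_id": session.user_id,
            "boundaries": [{"t_ms": t, "opinion_kind": k.value} for t, k in session.boundaries],
            "reports": [
                {
                    "time_point": r.time_point,
                    "pleasure": r.pleasure,
                    "arousal": r.arousal,
                    "dominance": r.dominance,
                }
                for r in session.reports
            ],
        }
        Path(sidecar_path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def slice_session(session: Session) -> list[OpinionSegment]:
    """Cut a session's event stream into its labeled opinion segments.

    Boundary *i* opens the half-open interval [start_i, start_{i+1}); the
    last interval extends to the end of the session.  Events before the
    first boundary (intake questionnaire typing) are excluded.  The report
    filed after opinion *i* is the one at time point *i*+1.
    """
    if not session.boundaries:
        raise ValueError(f"session {session.user_id!r} has no opinion boundaries")
    reports_by_tp = {r.time_point: r for r in session.reports}
    starts = [t for t, _ in session.boundaries]
    ends = starts[1:] + [math.inf]
    segments = []
    for i, ((start, kind), end) in enumerate(zip(session.boundaries, ends)):
        seg_events = [e for e in session.events if start <= e.timestamp_ms < end]
        segments.append(
            OpinionSegment(
                user_id=session.user_id,
                opinion_kind=kind,
                events=seg_events,
                post_report=reports_by_tp.get(i + 1),
            )
        )
    return segments


def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as CSV (full float precision, round-trip safe)."""
    rows = []
    for v in vectors:
        row = {"user_id": v.user_id, "opinion_kind": v.opinion_kind}
        row.update({name: v.values[name] for name in FEATURE_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["user_id", "opinion_kind", *FEATURE_NAMES])
    df.to_csv(path, index=False)  # default float repr is shortest round-trip


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    """Read a feature-table CSV; errors name any missing/extra feature columns."""
    df = pd.read_csv(
        path, dtype={"user_id": str, "opinion_kind": str}, float_precision="round_trip"
    )
    expected = ["user_id", "opinion_kind", *FEATURE_NAMES]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise ValueError(f"feature table schema mismatch: missing={missing} extra={extra}")
    vectors = []
    for _, row in df.iterrows():
        vectors.append(
            FeatureVector(
                user_id=row["user_id"],
                opinion_kind=row["opinion_kind"],
                values={name: float(row[name]) for name in FEATURE_NAMES},
            )
        )
    return vectors
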