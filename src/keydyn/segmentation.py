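"""Pair raw down/up events into key presses and split them at typing pauses.

Nobody types continuously: the event stream of an opinion is cut into
shorter *typing sequences* wherever the idle gap between two consecutive
presses exceeds a threshold (3 s in the study design this package models).
All digraph/trigraph timing statistics are computed within sequences, never
across a pause.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .types import EventType, KeyEvent, KeyPress, TypingSequence


@dataclass
class SegmentationConfig:
    """Idle-splitting parameters.

    idle_threshold_ms
        Maximum within-sequence gap; a strictly larger gap splits the
        stream.  Default 3000 ms.
    gap_mode
        Which gap the threshold applies to.  ``"release_press"`` (default)
        is the flight time: previous key's release to next key's press —
        the standard keystroke-dynamics convention.  ``"press_press"``
        measures press to press instead.
    """

    idle_threshold_ms: int = 3000
    gap_mode: str = "release_press"

    def __post_init__(self) -> None:
        if self.idle_threshold_ms <= 0:
            raise ValueError("idle_threshold_ms must be positive")
        if self.gap_mode not in ("release_press", "press_press"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


def pair_events(events: list[KeyEvent]) -> tuple[list[KeyPress], list[str]]:
    """Match DOWN events to UP events of the same key slot.

    Each DOWN is matched to the earliest subsequent UP with the same
    ``slot_id``.  Rollover (the next key pressed before the previous one is
    released) is normal fast typing, not an error.  Anomalies never raise;
    they are reported as warnings:

    * an UP with no pending DOWN for its slot is dropped;
    * a DOWN that never gets an UP has its release imputed as press time
      plus the median hold of the matched presses in the same batch.

    Returns the presses ordered by press time and the warning list.
    """
    matched: list[tuple[int, KeyPress]] = []  # (emission order, press)
    pending: dict[str, list[tuple[int, KeyEvent]]] = {}
    warnings: list[str] = []
    unmatched: list[tuple[int, KeyEvent]] = []

    for i, ev in enumerate(events):
        if ev.event_type is EventType.DOWN:
            pending.setdefault(ev.slot_id, []).append((i, ev))
        else:
            queue = pending.get(ev.slot_id)
            if not queue:
                warnings.append(
                    f"orphan UP at t={ev.timestamp_ms} ms (slot {ev.slot_id}): dropped"
                )
                continue
            j, down = queue.pop(0)
            matched.append(
                (
                    j,
                    KeyPress(
                        press_ms=down.timestamp_ms,
                        release_ms=ev.timestamp_ms,
                        key_class=down.key_class,
                        capital=bool(down.capital),
                    ),
                )
            )

    for queue in pending.values():
        unmatched.extend(queue)

    if unmatched:
        holds = [p.hold_ms for _, p in matched]
        imputed_hold = int(round(median(holds))) if holds else 0
        for j, down in unmatched:
            warnings.append(
                f"unmatched DOWN at t={down.timestamp_ms} ms (slot {down.slot_id}): "
                f"release imputed at +{imputed_hold} ms"
            )
            matched.append(
                (
                    j,
                    KeyPress(
                        press_ms=down.timestamp_ms,
                        release_ms=down.timestamp_ms + imputed_hold,
                        key_class=down.key_class,
                        capital=bool(down.capital),
                    ),
                )
            )

    # order by press time; emission order breaks ties deterministically
    matched.sort(key=lambda t: (t[1].press_ms, t[0]))
    return [p for _, p in matched], warnings


def split_sequences(
    presses: list[KeyPress],
    raw_events: list[KeyEvent] | None = None,
    config: SegmentationConfig | None = None,
) -> list[TypingSequence]:
    """Split ordered presses into typing sequences at idle gaps.

    The split is made when the gap (release of press *i* to press of press
    *i*+1 by default) strictly exceeds ``config.idle_threshold_ms``; a gap
    exactly equal to the threshold does not split.  Negative gaps (rollover)
    never split.  Every press ends up in exactly one sequence.
    """
    config = config or SegmentationConfig()
    if not presses:
        return []

    groups: list[list[KeyPress]] = [[presses[0]]]
    for prev, cur in zip(presses, presses[1:]):
        start = prev.release_ms if config.gap_mode == "release_press" else prev.press_ms
        if cur.press_ms - start > config.idle_threshold_ms:
            groups.append([cur])
        else:
            groups[-1].append(cur)

    raw_events = raw_events or []
    sequences = []
    for group in groups:
        lo = group[0].press_ms
        hi = max(p.release_ms for p in group)
        span = [e for e in raw_events if lo <= e.timestamp_ms <= hi]
        sequences.append(TypingSequence(presses=group, raw_events=span))
    return sequences
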