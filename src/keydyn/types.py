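"""Core domain types for keystroke-dynamics opinion-writing studies.

The study design these types model: each participant writes four short
opinions (best/worst teacher, best/worst subject) at a standardized
workstation while an anonymizing key logger records one row per key-down /
key-up event.  Between opinions the participant files a Self-Assessment
Manikin (SAM) report of pleasure, arousal and dominance on a 9-point scale
where 1 is the *high* end and 9 the *low* end of each dimension.

Privacy contract: the logger records only the *class* of a key (letter,
digit, space, ...) plus an opaque slot id that lets down/up events be
paired.  Letter and digit identities are never stored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class KeyClass(str, enum.Enum):
    """Anonymized class of a physical key."""

    LETTER = "LETTER"
    DIGIT = "DIGIT"
    SPACE = "SPACE"
    BACKSPACE = "BACKSPACE"
    DEL = "DEL"
    UP = "UP"
    DOWN = "DOWN"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    HOME = "HOME"
    END = "END"
    PGUP = "PGUP"
    PGDN = "PGDN"
    SHIFT_L = "SHIFT_L"
    SHIFT_R = "SHIFT_R"
    CAPSLOCK = "CAPSLOCK"
    PUNCT = "PUNCT"
    OTHER = "OTHER"


class EventType(str, enum.Enum):
    DOWN = "DOWN"
    UP = "UP"


class OpinionKind(str, enum.Enum):
    BEST_TEACHER = "BEST_TEACHER"
    WORST_TEACHER = "WORST_TEACHER"
    BEST_SUBJECT = "BEST_SUBJECT"
    WORST_SUBJECT = "WORST_SUBJECT"


class Valence(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class Topic(str, enum.Enum):
    TEACHER = "TEACHER"
    SUBJECT = "SUBJECT"


#: Valence implied by each opinion kind ("best" prompts are positive).
VALENCE_OF_KIND = {
    OpinionKind.BEST_TEACHER: Valence.POSITIVE,
    OpinionKind.BEST_SUBJECT: Valence.POSITIVE,
    OpinionKind.WORST_TEACHER: Valence.NEGATIVE,
    OpinionKind.WORST_SUBJECT: Valence.NEGATIVE,
}

TOPIC_OF_KIND = {
    OpinionKind.BEST_TEACHER: Topic.TEACHER,
    OpinionKind.WORST_TEACHER: Topic.TEACHER,
    OpinionKind.BEST_SUBJECT: Topic.SUBJECT,
    OpinionKind.WORST_SUBJECT: Topic.SUBJECT,
}


@dataclass(frozen=True)
class KeyEvent:
    """One raw key-down or key-up event.

    ``capital`` is meaningful only for LETTER DOWN events: it records the
    shift/caps state at capture time (it cannot be re-derived after
    anonymization).  ``slot_id`` is an opaque token identifying the physical
    key so that the matching UP can be found without revealing which letter
    or digit it is.
    """

    timestamp_ms: int
    key_class: KeyClass
    slot_id: str
    event_type: EventType
    capital: bool | None = None


@dataclass(frozen=True)
class SelfReport:
    """SAM self-report at one time point (0 = before the first opinion).

    Scale orientation is inverted: 1 = highest, 9 = lowest level of the
    dimension.
    """

    time_point: int
    pleasure: int
    arousal: int
    dominance: int

    def __post_init__(self) -> None:
        for name in ("pleasure", "arousal", "dominance"):
            v = getattr(self, name)
            if not 1 <= v <= 9:
                raise ValueError(f"{name}={v} outside the 9-point scale [1, 9]")
        if self.time_point < 0:
            raise ValueError(f"time_point must be >= 0, got {self.time_point}")


@dataclass
class Session:
    """One participant's full recording: events, opinion boundaries, reports.

    ``boundaries`` holds (timestamp_ms, OpinionKind) pairs marking where each
    opinion starts; events before the first boundary belong to the intake
    questionnaire and are excluded from analysis.
    """

    user_id: str
    events: list[KeyEvent] = field(default_factory=list)
    boundaries: list[tuple[int, OpinionKind]] = field(default_factory=list)
    reports: list[SelfReport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.boundaries]
        if any(b >= a for a, b in zip(ts[1:], ts)):
            raise ValueError("boundary timestamps must be strictly increasing")


@dataclass
class OpinionSegment:
    """The slice of a session assigned to one opinion."""

    user_id: str
    opinion_kind: OpinionKind
    events: list[KeyEvent]
    post_report: SelfReport | None = None

    @property
    def valence_label(self) -> Valence:
        return VALENCE_OF_KIND[self.opinion_kind]

    @property
    def topic_label(self) -> Topic:
        return TOPIC_OF_KIND[self.opinion_kind]


@dataclass(frozen=True)
class KeyPress:
    """A paired key press: down at ``press_ms``, up at ``release_ms``."""

    press_ms: int
    release_ms: int
    key_class: KeyClass
    capital: bool = False

    def __post_init__(self) -> None:
        if self.release_ms < self.press_ms:
            raise ValueError("release_ms must be >= press_ms")

    @property
    def hold_ms(self) -> int:
        return self.release_ms - self.press_ms


@dataclass
class TypingSequence:
    """A pause-free run of key presses (no idle gap above the threshold)."""

    presses: list[KeyPress]
    raw_events: list[KeyEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.presses)
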