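"""The 51 keystroke-dynamics features.

Five groups, computed per opinion segment after idle-gap segmentation:

* **digraph features** (12): mean ``[0]`` and standard deviation ``[1]`` of
  six timing/count parameters over all consecutive press pairs within a
  typing sequence;
* **trigraph features** (18): likewise over consecutive press triples;
* **shift-digraph features** (10): timing of digraphs whose first key is the
  left or right shift, plus the fraction of them where the shift is released
  before the second key ("first shift up");
* **frequency features** (10): per-segment usage rates of spacebar,
  backspace, delete, the four arrows and both shifts, plus the capital-letter
  ratio (CAPS);
* **typing speed** (1): keystrokes per second of elapsed segment time.

Graphs are enumerated within typing sequences only — never across a pause —
and pooled over all sequences of a segment before taking mean and standard
deviation.  The standard deviation uses the population convention (÷n), so a
single graph yields std 0 rather than an undefined value.  A feature whose
underlying pool is empty is *missing* (NaN), never fabricated as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegmentationConfig, pair_events, split_sequences
from .types import KeyClass, KeyEvent, KeyPress, OpinionSegment, TypingSequence

_DIGRAPH_PARAMS = ("di_1D2D", "di_1Dur", "di_1KeyLat", "di_2Dur", "di_Dur", "di_NumEvents")
_TRIGRAPH_PARAMS = (
    "tri_1D2D",
    "tri_1Dur",
    "tri_1KeyLat",
    "tri_2D3D",
    "tri_2Dur",
    "tri_2KeyLat",
    "tri_3Dur",
    "tri_Dur",
    "tri_NumEvents",
)
_SHIFT_PARAMS = ("di_1D2D", "di_Dur")  # per side, prefixed L_/R_

FREQUENCY_FEATURES = (
    "SPACE",
    "BCKSPACE",
    "DEL",
    "UP",
    "DOWN",
    "LEFT",
    "RIGHT",
    "SHIFT_L",
    "SHIFT_R",
    "CAPS",
)

#: key class counted by each count-based frequency feature
_FREQ_KEY_CLASS = {
    "SPACE": KeyClass.SPACE,
    "BCKSPACE": KeyClass.BACKSPACE,
    "DEL": KeyClass.DEL,
    "UP": KeyClass.UP,
    "DOWN": KeyClass.DOWN,
    "LEFT": KeyClass.LEFT,
    "RIGHT": KeyClass.RIGHT,
    "SHIFT_L": KeyClass.SHIFT_L,
    "SHIFT_R": KeyClass.SHIFT_R,
}


def _mean_std_names(params: tuple[str, ...]) -> list[str]:
    return [f"{p}[{i}]" for p in params for i in (0, 1)]


#: The 51 canonical feature names, in serialization (and tie-break) order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    _mean_std_names(_DIGRAPH_PARAMS)
    + _mean_std_names(_TRIGRAPH_PARAMS)
    + _mean_std_names(tuple(f"L_{p}" for p in _SHIFT_PARAMS))
    + ["L_first_shift_up"]
    + _mean_std_names(tuple(f"R_{p}" for p in _SHIFT_PARAMS))
    + ["R_first_shift_up"]
    + list(FREQUENCY_FEATURES)
    + ["SPEED"]
)

assert len(FEATURE_NAMES) == 51


@dataclass
class FeatureConfig:
    """Feature-extraction knobs.

    caps_mode
        ``"capital_ratio"`` (default): CAPS = capital letters ÷ letters.
        ``"capslock_count"``: CAPS = caps-lock presses ÷ total presses.
    speed_mode
        ``"elapsed"`` (default): SPEED denominator is last-minus-first event
        time of the segment.  ``"active"``: sum of typing-sequence spans.
    segmentation
        Idle-split settings applied before graph enumeration.
    """

    caps_mode: str = "capital_ratio"
    speed_mode: str = "elapsed"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        if self.caps_mode not in ("capital_ratio", "capslock_count"):
            raise ValueError(f"unknown caps_mode {self.caps_mode!r}")
        if self.speed_mode not in ("elapsed", "active"):
            raise ValueError(f"unknown speed_mode {self.speed_mode!r}")


@dataclass
class GraphRecord:
    """Timing parameters of one digraph or trigraph.

    ``t1KeyLat`` (and ``t2KeyLat``) may be negative under rollover.
    ``numEvents`` counts every raw down/up event whose timestamp falls in the
    closed window from the first press to the last release of the graph —
    usually 4 for a digraph and 6 for a trigraph, more when other keys are
    interleaved by fast typing.
    """

    t1D2D: float
    t1Dur: float
    t1KeyLat: float
    t2Dur: float
    tDur: float
    numEvents: int
    t2D3D: float | None = None
    t2KeyLat: float | None = None
    t3Dur: float | None = None


@dataclass
class FeatureVector:
    """The 51 features of one opinion segment (or one whole-session baseline).

    ``values`` maps each name in :data:`FEATURE_NAMES` to a float; missing
    features are ``nan``.  The three counts are diagnostics, not features.
    """

    user_id: str
    opinion_kind: str
    values: dict[str, float]
    n_keystrokes: int = 0
    n_digraphs: int = 0
    n_trigraphs: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(f"feature schema mismatch: missing={missing} extra={extra}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def _num_events(timestamps: np.ndarray, lo: int, hi: int) -> int:
    return int(np.searchsorted(timestamps, hi, side="right") - np.searchsorted(timestamps, lo, side="left"))


def enumerate_digraphs(seq: TypingSequence) -> list[GraphRecord]:
    """One record per consecutive press pair of the sequence."""
    ts = np.array(sorted(e.timestamp_ms for e in seq.raw_events))
    out = []
    for a, b in zip(seq.presses, seq.presses[1:]):
        out.append(
            GraphRecord(
                t1D2D=b.press_ms - a.press_ms,
                t1Dur=a.hold_ms,
                t1KeyLat=b.press_ms - a.release_ms,
                t2Dur=b.hold_ms,
                tDur=b.release_ms - a.press_ms,
                numEvents=_num_events(ts, a.press_ms, b.release_ms),
            )
        )
    return out


def enumerate_trigraphs(seq: TypingSequence) -> list[GraphRecord]:
    """One record per consecutive press triple of the sequence."""
    ts = np.array(sorted(e.timestamp_ms for e in seq.raw_events))
    out = []
    for a, b, c in zip(seq.presses, seq.presses[1:], seq.presses[2:]):
        out.append(
            GraphRecord(
                t1D2D=b.press_ms - a.press_ms,
                t1Dur=a.hold_ms,
                t1KeyLat=b.press_ms - a.release_ms,
                t2Dur=b.hold_ms,
                tDur=c.release_ms - a.press_ms,
                numEvents=_num_events(ts, a.press_ms, c.release_ms),
                t2D3D=c.press_ms - b.press_ms,
                t2KeyLat=c.press_ms - b.release_ms,
                t3Dur=c.hold_ms,
            )
        )
    return out


def enumerate_shift_digraphs(
    seq: TypingSequence,
) -> tuple[list[tuple[float, float, bool]], list[tuple[float, float, bool]]]:
    """Digraphs whose first press is a shift key.

    Returns per side (left, right) a list of ``(t1D2D, tDur, first_shift_up)``
    where ``first_shift_up`` is True when the shift's release strictly
    precedes the second key's release.  Shift-starting digraphs remain in the
    general digraph pool as well; this routes them *additionally* to the
    shift features.
    """
    left: list[tuple[float, float, bool]] = []
    right: list[tuple[float, float, bool]] = []
    for a, b in zip(seq.presses, seq.presses[1:]):
        if a.key_class not in (KeyClass.SHIFT_L, KeyClass.SHIFT_R):
            continue
        rec = (
            float(b.press_ms - a.press_ms),
            float(b.release_ms - a.press_ms),
            a.release_ms < b.release_ms,
        )
        (left if a.key_class is KeyClass.SHIFT_L else right).append(rec)
    return left, right


def frequency_features(
    presses: list[KeyPress], config: FeatureConfig | None = None
) -> dict[str, float]:
    """Usage-rate features: key-class counts over total presses, and CAPS.

    CAPS defaults to capital letters ÷ letters (missing when the segment has
    no letters); the ``capslock_count`` mode counts caps-lock presses over
    total presses instead.
    """
    config = config or FeatureConfig()
    out = {name: math.nan for name in FREQUENCY_FEATURES}
    n = len(presses)
    if n == 0:
        return out
    for name, kc in _FREQ_KEY_CLASS.items():
        out[name] = sum(1 for p in presses if p.key_class is kc) / n
    if config.caps_mode == "capslock_count":
        out["CAPS"] = sum(1 for p in presses if p.key_class is KeyClass.CAPSLOCK) / n
    else:
        letters = [p for p in presses if p.key_class is KeyClass.LETTER]
        if letters:
            out["CAPS"] = sum(1 for p in letters if p.capital) / len(letters)
    return out


def typing_speed(events: list[KeyEvent], n_presses: int) -> float:
    """Key presses per second of elapsed time (first to last event)."""
    if len(events) < 2:
        return math.nan
    span_ms = events[-1].timestamp_ms - events[0].timestamp_ms
    if span_ms <= 0:
        return math.nan
    return n_presses / (span_ms / 1000.0)


def _pool_stats(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def features_from_event_groups(
    groups: list[list[KeyEvent]],
    user_id: str = "",
    opinion_kind: str = "",
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Compute the 51 features over one or more event groups.

    A single group is an ordinary opinion segment.  Multiple groups give the
    whole-session baseline: graphs and sequences are computed within each
    group (they never span the gap between opinions) and then pooled, as if
    the session were one long typing phase.
    """
    config = config or FeatureConfig()

    digraph_pools: dict[str, list[float]] = {p: [] for p in _DIGRAPH_PARAMS}
    trigraph_pools: dict[str, list[float]] = {p: [] for p in _TRIGRAPH_PARAMS}
    shift_pools = {
        "L": {"di_1D2D": [], "di_Dur": [], "up": []},
        "R": {"di_1D2D": [], "di_Dur": [], "up": []},
    }
    all_presses: list[KeyPress] = []
    speed_num = 0
    speed_den_ms = 0
    n_digraphs = n_trigraphs = 0

    for events in groups:
        events = sorted(events, key=lambda e: e.timestamp_ms)
        presses, _ = pair_events(events)
        all_presses.extend(presses)
        sequences = split_sequences(presses, events, config.segmentation)
        for seq in sequences:
            for rec in enumerate_digraphs(seq):
                n_digraphs += 1
                digraph_pools["di_1D2D"].append(rec.t1D2D)
                digraph_pools["di_1Dur"].append(rec.t1Dur)
                digraph_pools["di_1KeyLat"].append(rec.t1KeyLat)
                digraph_pools["di_2Dur"].append(rec.t2Dur)
                digraph_pools["di_Dur"].append(rec.tDur)
                digraph_pools["di_NumEvents"].append(rec.numEvents)
            for rec in enumerate_trigraphs(seq):
                n_trigraphs += 1
                trigraph_pools["tri_1D2D"].append(rec.t1D2D)
                trigraph_pools["tri_1Dur"].append(rec.t1Dur)
                trigraph_pools["tri_1KeyLat"].append(rec.t1KeyLat)
                trigraph_pools["tri_2D3D"].append(rec.t2D3D)
                trigraph_pools["tri_2Dur"].append(rec.t2Dur)
                trigraph_pools["tri_2KeyLat"].append(rec.t2KeyLat)
                trigraph_pools["tri_3Dur"].append(rec.t3Dur)
                trigraph_pools["tri_Dur"].append(rec.tDur)
                trigraph_pools["tri_NumEvents"].append(rec.numEvents)
            left, right = enumerate_shift_digraphs(seq)
            for side, recs in (("L", left), ("R", right)):
                for d1d2, dur, up in recs:
                    shift_pools[side]["di_1D2D"].append(d1d2)
                    shift_pools[side]["di_Dur"].append(dur)
                    shift_pools[side]["up"].append(1.0 if up else 0.0)
        if config.speed_mode == "elapsed":
            if len(events) >= 2:
                speed_num += len(presses)
                speed_den_ms += events[-1].timestamp_ms - events[0].timestamp_ms
        else:
            for seq in sequences:
                speed_num += len(seq.presses)
                speed_den_ms += max(p.release_ms for p in seq.presses) - seq.presses[0].press_ms

    values: dict[str, float] = {}
    for p in _DIGRAPH_PARAMS:
        values[f"{p}[0]"], values[f"{p}[1]"] = _pool_stats(digraph_pools[p])
    for p in _TRIGRAPH_PARAMS:
        values[f"{p}[0]"], values[f"{p}[1]"] = _pool_stats(trigraph_pools[p])
    for side in ("L", "R"):
        for p in _SHIFT_PARAMS:
            values[f"{side}_{p}[0]"], values[f"{side}_{p}[1]"] = _pool_stats(shift_pools[side][p])
        ups = shift_pools[side]["up"]
        values[f"{side}_first_shift_up"] = float(np.mean(ups)) if ups else math.nan

    values.update(frequency_features(all_presses, config))
    values["SPEED"] = speed_num / (speed_den_ms / 1000.0) if speed_den_ms > 0 else math.nan

    return FeatureVector(
        user_id=user_id,
        opinion_kind=opinion_kind,
        values=values,
        n_keystrokes=len(all_presses),
        n_digraphs=n_digraphs,
        n_trigraphs=n_trigraphs,
    )


def build_feature_vector(
    segment: OpinionSegment, config: FeatureConfig | None = None
) -> FeatureVector:
    """Feature vector of a single opinion segment."""
    return features_from_event_groups(
        [segment.events],
        user_id=segment.user_id,
        opinion_kind=segment.opinion_kind.value,
        config=config,
    )
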