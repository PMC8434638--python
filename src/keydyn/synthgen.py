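"""Synthetic opinion-writing studies with known ground truth.

Emulates the capture setting of a 49-participant lab study: every
participant types four opinions (best/worst teacher, best/worst subject) on
an anonymizing key logger and files a 9-point SAM self-report before the
first opinion and after each one.

Timing model: per-user log-normal hold and flight (release-to-next-press)
times — the common empirical shape of keystroke latencies — plus a pause
process that occasionally inserts an idle gap above the 3 s split threshold,
occasional rollover (negative flights), special-key usage, and shift-preceded
capital letters.  A configurable :class:`EffectSpec` injects condition
effects into the NEGATIVE (worst-*) opinions: multiplicative slowdown of
flights, a shift in spacebar probability, extra latency dispersion, and
condition-dependent self-report distributions.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    KeyClass,
    KeyEvent,
    EventType,
    OpinionKind,
    SelfReport,
    Session,
    Valence,
    VALENCE_OF_KIND,
)

IDLE_THRESHOLD_MS = 3000

#: Self-report distribution per dimension and context: (mean, sd) on the
#: inverted 9-point scale (1 = high).  Condition means mirror the sample
#: means observed in the motivating study; the baseline (time point 0) is a
#: neutral pre-task state.
DEFAULT_REPORT_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "pleasure": {"POSITIVE": (3.24, 2.0), "NEGATIVE": (4.14, 2.0), "BASELINE": (4.0, 1.5)},
    "arousal": {"POSITIVE": (4.97, 2.0), "NEGATIVE": (4.36, 2.0), "BASELINE": (5.0, 1.5)},
    "dominance": {"POSITIVE": (5.67, 2.0), "NEGATIVE": (5.63, 2.0), "BASELINE": (5.6, 1.5)},
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth condition effects applied to NEGATIVE opinions.

    speed_factor
        Multiplier on flight times (>1 = slower typing when negative).
    space_delta
        Additive shift of the spacebar probability.
    latency_jitter
        Extra log-normal dispersion added to the flight sigma.
    report_model
        (mean, sd) of the discretized truncated normal generating each
        report dimension per condition.
    """

    speed_factor: float = 1.15
    space_delta: float = -0.02
    latency_jitter: float = 0.0
    report_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REPORT_MODEL.items()}
    )

    def __post_init__(self) -> None:
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No condition effect at all (identical generating law everywhere)."""
        neutral = {
            dim: {ctx: DEFAULT_REPORT_MODEL[dim]["BASELINE"] for ctx in ("POSITIVE", "NEGATIVE", "BASELINE")}
            for dim in DEFAULT_REPORT_MODEL
        }
        return cls(speed_factor=1.0, space_delta=0.0, latency_jitter=0.0, report_model=neutral)


@dataclass(frozen=True)
class UserProfile:
    """Per-user typing style drawn from population hyper-distributions."""

    user_id: str
    hold_median_ms: float
    hold_sigma: float
    flight_median_ms: float
    flight_sigma: float
    pause_prob: float
    pause_scale_ms: float
    rollover_prob: float
    space_prob: float
    backspace_prob: float
    del_prob: float
    arrow_prob: float
    capital_rate: float
    left_shift_pref: float
    seed: int

    def __post_init__(self) -> None:
        if self.hold_median_ms <= 0 or self.flight_median_ms <= 0:
            raise ValueError("timing medians must be positive")
        special = self.space_prob + self.backspace_prob + self.del_prob + self.arrow_prob
        if special >= 1.0:
            raise ValueError("special-key probabilities must sum below 1")


def generate_user(seed: int, user_id: str | None = None) -> UserProfile:
    """Draw one user's typing profile; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return UserProfile(
        user_id=user_id if user_id is not None else f"u{seed}",
        hold_median_ms=float(np.exp(rng.normal(np.log(95.0), 0.15))),
        hold_sigma=float(rng.uniform(0.25, 0.40)),
        flight_median_ms=float(np.exp(rng.normal(np.log(170.0), 0.25))),
        flight_sigma=float(rng.uniform(0.40, 0.60)),
        pause_prob=float(rng.uniform(0.01, 0.04)),
        pause_scale_ms=2000.0,
        rollover_prob=float(rng.uniform(0.03, 0.10)),
        space_prob=float(np.clip(rng.normal(0.16, 0.02), 0.08, 0.24)),
        backspace_prob=float(rng.uniform(0.02, 0.08)),
        del_prob=float(rng.uniform(0.0, 0.01)),
        arrow_prob=float(rng.uniform(0.0, 0.02)),
        capital_rate=float(rng.uniform(0.02, 0.06)),
        left_shift_pref=float(rng.uniform(0.2, 0.8)),
        seed=int(seed),
    )


_ARROWS = (KeyClass.UP, KeyClass.DOWN, KeyClass.LEFT, KeyClass.RIGHT)
_SLOT = {
    KeyClass.SPACE: "SP",
    KeyClass.BACKSPACE: "BS",
    KeyClass.DEL: "DL",
    KeyClass.UP: "AU",
    KeyClass.DOWN: "AD",
    KeyClass.LEFT: "AL",
    KeyClass.RIGHT: "AR",
    KeyClass.SHIFT_L: "SL",
    KeyClass.SHIFT_R: "SR",
}


def generate_segment(
    profile: UserProfile,
    condition: Valence,
    n_keystrokes: int,
    rng: np.random.Generator,
    effect: EffectSpec | None = None,
    t_start: int = 0,
) -> list[KeyEvent]:
    """One opinion's raw DOWN/UP event stream.

    ``n_keystrokes`` counts ordinary presses; shift presses preceding capital
    letters come on top.  Events are returned time-sorted with integer
    millisecond stamps starting at ``t_start``.
    """
    if n_keystrokes < 2:
        raise ValueError("n_keystrokes must be >= 2")
    effect = effect or EffectSpec()
    negative = condition is Valence.NEGATIVE
    flight_mu = np.log(profile.flight_median_ms) + (np.log(effect.speed_factor) if negative else 0.0)
    flight_sigma = profile.flight_sigma + (effect.latency_jitter if negative else 0.0)
    space_p = np.clip(profile.space_prob + (effect.space_delta if negative else 0.0), 0.01, 0.5)

    # vector draws up front; assembly is a single ordered pass
    holds = np.exp(rng.normal(np.log(profile.hold_median_ms), profile.hold_sigma, n_keystrokes))
    flights = np.exp(rng.normal(flight_mu, flight_sigma, n_keystrokes))
    rollover = rng.random(n_keystrokes) < profile.rollover_prob
    flights[rollover] = -rng.uniform(5.0, 50.0, int(rollover.sum()))
    pauses = rng.random(n_keystrokes) < profile.pause_prob
    flights[pauses] = IDLE_THRESHOLD_MS + rng.exponential(profile.pause_scale_ms, int(pauses.sum()))

    probs = np.array([space_p, profile.backspace_prob, profile.del_prob, profile.arrow_prob])
    choice = rng.random(n_keystrokes)
    arrows = rng.integers(0, 4, n_keystrokes)
    capitals = rng.random(n_keystrokes) < profile.capital_rate
    shift_left = rng.random(n_keystrokes) < profile.left_shift_pref
    shift_lead = rng.uniform(60.0, 140.0, n_keystrokes)
    shift_early = rng.random(n_keystrokes) < 0.5
    letter_slots = rng.integers(0, 26, n_keystrokes)

    events: list[KeyEvent] = []
    prev_press = float(t_start)
    prev_release = None
    prev_letter_slot = -1
    for i in range(n_keystrokes):
        if prev_release is None:
            t_press = float(t_start)
        else:
            # rollover makes flights negative but never reorders presses
            t_press = max(prev_release + flights[i], prev_press + 1.0)
        c = choice[i]
        if c < probs[0]:
            kc = KeyClass.SPACE
        elif c < probs[:2].sum():
            kc = KeyClass.BACKSPACE
        elif c < probs[:3].sum():
            kc = KeyClass.DEL
        elif c < probs.sum():
            kc = _ARROWS[arrows[i]]
        else:
            kc = KeyClass.LETTER
        capital = kc is KeyClass.LETTER and bool(capitals[i])
        release = t_press + holds[i]

        if capital:
            side = KeyClass.SHIFT_L if shift_left[i] else KeyClass.SHIFT_R
            s_down = max(t_press - shift_lead[i], float(t_start))
            # shift released either between the letter's press and release or after
            s_up = t_press + 0.5 * holds[i] if shift_early[i] else release + rng.uniform(10.0, 60.0)
            slot = _SLOT[side]
            events.append(KeyEvent(int(round(s_down)), side, slot, EventType.DOWN))
            events.append(KeyEvent(int(round(s_up)), side, slot, EventType.UP))
        if kc is KeyClass.LETTER:
            s = int(letter_slots[i])
            if s == prev_letter_slot:  # avoid re-pressing a possibly held key
                s = (s + 1) % 26
            prev_letter_slot = s
            slot = f"K{s:02d}"
        else:
            prev_letter_slot = -1
            slot = _SLOT[kc]
        events.append(
            KeyEvent(int(round(t_press)), kc, slot, EventType.DOWN, capital if kc is KeyClass.LETTER else None)
        )
        events.append(KeyEvent(int(round(release)), kc, slot, EventType.UP))
        prev_release = release
        prev_press = t_press

    events.sort(key=lambda e: e.timestamp_ms)
    return events


def _draw_report(rng: np.random.Generator, model, context: str) -> SelfReport:
    vals = {}
    for dim in ("pleasure", "arousal", "dominance"):
        mean, sd = model[dim][context]
        v = int(np.clip(round(rng.normal(mean, sd)), 1, 9))
        vals[dim] = v
    return SelfReport(time_point=0, **vals)  # time_point patched by caller


def generate_session(
    profile: UserProfile,
    effect: EffectSpec,
    rng: np.random.Generator,
    n_keystrokes_mean: int = 250,
) -> Session:
    """One participant's full session: 4 opinions in random order + 5 reports."""
    kinds = list(OpinionKind)
    rng.shuffle(kinds)

    events: list[KeyEvent] = []
    boundaries: list[tuple[int, OpinionKind]] = []
    # intake questionnaire typing before the first boundary (excluded downstream)
    events.extend(
        generate_segment(profile, Valence.POSITIVE, 15, rng, EffectSpec.null(), t_start=0)
    )
    t = events[-1].timestamp_ms + int(rng.integers(20_000, 60_000))

    reports = [_draw_report(rng, effect.report_model, "BASELINE")]
    for kind in kinds:
        boundaries.append((t, kind))
        n = max(30, int(rng.poisson(n_keystrokes_mean)))
        seg = generate_segment(
            profile, VALENCE_OF_KIND[kind], n, rng, effect, t_start=t + int(rng.integers(500, 3000))
        )
        events.extend(seg)
        reports.append(_draw_report(rng, effect.report_model, VALENCE_OF_KIND[kind].value))
        t = seg[-1].timestamp_ms + int(rng.integers(30_000, 90_000))

    reports = [
        SelfReport(time_point=i, pleasure=r.pleasure, arousal=r.arousal, dominance=r.dominance)
        for i, r in enumerate(reports)
    ]
    events.sort(key=lambda e: e.timestamp_ms)
    return Session(
        user_id=profile.user_id,
        events=events,
        boundaries=boundaries,
        reports=reports,
    )


def generate_study(
    n_users: int = 49,
    effect: EffectSpec | None = None,
    seed: int = 0,
    n_keystrokes_mean: int = 250,
) -> list[Session]:
    """A complete synthetic study: ``n_users`` sessions, 4 opinions each.

    Fully reproducible from ``seed``; per-user streams are independently
    spawned so adding users never reshuffles existing ones.
    """
    if n_users < 1:
        raise ValueError("n_users must be >= 1")
    effect = effect or EffectSpec()
    root = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(root.spawn(n_users)):
        profile_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        profile = generate_user(profile_seed, user_id=f"u{i:03d}")
        rng = np.random.default_rng(child.spawn(1)[0])
        sessions.append(generate_session(profile, effect, rng, n_keystrokes_mean))
    return sessions
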