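from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from keydyn.types import EventType, KeyClass, KeyEvent

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ev(t: int, kc: KeyClass, slot: str, etype: EventType, capital=None) -> KeyEvent:
    return KeyEvent(t, kc, slot, etype, capital)


def press_events(specs) -> list[KeyEvent]:
    """Build a DOWN/UP stream from (press, release, key_class[, capital]) tuples."""
    events = []
    for i, spec in enumerate(specs):
        press, release, kc = spec[:3]
        capital = spec[3] if len(spec) > 3 else None
        slot = f"s{i}"
        events.append(ev(press, kc, slot, EventType.DOWN, capital))
        events.append(ev(release, kc, slot, EventType.UP))
    return sorted(events, key=lambda e: e.timestamp_ms)


@pytest.fixture
def simple_typing_events():
    """Three non-overlapping letter presses: (0,100), (150,260), (300,420)."""
    return press_events([(0, 100, KeyClass.LETTER), (150, 260, KeyClass.LETTER), (300, 420, KeyClass.LETTER)])


@pytest.fixture(scope="session")
def small_study():
    """A 6-user synthetic study shared by read-only tests."""
    from keydyn.synthgen import EffectSpec, generate_study

    return generate_study(n_users=6, effect=EffectSpec(speed_factor=1.2), seed=42, n_keystrokes_mean=120)


@pytest.fixture(scope="session")
def small_dataset(small_study):
    from keydyn.dataset import build_dataset

    return build_dataset(small_study)
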