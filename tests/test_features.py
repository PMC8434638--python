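"""Digraph/trigraph/shift/frequency/speed feature extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from keydyn import (
    FEATURE_NAMES,
    FeatureConfig,
    features_from_event_groups,
    frequency_features,
    pair_events,
    split_sequences,
)
from keydyn.features import enumerate_digraphs, enumerate_shift_digraphs, enumerate_trigraphs
from keydyn.types import KeyClass, KeyEvent, KeyPress

from .conftest import press_events
from .oracles import brute_features

L = KeyClass.LETTER


def _seq(specs):
    events = press_events(specs)
    presses, _ = pair_events(events)
    (seq,) = split_sequences(presses, events)
    return seq


def test_digraph_hand_trace():
    seq = _seq([(0, 100, L), (150, 260, L), (300, 420, L)])
    recs = enumerate_digraphs(seq)
    assert [r.t1D2D for r in recs] == [150, 150]
    assert [r.t1KeyLat for r in recs] == [50, 40]
    assert [r.tDur for r in recs] == [260, 270]
    assert [r.numEvents for r in recs] == [4, 4]


def test_trigraph_hand_trace():
    seq = _seq([(0, 100, L), (150, 260, L), (300, 420, L)])
    (rec,) = enumerate_trigraphs(seq)
    assert rec.t1D2D == 150 and rec.t2D3D == 150
    assert rec.t2KeyLat == 40 and rec.t3Dur == 120
    assert rec.tDur == 420 and rec.numEvents == 6


def test_rollover_digraph_negative_latency():
    seq = _seq([(0, 120, L), (80, 200, L)])
    (rec,) = enumerate_digraphs(seq)
    assert rec.t1KeyLat == -40 and rec.numEvents == 4


def test_interleaved_key_inflates_num_events():
    # third key pressed inside the first digraph's span
    events = press_events([(0, 100, L), (150, 260, L), (90, 95, KeyClass.PUNCT)])
    presses, _ = pair_events(events)
    (seq,) = split_sequences(presses, events)
    recs = enumerate_digraphs(seq)
    assert any(r.numEvents > 4 for r in recs)


def test_too_few_presses_give_empty_graphs():
    seq = _seq([(0, 100, L), (150, 260, L)])
    assert enumerate_trigraphs(seq) == []
    one = _seq([(0, 100, L)])
    assert enumerate_digraphs(one) == []


def test_shift_digraph_first_shift_up():
    late = _seq([(0, 300, KeyClass.SHIFT_L), (100, 200, L)])
    left, right = enumerate_shift_digraphs(late)
    assert right == []
    assert left == [(100.0, 200.0, False)]
    early = _seq([(0, 150, KeyClass.SHIFT_L), (100, 200, L)])
    left, _ = enumerate_shift_digraphs(early)
    assert left == [(100.0, 200.0, True)]


def test_frequency_features_ratios():
    presses = [KeyPress(i * 200, i * 200 + 50, KeyClass.SPACE if i < 2 else L) for i in range(10)]
    freqs = frequency_features(presses)
    assert freqs["SPACE"] == pytest.approx(0.2)
    assert freqs["UP"] == 0 and freqs["LEFT"] == 0


def test_caps_ratio_and_capslock_mode():
    presses = [KeyPress(i * 200, i * 200 + 50, L, capital=(i == 0)) for i in range(5)]
    presses.append(KeyPress(1000, 1050, KeyClass.CAPSLOCK))
    assert frequency_features(presses)["CAPS"] == pytest.approx(0.2)
    alt = frequency_features(presses, FeatureConfig(caps_mode="capslock_count"))
    assert alt["CAPS"] == pytest.approx(1 / 6)


def test_speed_and_scaling_identity():
    specs = [(i * 500, i * 500 + 100, L) for i in range(10)]  # spans 4.6 s
    v = features_from_event_groups([press_events(specs)])
    assert v.values["SPEED"] == pytest.approx(10 / 4.6)
    doubled = [(2 * p, 2 * r, kc) for p, r, kc in specs]
    v2 = features_from_event_groups([press_events(doubled)])
    assert v2.values["SPEED"] == pytest.approx(v.values["SPEED"] / 2)


def test_identical_timings_give_zero_std():
    specs = [(i * 250, i * 250 + 100, L) for i in range(6)]
    v = features_from_event_groups([press_events(specs)])
    for name in ("di_1D2D[1]", "di_Dur[1]", "tri_2D3D[1]", "tri_Dur[1]"):
        assert v.values[name] == 0.0


def test_empty_pools_are_missing_not_zero():
    v = features_from_event_groups([press_events([(0, 100, L), (150, 250, L)])])
    assert math.isnan(v.values["L_first_shift_up"])
    assert math.isnan(v.values["tri_Dur[0]"])  # only 2 presses: no trigraphs
    assert not math.isnan(v.values["di_Dur[0]"])
    empty = features_from_event_groups([[]])
    assert all(math.isnan(x) for x in empty.values.values())


def test_graph_counts(small_study):
    from keydyn.keylog_io import slice_session

    seg = slice_session(small_study[0])[0]
    v = features_from_event_groups([seg.events])
    presses, _ = pair_events(sorted(seg.events, key=lambda e: e.timestamp_ms))
    seqs = split_sequences(presses, seg.events)
    assert v.n_keystrokes == len(presses)
    assert v.n_digraphs == sum(max(len(s) - 1, 0) for s in seqs)
    assert v.n_trigraphs == sum(max(len(s) - 2, 0) for s in seqs)


def _assert_matches_oracle(groups):
    got = features_from_event_groups(groups).values
    want = brute_features(groups)
    assert set(got) == set(want) == set(FEATURE_NAMES)
    for name in FEATURE_NAMES:
        a, b = got[name], want[name]
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9), name


@pytest.mark.parametrize(
    "specs",
    [
        [(0, 100, L), (150, 260, L), (300, 420, L)],
        [(0, 120, L), (80, 200, L), (210, 280, KeyClass.SPACE), (5000, 5100, L), (5200, 5300, L)],
        [(0, 300, KeyClass.SHIFT_L, None), (100, 200, L, True), (400, 480, L), (600, 700, KeyClass.BACKSPACE)],
        [(0, 150, KeyClass.SHIFT_R), (100, 200, L, True), (9000, 9100, L), (9150, 9250, L), (9300, 9400, L)],
    ],
)
def test_oracle_equivalence_on_handmade_fixtures(specs):
    """Every feature equals an independent brute-force recomputation."""
    _assert_matches_oracle([press_events(specs)])


def test_oracle_equivalence_on_synthetic_small_segments():
    """Random <=30-event segments from the generator match the oracle exactly."""
    from keydyn.synthgen import EffectSpec, generate_segment, generate_user
    from keydyn.types import Valence

    for seed in range(8):
        profile = generate_user(seed)
        rng = np.random.default_rng(seed)
        events = generate_segment(profile, Valence.NEGATIVE, 12, rng, EffectSpec(speed_factor=1.3))
        assert len(events) <= 30
        _assert_matches_oracle([events])


def test_oracle_equivalence_pooled_baseline_groups():
    groups = [
        press_events([(0, 100, L), (150, 260, L), (300, 420, L)]),
        press_events([(0, 90, L), (200, 310, KeyClass.SPACE), (340, 400, L), (450, 520, L)]),
    ]
    _assert_matches_oracle(groups)


def test_time_shift_invariance():
    specs = [(0, 120, L), (80, 200, L), (400, 480, KeyClass.SPACE), (5000, 5100, L)]
    base = features_from_event_groups([press_events(specs)]).values
    shifted_events = [
        KeyEvent(e.timestamp_ms + 123456, e.key_class, e.slot_id, e.event_type, e.capital)
        for e in press_events(specs)
    ]
    shifted = features_from_event_groups([shifted_events]).values
    for name in FEATURE_NAMES:
        a, b = base[name], shifted[name]
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-12)
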