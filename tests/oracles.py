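"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions, with plain loops and the
statistics module, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math
from statistics import median

import numpy as np

from keydyn.types import EventType, KeyClass


def _pop_mean_std(vals):
    if not vals:
        return math.nan, math.nan
    m = sum(vals) / len(vals)
    var = sum((v - m) ** 2 for v in vals) / len(vals)
    return m, math.sqrt(var)


def brute_pair(events):
    """Pairing by definition: earliest later UP with the same slot."""
    events = sorted(enumerate(events), key=lambda t: (t[1].timestamp_ms, t[0]))
    used = set()
    presses = []
    downs = []
    for i, (orig, ev) in enumerate(events):
        if ev.event_type is EventType.UP:
            continue
        downs.append((i, orig, ev))
        rel = None
        for j in range(i + 1, len(events)):
            _, up = events[j]
            if j in used or up.event_type is not EventType.UP or up.slot_id != ev.slot_id:
                continue
            rel = up.timestamp_ms
            used.add(j)
            break
        presses.append(
            {
                "order": orig,
                "press": ev.timestamp_ms,
                "release": rel,  # None = unmatched, imputed below
                "key_class": ev.key_class,
                "capital": bool(ev.capital),
            }
        )
    holds = [p["release"] - p["press"] for p in presses if p["release"] is not None]
    imputed = int(round(median(holds))) if holds else 0
    for p in presses:
        if p["release"] is None:
            p["release"] = p["press"] + imputed
    presses.sort(key=lambda p: (p["press"], p["order"]))
    return presses


def brute_split(presses, threshold=3000):
    """Sequence splitting by definition: flight gap strictly above threshold."""
    if not presses:
        return []
    seqs = [[presses[0]]]
    for prev, cur in zip(presses, presses[1:]):
        if cur["press"] - prev["release"] > threshold:
            seqs.append([cur])
        else:
            seqs[-1].append(cur)
    return seqs


def brute_features(event_groups, threshold=3000):
    """Recompute all 51 features from raw events, by definition."""
    di = {k: [] for k in ("1D2D", "1Dur", "1KeyLat", "2Dur", "Dur", "NumEvents")}
    tri = {k: [] for k in ("1D2D", "1Dur", "1KeyLat", "2D3D", "2Dur", "2KeyLat", "3Dur", "Dur", "NumEvents")}
    shift = {"L": {"1D2D": [], "Dur": [], "up": []}, "R": {"1D2D": [], "Dur": [], "up": []}}
    all_presses = []
    speed_presses, speed_ms = 0, 0

    for events in event_groups:
        ts_all = sorted(e.timestamp_ms for e in events)

        def nev(lo, hi):
            return sum(1 for t in ts_all if lo <= t <= hi)

        presses = brute_pair(events)
        all_presses.extend(presses)
        for seq in brute_split(presses, threshold):
            for a, b in zip(seq, seq[1:]):
                di["1D2D"].append(b["press"] - a["press"])
                di["1Dur"].append(a["release"] - a["press"])
                di["1KeyLat"].append(b["press"] - a["release"])
                di["2Dur"].append(b["release"] - b["press"])
                di["Dur"].append(b["release"] - a["press"])
                di["NumEvents"].append(nev(a["press"], b["release"]))
                if a["key_class"] in (KeyClass.SHIFT_L, KeyClass.SHIFT_R):
                    side = "L" if a["key_class"] is KeyClass.SHIFT_L else "R"
                    shift[side]["1D2D"].append(b["press"] - a["press"])
                    shift[side]["Dur"].append(b["release"] - a["press"])
                    shift[side]["up"].append(1.0 if a["release"] < b["release"] else 0.0)
            for a, b, c in zip(seq, seq[1:], seq[2:]):
                tri["1D2D"].append(b["press"] - a["press"])
                tri["1Dur"].append(a["release"] - a["press"])
                tri["1KeyLat"].append(b["press"] - a["release"])
                tri["2D3D"].append(c["press"] - b["press"])
                tri["2Dur"].append(b["release"] - b["press"])
                tri["2KeyLat"].append(c["press"] - b["release"])
                tri["3Dur"].append(c["release"] - c["press"])
                tri["Dur"].append(c["release"] - a["press"])
                tri["NumEvents"].append(nev(a["press"], c["release"]))
        if len(events) >= 2:
            speed_presses += len(presses)
            speed_ms += ts_all[-1] - ts_all[0]

    out = {}
    for k, vals in di.items():
        out[f"di_{k}[0]"], out[f"di_{k}[1]"] = _pop_mean_std(vals)
    for k, vals in tri.items():
        out[f"tri_{k}[0]"], out[f"tri_{k}[1]"] = _pop_mean_std(vals)
    for side in ("L", "R"):
        for k in ("1D2D", "Dur"):
            out[f"{side}_di_{k}[0]"], out[f"{side}_di_{k}[1]"] = _pop_mean_std(shift[side][k])
        ups = shift[side]["up"]
        out[f"{side}_first_shift_up"] = sum(ups) / len(ups) if ups else math.nan

    n = len(all_presses)
    counts = {
        "SPACE": KeyClass.SPACE, "BCKSPACE": KeyClass.BACKSPACE, "DEL": KeyClass.DEL,
        "UP": KeyClass.UP, "DOWN": KeyClass.DOWN, "LEFT": KeyClass.LEFT,
        "RIGHT": KeyClass.RIGHT, "SHIFT_L": KeyClass.SHIFT_L, "SHIFT_R": KeyClass.SHIFT_R,
    }
    for name, kc in counts.items():
        out[name] = sum(1 for p in all_presses if p["key_class"] is kc) / n if n else math.nan
    letters = [p for p in all_presses if p["key_class"] is KeyClass.LETTER]
    out["CAPS"] = (
        sum(1 for p in letters if p["capital"]) / len(letters) if letters else math.nan
    )
    out["SPEED"] = speed_presses / (speed_ms / 1000) if speed_ms > 0 else math.nan
    return out


def brute_bh_selected(p_values, q):
    """BH by exhaustive search over every candidate cutoff rank."""
    p = list(p_values)
    n = len(p)
    order = sorted(range(n), key=lambda i: (p[i], i))
    best = 0
    for r in range(1, n + 1):
        if p[order[r - 1]] <= q * r / n:
            best = r
    return sorted(order[:best])


def exact_mannwhitney_p(a, b):
    """Exact two-sided Mann–Whitney p by enumerating all group assignments.

    Tie-free samples only.  U for sample ``a``; p = P(min(U, U') <= min
    observed) under the permutation null.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_of(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = min(u_of(a, b), u_of(b, a))
    total = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if min(u_of(ga, gb), u_of(gb, ga)) <= u_obs:
            hits += 1
        total += 1
    return hits / total


def exact_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Zero differences are removed first; tie-free magnitudes required.
    """
    d = [x for x in diffs if x != 0]
    mags = sorted(abs(x) for x in d)
    assert len(set(mags)) == len(mags), "oracle requires tie-free magnitudes"
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    n = len(d)

    def stat(signs):
        w_plus = sum(ranks[abs(x)] for x, s in zip(d, signs) if s > 0)
        w_minus = sum(ranks[abs(x)] for x, s in zip(d, signs) if s <= 0)
        return min(w_plus, w_minus)

    obs = stat([1 if x > 0 else -1 for x in d])
    hits = sum(
        1 for signs in itertools.product((1, -1), repeat=n) if stat(signs) <= obs
    )
    return hits / 2**n


def sample_paired_t(x, y):
    """t statistic and p from the closed form, via numpy only."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n - 1)
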