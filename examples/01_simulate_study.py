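"""Generate a synthetic opinion-writing study and inspect its shape.

Each of the 49 simulated participants types four opinions (best/worst
teacher, best/worst subject) with an individual typing style, and files a
9-point SAM self-report before the first opinion and after each one.
"""

from keydyn import EffectSpec, generate_study, slice_session, write_event_log

sessions = generate_study(n_users=49, effect=EffectSpec(speed_factor=1.15), seed=7)

print(f"sessions: {len(sessions)}")
print(f"events in first session: {len(sessions[0].events)}")
segments = slice_session(sessions[0])
for seg in segments:
    print(
        f"  {seg.opinion_kind.value:14s} {len(seg.events):5d} events "
        f"valence={seg.valence_label.value:8s} "
        f"pleasure report={seg.post_report.pleasure}"
    )

# Serialize one session to the anonymized CSV + JSON sidecar formats.
write_event_log(sessions[0], "scratch_session.csv", "scratch_session.json")
print("wrote scratch_session.csv / scratch_session.json")

# A session holds only key classes and opaque slot ids; which letters were
# typed is never recorded, so typing *style* is captured without content.
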