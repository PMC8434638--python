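"""Extract the 51 keystroke-dynamics features from one synthetic study.

Features summarize digraph/trigraph timing (mean [0] and standard deviation
[1]), shift-digraph behaviour, special-key frequencies and typing speed,
computed per opinion segment after splitting at idle pauses above 3 s.
"""

from keydyn import build_dataset, generate_study, make_relative

sessions = generate_study(n_users=10, seed=3, n_keystrokes_mean=200)
dataset, baselines = build_dataset(sessions)

print(f"feature matrix: {dataset.X.shape[0]} segments x {dataset.X.shape[1]} features")
print(f"baselines: {len(baselines)} users\n")

row = dataset.X.iloc[0]
meta = dataset.meta.iloc[0]
print(f"user {meta['user_id']}, {meta['opinion_kind']}:")
for name in ("di_1D2D[0]", "di_1KeyLat[0]", "tri_Dur[0]", "SPACE", "SPEED"):
    print(f"  {name:14s} {row[name]:8.3f}")
# di_1D2D[0]: mean press-to-press interval (ms); di_1KeyLat[0]: mean flight
# time (ms); tri_Dur[0]: mean trigraph span (ms); SPACE: fraction of presses
# that are the spacebar; SPEED: keystrokes per second.

relative = make_relative(dataset, baselines)
print("\nrelative variant (user baseline subtracted), same segment:")
for name in ("di_1D2D[0]", "SPACE", "SPEED"):
    print(f"  {name:14s} {relative.X.iloc[0][name]:+8.3f}")
# Values near zero mean this opinion was typed close to the user's overall
# style; deviations are the within-person signal the classifiers use.
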