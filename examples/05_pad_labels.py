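"""Dichotomize SAM self-reports and test them against the opinion conditions.

Self-reports use an inverted 9-point scale (1 = high pleasure/arousal,
9 = low).  Three merge rules split them at the midpoint 5 into High/Low
classes: L1 removes midpoint samples, L2 sends them to Low, L3 to High.
"""

import numpy as np

from keydyn import (
    LabelMergeSpec,
    build_dataset,
    generate_study,
    mann_whitney,
    merge_pad_labels,
    wilcoxon_signed_rank,
)

sessions = generate_study(n_users=49, seed=13, n_keystrokes_mean=60)
dataset, _ = build_dataset(sessions)
pleasure = dataset.meta["pleasure"].to_numpy()

for proc in ("L1", "L2", "L3"):
    labels, kept = merge_pad_labels(pleasure, LabelMergeSpec(proc, "pleasure"))
    n_high = int(np.sum(labels == "High"))
    n_low = int(np.sum(labels == "Low"))
    print(f"{proc}: {kept.sum():3d} samples kept ({n_high} High / {n_low} Low)")
# Class balance differs sharply between rules, which is why downstream
# classifier scores depend on the labeling procedure chosen.

pos = pleasure[(dataset.meta["valence"] == "POSITIVE").to_numpy()]
neg = pleasure[(dataset.meta["valence"] == "NEGATIVE").to_numpy()]
mw = mann_whitney(pos, neg)
print(f"\nMann-Whitney, pleasure after positive vs negative opinions: "
      f"U={mw.statistic:.1f}, p={mw.p_value:.4f}")

wil = wilcoxon_signed_rank(pos, neg)
print(f"Wilcoxon signed-rank on within-user pairs:                  "
      f"W={wil.statistic:.1f}, p={wil.p_value:.4f}")
# Both tests detect the generator's report-model shift: positive opinions
# are followed by lower (= more pleasant) pleasure values.
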