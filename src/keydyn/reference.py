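"""Packaged reference tables from the motivating 49-participant study.

Two CSVs ship with the package, holding the published feature-evaluation
results of the original opinion-writing study this pipeline models:

* ``reference_pvalues.csv`` — per-feature paired t-test p-values for the
  positive-vs-negative comparison, computed on all 196 samples and on the
  teacher-only / subject-only halves;
* ``reference_mutual_information.csv`` — per-feature mutual information with
  the positive/negative label (all / teacher / subject samples) and with the
  dichotomized High/Low pleasure and arousal labels.

They are *inputs* (e.g. for multiple-testing demonstrations on realistic
p-value sets), not outputs this package regenerates: regenerating them would
require the study's raw keystroke recordings.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .features import FEATURE_NAMES


def _load(name: str) -> pd.DataFrame:
    with resources.files("keydyn.data").joinpath(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="feature")
    missing = set(FEATURE_NAMES) - set(df.index)
    if missing or len(df) != len(FEATURE_NAMES):
        raise ValueError(f"reference table {name} does not match the 51-feature schema")
    return df


def load_reference_pvalues() -> pd.DataFrame:
    """51 features x columns (p_all, p_teacher, p_subject)."""
    return _load("reference_pvalues.csv")


def load_reference_mutual_information() -> pd.DataFrame:
    """51 features x columns (mi_all, mi_teacher, mi_subject, mi_pleasure, mi_arousal)."""
    return _load("reference_mutual_information.csv")
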