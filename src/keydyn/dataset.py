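"""Build modeling datasets from per-segment feature vectors.

Each participant contributes five vectors: one per opinion segment (4) plus
a whole-session *baseline* computed over all typed text.  Two dataset
variants follow:

* **absolute** — the four original segment vectors per user;
* **relative** — the four vectors after subtracting that user's baseline,
  which removes stable individual typing style and keeps within-person
  deviation.

The module also dichotomizes the 9-point self-report values into High/Low
classes (three merge rules around the midpoint 5), standardizes columns, and
reduces features by variance and pairwise-correlation screens.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureConfig, FeatureVector, features_from_event_groups
from .keylog_io import slice_session
from .types import Session, TOPIC_OF_KIND, VALENCE_OF_KIND

#: Per-sample metadata columns carried alongside the feature matrix.
META_COLUMNS = (
    "user_id",
    "opinion_kind",
    "valence",
    "topic",
    "pleasure",
    "arousal",
    "dominance",
)


@dataclass
class Dataset:
    """A samples x 51 feature matrix with per-sample study metadata."""

    X: pd.DataFrame
    meta: pd.DataFrame
    variant: str = "absolute"
    scaled: bool = False

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(FEATURE_NAMES):
            raise ValueError("X must have exactly the 51 canonical feature columns")
        if len(self.X) != len(self.meta):
            raise ValueError("X and meta row counts differ")
        if self.variant not in ("absolute", "relative"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_samples(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class LabelMergeSpec:
    """How to dichotomize a 9-point report dimension into High/Low.

    The scale is inverted (1 = high, 9 = low), so values *below* 5 are the
    High side.  Procedures: L1 removes midpoint samples; L2 sends the
    midpoint to Low; L3 sends it to High.
    """

    procedure: str
    dimension: str

    def __post_init__(self) -> None:
        if self.procedure not in ("L1", "L2", "L3"):
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.dimension not in ("pleasure", "arousal", "dominance"):
            raise ValueError(f"unknown dimension {self.dimension!r}")


def baseline_vector(session: Session, config: FeatureConfig | None = None) -> FeatureVector:
    """Whole-session feature vector: all four opinions pooled as one phase.

    Typing sequences and graphs are still computed within each opinion slice
    (they never span the gaps between opinions), then pooled.
    """
    segments = slice_session(session)
    groups = [seg.events for seg in segments if seg.events]
    if not groups:
        raise ValueError(f"session {session.user_id!r} has no events inside its opinions")
    return features_from_event_groups(
        groups, user_id=session.user_id, opinion_kind="BASELINE", config=config
    )


def build_dataset(
    sessions: list[Session], config: FeatureConfig | None = None
) -> tuple[Dataset, pd.DataFrame]:
    """Extract the absolute dataset and per-user baselines from sessions.

    Returns ``(dataset, baselines)`` where ``baselines`` is a user-indexed
    DataFrame of the 51 baseline features.
    """
    rows, meta_rows, base_rows = [], [], {}
    for session in sessions:
        for seg in slice_session(session):
            vec = features_from_event_groups(
                [seg.events],
                user_id=session.user_id,
                opinion_kind=seg.opinion_kind.value,
                config=config,
            )
            rows.append([vec.values[n] for n in FEATURE_NAMES])
            rep = seg.post_report
            meta_rows.append(
                {
                    "user_id": session.user_id,
                    "opinion_kind": seg.opinion_kind.value,
                    "valence": VALENCE_OF_KIND[seg.opinion_kind].value,
                    "topic": TOPIC_OF_KIND[seg.opinion_kind].value,
                    "pleasure": rep.pleasure if rep else np.nan,
                    "arousal": rep.arousal if rep else np.nan,
                    "dominance": rep.dominance if rep else np.nan,
                }
            )
        base = baseline_vector(session, config)
        base_rows[session.user_id] = [base.values[n] for n in FEATURE_NAMES]

    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    baselines = pd.DataFrame.from_dict(base_rows, orient="index", columns=list(FEATURE_NAMES))
    baselines.index.name = "user_id"
    return Dataset(X=X, meta=meta, variant="absolute"), baselines


def make_relative(dataset: Dataset, baselines: pd.DataFrame) -> Dataset:
    """Subtract each user's baseline vector from their segment vectors."""
    missing = sorted(set(dataset.meta["user_id"]) - set(baselines.index))
    if missing:
        raise ValueError(f"no baseline for user(s): {', '.join(map(str, missing))}")
    base = baselines.loc[dataset.meta["user_id"].to_numpy(), list(FEATURE_NAMES)]
    X = dataset.X.to_numpy(dtype=float) - base.to_numpy(dtype=float)
    return replace(
        dataset,
        X=pd.DataFrame(X, columns=list(FEATURE_NAMES), index=dataset.X.index),
        variant="relative",
    )


def standardize(dataset: Dataset) -> Dataset:
    """Z-score every column over its non-missing entries.

    Constant columns cannot be scaled; they become all-zero and a warning is
    emitted.
    """
    if dataset.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    X = dataset.X.to_numpy(dtype=float).copy()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(X, axis=0)
        std = np.nanstd(X, axis=0, ddof=0)
    constant = (std == 0) | np.isnan(std)
    for j in np.flatnonzero(constant):
        _warnings.warn(
            f"column {FEATURE_NAMES[j]!r} is constant; standardized to zeros",
            stacklevel=2,
        )
    std_safe = np.where(constant, 1.0, std)
    Z = (X - mean) / std_safe
    Z[:, constant & ~np.isnan(X).all(axis=0)] = 0.0
    return replace(
        dataset,
        X=pd.DataFrame(Z, columns=list(FEATURE_NAMES), index=dataset.X.index),
        scaled=True,
    )


def merge_pad_labels(values, spec: LabelMergeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomize 9-point report values into 'High'/'Low' labels.

    Remember the inverted scale (1 = high).  Returns ``(labels, kept)``
    aligned with the input: ``kept`` is False for samples removed by L1's
    midpoint rule; removed entries carry an empty label.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("report values contain missing entries")
    if ((v < 1) | (v > 9) | (v != np.round(v))).any():
        raise ValueError("report values must be integers in [1, 9]")
    labels = np.full(v.shape, "", dtype=object)
    kept = np.ones(v.shape, dtype=bool)
    if spec.procedure == "L1":
        labels[v > 5] = "Low"
        labels[v < 5] = "High"
        kept = v != 5
    elif spec.procedure == "L2":
        labels[v >= 5] = "Low"
        labels[v < 5] = "High"
    else:  # L3
        labels[v > 5] = "Low"
        labels[v <= 5] = "High"
    return labels, kept


def impute_column_means(
    X: pd.DataFrame, means: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing entries with column means (training-fold means if given).

    A column with no observed values falls back to 0.  Returns the imputed
    frame and the means used, so test folds can reuse training-fold means.
    """
    if means is None:
        means = X.mean(axis=0, skipna=True).fillna(0.0)
    return X.fillna(means), means


def reduce_features(
    X: pd.DataFrame,
    var_threshold: float = 1e-10,
    corr_threshold: float = 0.95,
) -> list[str]:
    """Variance + correlation screen; returns the kept column names.

    Drops columns with variance below ``var_threshold``, then scans pairs in
    canonical column order and drops the *later* column of any pair whose
    absolute Pearson correlation exceeds ``corr_threshold``.  Deterministic
    and invariant to sample order.
    """
    if X.isna().any().any():
        raise ValueError("reduce_features requires an imputed (complete) matrix")
    variances = X.var(axis=0, ddof=0)
    kept = [c for c in X.columns if variances[c] >= var_threshold]
    if not kept:
        raise ValueError("all features dropped by the variance screen")
    corr = X[kept].corr().abs().to_numpy()
    keep_mask = np.ones(len(kept), dtype=bool)
    for j in range(1, len(kept)):
        for i in range(j):
            if keep_mask[i] and corr[i, j] > corr_threshold:
                keep_mask[j] = False
                break
    final = [c for c, k in zip(kept, keep_mask) if k]
    if not final:
        raise ValueError("all features dropped by the correlation screen")
    return final
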