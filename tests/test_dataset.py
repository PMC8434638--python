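"""Absolute/relative datasets, standardization, PAD merging, feature screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from keydyn import (
    FEATURE_NAMES,
    LabelMergeSpec,
    baseline_vector,
    build_dataset,
    impute_column_means,
    make_relative,
    merge_pad_labels,
    reduce_features,
    standardize,
)
from keydyn.dataset import Dataset


def test_five_vectors_per_user(small_study, small_dataset):
    dataset, baselines = small_dataset
    assert dataset.n_samples == 4 * len(small_study)
    assert dataset.X.shape[1] == 51
    assert len(baselines) == len(small_study)
    assert (dataset.meta.groupby("user_id").size() == 4).all()


def test_baseline_of_identical_segments_matches_segment_vector():
    """A session whose four opinions are timing-identical has baseline == segment."""
    from keydyn.synthgen import generate_study

    (session,) = generate_study(n_users=1, seed=0, n_keystrokes_mean=100)
    from keydyn.keylog_io import slice_session

    seg = slice_session(session)[0]
    # clone the first opinion into all four slots
    span = max(e.timestamp_ms for e in seg.events) - seg.events[0].timestamp_ms
    gap = span + 60_000
    cloned, boundaries = [], []
    from keydyn.types import KeyEvent, OpinionKind, Session

    for i, kind in enumerate(OpinionKind):
        offset = i * gap
        boundaries.append((seg.events[0].timestamp_ms + offset - 100, kind))
        cloned.extend(
            KeyEvent(e.timestamp_ms + offset, e.key_class, e.slot_id, e.event_type, e.capital)
            for e in seg.events
        )
    clone = Session(user_id="c", events=cloned, boundaries=boundaries)
    dataset, baselines = build_dataset([clone])
    base = baselines.loc["c"]
    for name in FEATURE_NAMES:
        a, b = dataset.X.iloc[0][name], base[name]
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-9), name
    rel = make_relative(dataset, baselines)
    assert np.nanmax(np.abs(rel.X.to_numpy())) == pytest.approx(0, abs=1e-9)


def test_relative_is_subtraction_and_invertible(small_dataset):
    dataset, baselines = small_dataset
    rel = make_relative(dataset, baselines)
    assert rel.variant == "relative"
    back = rel.X.to_numpy() + baselines.loc[dataset.meta["user_id"]].to_numpy()
    mask = ~np.isnan(dataset.X.to_numpy())
    np.testing.assert_allclose(back[mask], dataset.X.to_numpy()[mask], atol=1e-9)
    # missing entries stay missing
    assert (np.isnan(rel.X.to_numpy()) >= np.isnan(dataset.X.to_numpy())).all()


def test_relative_mean_identity(small_dataset):
    """Mean of a user's relative vectors == mean of absolute vectors - baseline."""
    dataset, baselines = small_dataset
    rel = make_relative(dataset, baselines)
    user = dataset.meta["user_id"].iloc[0]
    m = (dataset.meta["user_id"] == user).to_numpy()
    lhs = rel.X[m].mean(skipna=False)
    rhs = dataset.X[m].mean(skipna=False) - baselines.loc[user]
    pd.testing.assert_series_equal(lhs, rhs, atol=1e-9, check_names=False)


def test_missing_baseline_names_user(small_dataset):
    dataset, baselines = small_dataset
    with pytest.raises(ValueError, match=baselines.index[0]):
        make_relative(dataset, baselines.drop(baselines.index[0]))


def test_standardize_columns(small_dataset):
    dataset, _ = small_dataset
    z = standardize(dataset)
    arr = z.X.to_numpy()
    mean = np.nanmean(arr, axis=0)
    std = np.nanstd(arr, axis=0)
    observed = ~np.isnan(arr).all(axis=0)
    np.testing.assert_allclose(mean[observed], 0, atol=1e-9)
    varying = observed & (std > 0)
    np.testing.assert_allclose(std[varying], 1, atol=1e-9)
    # idempotent up to tolerance
    z2 = standardize(z)
    np.testing.assert_allclose(z2.X.to_numpy()[:, varying], arr[:, varying], atol=1e-9)


def test_standardize_constant_column_warns(small_dataset):
    dataset, _ = small_dataset
    X = dataset.X.copy()
    X["SPEED"] = 3.14
    with pytest.warns(UserWarning, match="SPEED"):
        z = standardize(Dataset(X=X, meta=dataset.meta))
    assert (z.X["SPEED"] == 0).all()


@pytest.mark.parametrize(
    "procedure,expected,kept",
    [
        ("L1", ["High", "", "Low"], [True, False, True]),
        ("L2", ["High", "Low", "Low"], [True, True, True]),
        ("L3", ["High", "High", "Low"], [True, True, True]),
    ],
)
def test_merge_pad_labels_rules(procedure, expected, kept):
    labels, mask = merge_pad_labels([3, 5, 7], LabelMergeSpec(procedure, "pleasure"))
    assert labels.tolist() == expected
    assert mask.tolist() == kept


def test_merge_pad_labels_rejects_out_of_scale():
    with pytest.raises(ValueError):
        merge_pad_labels([0, 5], LabelMergeSpec("L1", "arousal"))
    with pytest.raises(ValueError):
        merge_pad_labels([10], LabelMergeSpec("L2", "arousal"))


@given(st.lists(st.integers(1, 9), min_size=1, max_size=60), st.sampled_from(["L1", "L2", "L3"]))
def test_merge_pad_labels_partition(values, procedure):
    labels, kept = merge_pad_labels(values, LabelMergeSpec(procedure, "pleasure"))
    n_high = int(np.sum(labels == "High"))
    n_low = int(np.sum(labels == "Low"))
    assert n_high + n_low + int(np.sum(~kept)) == len(values)
    assert (labels[~kept] == "").all()


def test_reduce_features_drops_duplicates_and_constants():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(
        {
            "a": rng.normal(size=50),
            "b": np.ones(50),  # constant: variance screen
            "c": rng.normal(size=50),
        }
    )
    X["d"] = X["a"] * 2 + 1e-9 * rng.normal(size=50)  # near-duplicate of a
    kept = reduce_features(X)
    assert kept == ["a", "c"]


def test_reduce_features_keeps_independent_columns_and_ignores_order():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(200, 8)), columns=list("abcdefgh"))
    kept = reduce_features(X, corr_threshold=0.95)
    assert kept == list("abcdefgh")
    shuffled = X.sample(frac=1.0, random_state=7)
    assert reduce_features(shuffled, corr_threshold=0.95) == kept


def test_reduce_features_requires_complete_matrix():
    X = pd.DataFrame({"a": [1.0, np.nan]})
    with pytest.raises(ValueError, match="imputed"):
        reduce_features(X)


def test_impute_column_means_roundtrip():
    X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [np.nan, np.nan, np.nan]})
    filled, means = impute_column_means(X)
    assert filled["a"].tolist() == [1.0, 2.0, 3.0]
    assert (filled["b"] == 0).all()
    other = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
    reused, _ = impute_column_means(other, means)
    assert reused["a"].iloc[0] == 2.0
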