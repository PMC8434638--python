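"""Statistical evaluation of keystroke features and self-report labels.

* paired (dependent-samples) t-test for positive-vs-negative feature values,
  two-sided;
* Benjamini–Hochberg step-up procedure controlling the false-discovery rate
  across the 51 simultaneous feature tests;
* Mann–Whitney U and Wilcoxon signed-rank tests for the ordinal 9-point
  self-report labels (independent and paired comparisons respectively);
* k-nearest-neighbour mutual-information estimates between features and
  binary class labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.feature_selection import mutual_info_classif


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class BHResult:
    """Benjamini–Hochberg selection at FDR level ``q``.

    ``order`` holds the original indices sorted by ascending p-value;
    ``cutoff_rank`` is the largest rank r (1-based) with p_(r) <= q*r/n, or 0
    when nothing is selected; ``selected`` are the original indices of ranks
    1..cutoff_rank.
    """

    q: float
    n: int
    order: np.ndarray
    p_sorted: np.ndarray
    cutoff_rank: int
    selected: np.ndarray


@dataclass
class MIResult:
    """Per-feature mutual information (nats) with the estimator settings."""

    values: pd.Series
    n_neighbors: int
    seed: int | None
    method: str = "knn"


def paired_t_test(x, y) -> TestResult:
    """Dependent-samples t-test on paired observations, two-sided.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, sample standard deviation,
    and n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired samples")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences: t-test undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), p_value=float(p), n=n)


def benjamini_hochberg(p_values, q: float) -> BHResult:
    """Step-up FDR control: reject the hypotheses of the ``r*`` smallest
    p-values, where r* is the largest rank r with p_(r) <= q*r/n.

    Ties in p are broken by original index, so the selection is
    deterministic.  An empty input yields an empty result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    n = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    cutoff = 0
    for r in range(n, 0, -1):
        if p_sorted[r - 1] <= q * r / n:
            cutoff = r
            break
    return BHResult(
        q=q,
        n=n,
        order=order,
        p_sorted=p_sorted,
        cutoff_rank=cutoff,
        selected=order[:cutoff].copy(),
    )


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test for two independent ordinal samples.

    The reported statistic is U of the first sample; the p-value is exact for
    small tie-free samples and uses the tie-corrected normal approximation
    otherwise (scipy's default policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), n=a.size + b.size)


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking; the statistic is the
    smaller of the positive/negative rank sums.  All-zero differences are an
    error (no information about a shift).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: test undefined")
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    n_used = int(np.sum(d != 0))
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), n=n_used)


def mutual_information(
    features, labels, n_neighbors: int = 3, seed: int | None = 0
) -> MIResult:
    """Mutual information (nats) of each feature with a binary label.

    Continuous features use the k-nearest-neighbour estimator (default k=3);
    negative estimates are clipped to zero.  The estimator is stochastic
    (jitter breaks ties), so a seed fixes the result.
    """
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        names = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(range(X.shape[1]))
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class: mutual information undefined")
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")
    mi = mutual_info_classif(
        X, y, n_neighbors=n_neighbors, random_state=seed, discrete_features=False
    )
    values = pd.Series(np.clip(mi, 0.0, None), index=names, name="mutual_information")
    return MIResult(values=values, n_neighbors=n_neighbors, seed=seed)


def evaluate_features_paired(
    X: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature paired t-test between positive and negative opinions.

    Pairs are formed within user and topic: (best teacher, worst teacher)
    and (best subject, worst subject).  Returns a DataFrame indexed by
    feature with columns ``statistic``, ``p_value``, ``n_pairs``; features
    with fewer than 3 complete pairs or zero-variance differences get NaN.
    """
    from .types import OpinionKind  # local import avoids cycles

    pair_kinds = [
        (OpinionKind.BEST_TEACHER.value, OpinionKind.WORST_TEACHER.value),
        (OpinionKind.BEST_SUBJECT.value, OpinionKind.WORST_SUBJECT.value),
    ]
    rows = {}
    for feat in X.columns:
        pos_vals, neg_vals = [], []
        for user in meta["user_id"].unique():
            m = meta["user_id"] == user
            for pos_kind, neg_kind in pair_kinds:
                pv = X.loc[m & (meta["opinion_kind"] == pos_kind), feat]
                nv = X.loc[m & (meta["opinion_kind"] == neg_kind), feat]
                if len(pv) == 1 and len(nv) == 1:
                    a, b = float(pv.iloc[0]), float(nv.iloc[0])
                    if not (np.isnan(a) or np.isnan(b)):
                        pos_vals.append(a)
                        neg_vals.append(b)
        try:
            res = paired_t_test(pos_vals, neg_vals)
            rows[feat] = (res.statistic, res.p_value, res.n)
        except ValueError:
            rows[feat] = (np.nan, np.nan, len(pos_vals))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["statistic", "p_value", "n_pairs"]
    ).rename_axis("feature")
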