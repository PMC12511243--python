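"""Feature selection: ANOVA F-test, greedy mRMR, and RReliefF.

Each selector produces a full deterministic ranking of the 57 features
for one target (SBP or DBP); downstream models use the top k (default
15).  Ties are always broken lexicographically by feature name so
rankings are bitwise reproducible.

* The F-test scores each feature by the one-way ANOVA F statistic across
  the four AHA categories (the only classes defined for this cohort);
  because the classes do not depend on the regression target, the F-test
  ranking is shared by SBP and DBP.
* mRMR is the greedy "minimum redundancy - maximum relevance" forward
  selection in its difference (MID) form: relevance is the absolute
  Pearson correlation with the continuous target, redundancy the mean
  absolute Pearson correlation with the already-selected features.
* RReliefF is the regression Relief variant of Robnik-Sikonja &
  Kononenko: feature weights accumulate how feature differences track
  target differences among the k nearest neighbors of every instance,
  with exponentially decaying rank weighting.  All instances are used
  (no sampling), making the result deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import f_oneway

from .features import feature_columns

__all__ = [
    "SelectionResult",
    "f_test_rank",
    "mrmr_rank",
    "relieff_rank",
    "select_top_k",
    "rank_features",
    "SELECTORS",
]

TARGET_COLUMNS = {"SBP": "sbp_ref", "DBP": "dbp_ref"}


@dataclass(frozen=True)
class SelectionResult:
    """Ranked features with scores for one (method, target) pair."""

    method: str
    target: str  # "SBP" or "DBP"
    ranking: tuple[str, ...]  # all features, most to least relevant
    scores: dict[str, float]  # score per feature (meaning depends on method)
    top_k: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.scores):
            raise ValueError("ranking must be a permutation of the scored features")
        if not all(np.isfinite(list(self.scores.values()))):
            raise ValueError("scores must be finite")


def _ranked(method: str, target: str, scores: dict[str, float], k: int,
            order: list[str] | None = None) -> SelectionResult:
    """Sort descending by score, ties lexicographic; or use explicit order."""
    if order is None:
        order = sorted(scores, key=lambda f: (-scores[f], f))
    return SelectionResult(
        method=method,
        target=target,
        ranking=tuple(order),
        scores=scores,
        top_k=tuple(order[:k]),
    )


def _validate_target(target: str) -> str:
    if target not in TARGET_COLUMNS:
        raise ValueError(f"target must be one of {sorted(TARGET_COLUMNS)}")
    return TARGET_COLUMNS[target]


def f_test_rank(table: pd.DataFrame, target: str, k: int = 15) -> SelectionResult:
    """Rank features by one-way ANOVA F across the AHA categories.

    Requires at least two non-empty classes with two or more rows each.
    A feature that is constant everywhere scores F = 0 (with a warning).
    """
    _validate_target(target)
    feats = feature_columns(table)
    groups = [g for _, g in table.groupby("category", observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 classes with >=2 samples each for the F-test")
    scores: dict[str, float] = {}
    for f in feats:
        col = table[f].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"feature {f!r} is constant; F set to 0", stacklevel=2)
            scores[f] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # within-class constant -> nan
            stat = f_oneway(*[g[f].to_numpy(dtype=float) for g in groups]).statistic
        scores[f] = float(stat) if np.isfinite(stat) else 0.0
    return _ranked("f_test", target, scores, k)


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r|, defined as 0 when either argument has zero variance."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def mrmr_rank(table: pd.DataFrame, target: str, k: int = 15) -> SelectionResult:
    """Greedy mRMR ordering (difference form).

    Step score of a candidate f given selected set S:
    ``|r(f, y)| - mean_{s in S} |r(f, s)|``; the first pick maximizes
    relevance alone.  The full greedy order is returned; ``scores`` holds
    each feature's step score at the moment it was picked.
    """
    ycol = _validate_target(target)
    feats = feature_columns(table)
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    y = table[ycol].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    X = {f: table[f].to_numpy(dtype=float) for f in feats}
    relevance = {f: _abs_pearson(X[f], y) for f in feats}
    # pairwise |r| computed lazily, cached
    cache: dict[tuple[str, str], float] = {}

    def red(f: str, s: str) -> float:
        key = (f, s) if f < s else (s, f)
        if key not in cache:
            cache[key] = _abs_pearson(X[f], X[s])
        return cache[key]

    order: list[str] = []
    step_scores: dict[str, float] = {}
    remaining = set(feats)
    while remaining:
        if not order:
            crit = {f: relevance[f] for f in remaining}
        else:
            crit = {
                f: relevance[f] - np.mean([red(f, s) for s in order])
                for f in remaining
            }
        best = min(crit, key=lambda f: (-crit[f], f))
        order.append(best)
        step_scores[best] = float(crit[best])
        remaining.discard(best)
    return _ranked("mrmr", target, step_scores, k, order=order)


def relieff_rank(
    table: pd.DataFrame,
    target: str,
    k: int = 15,
    n_neighbors: int = 10,
    sigma: float = 50.0,
) -> SelectionResult:
    """RReliefF feature weights for a continuous target.

    Features are min-max scaled before Manhattan distances are computed;
    every instance serves as a query (m = n), its ``n_neighbors`` nearest
    neighbors contribute with exponentially decaying rank influence
    ``exp(-(rank/sigma)^2)`` normalized to sum 1.  Weights lie in
    [-1, 1]; features are ranked by descending weight.
    """
    ycol = _validate_target(target)
    feats = feature_columns(table)
    n = len(table)
    if n < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} rows")
    X = table[feats].to_numpy(dtype=float)
    y = table[ycol].to_numpy(dtype=float)
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0  # constant feature: all diffs are 0 anyway
    Xs = (X - X.min(axis=0)) / span
    y_span = np.ptp(y)
    if y_span == 0:
        raise ValueError("target is constant")
    dy_all = np.abs(y[:, None] - y[None, :]) / y_span

    D = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    if not np.isfinite(D[D != np.inf]).all() or (D[D != np.inf] == 0).all():
        raise ValueError("all rows identical; RReliefF is undefined")

    rank_w = np.exp(-((np.arange(1, n_neighbors + 1) / sigma) ** 2))
    rank_w = rank_w / rank_w.sum()

    n_dc = 0.0
    n_df = np.zeros(len(feats))
    n_dcdf = np.zeros(len(feats))
    for i in range(n):
        nbrs = np.argsort(D[i], kind="stable")[:n_neighbors]
        dy = dy_all[i, nbrs]
        df = np.abs(Xs[nbrs] - Xs[i])  # (k, p), already range-normalized
        n_dc += float(dy @ rank_w)
        n_df += rank_w @ df
        n_dcdf += (dy * rank_w) @ df
    m = float(n)
    if n_dc == 0 or n_dc == m:
        raise ValueError("degenerate target differences; RReliefF is undefined")
    w = n_dcdf / n_dc - (n_df - n_dcdf) / (m - n_dc)
    scores = {f: float(v) for f, v in zip(feats, w)}
    return _ranked("relieff", target, scores, k)


def select_top_k(result: SelectionResult, k: int = 15) -> SelectionResult:
    """Re-cut an existing ranking to its first ``k`` features."""
    if k > len(result.ranking):
        raise ValueError(f"k={k} exceeds number of ranked features")
    return SelectionResult(
        method=result.method,
        target=result.target,
        ranking=result.ranking,
        scores=result.scores,
        top_k=result.ranking[:k],
    )


SELECTORS = {"f_test": f_test_rank, "mrmr": mrmr_rank, "relieff": relieff_rank}


def rank_features(
    table: pd.DataFrame, method: str, target: str, k: int = 15, **kwargs
) -> SelectionResult:
    """Dispatch to one of the three selectors by name."""
    if method not in SELECTORS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(SELECTORS)}")
    return SELECTORS[method](table, target, k=k, **kwargs)
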