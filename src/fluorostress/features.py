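"""Feature table, stage-wise correlations, and impurity-based scores.

One imaged plant contributes one row: the eight index values of its
ROI-mean spectrum plus a stage label (controlled / stressed /
recovered). On top of the table:

* per-stage Pearson correlation matrices with two-sided p < 0.05 flags,
* a feature-score map — for each index, the Gini impurity decrease of
  every decision-tree node that splits on it, weighted by the fraction
  of samples reaching that node, summed and normalised to 1. A single
  tree's scores are unstable at n ~ 131, so scores are averaged over a
  bootstrap ensemble of trees by default (single-tree mode retained for
  hand-checkable examples),
* selection of the top-k features by score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .indices import INDEX_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "make_table",
    "clean_table",
    "correlation_matrix",
    "tree_importances",
    "feature_scores",
    "select_features",
]

CLASS_LABELS = ("controlled", "stressed", "recovered")
LABEL_COLUMN = "label"


def make_table(rows: list[dict], labels: list[str]) -> pd.DataFrame:
    """Assemble index-vector dicts + labels into a feature table."""
    table = pd.DataFrame(rows, columns=list(INDEX_NAMES))
    table[LABEL_COLUMN] = pd.Categorical(labels, categories=CLASS_LABELS)
    return table


def clean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows containing NaN index values, logging the count."""
    keep = table[list(INDEX_NAMES)].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with NaN index values", dropped)
    return table.loc[keep].reset_index(drop=True)


def correlation_matrix(
    table: pd.DataFrame, stage: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of the eight indices within one stage.

    Returns ``(r, significant)``: an 8x8 symmetric matrix with unit
    diagonal, and a boolean matrix flagging two-sided p < ``alpha`` from
    the standard t transform of r (uncorrected, as is conventional for
    exploratory correlation heat maps). Constant columns yield NaN
    correlations for their pairs, with a warning.
    """
    sub = table.loc[table[LABEL_COLUMN] == stage, list(INDEX_NAMES)]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 samples in stage '{stage}', got {n}")
    x = sub.to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "constant column(s) %s in stage '%s': correlations undefined",
            [INDEX_NAMES[i] for i in np.flatnonzero(constant)], stage,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    # Two-sided p from t = r sqrt((n-2)/(1-r^2)), df = n-2.
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rr = np.clip(r, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    sig = (p < alpha) & np.isfinite(r)
    names = list(INDEX_NAMES)
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(sig, index=names, columns=names),
    )


def tree_importances(tree: DecisionTreeClassifier, n_features: int) -> np.ndarray:
    """Unnormalised importances from a fitted tree.

    For each internal node splitting on feature f, accumulate

        (n_node / n_total) * [ impurity(node)
                               - (n_left/n_node) * impurity(left)
                               - (n_right/n_node) * impurity(right) ]

    i.e. the impurity decrease weighted by the probability of reaching
    the node (samples reaching it over total samples). Implemented by
    direct traversal of the fitted tree structure.
    """
    t = tree.tree_
    n_total = t.weighted_n_node_samples[0]
    imp = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n_node = t.weighted_n_node_samples[node]
        decrease = t.impurity[node] - (
            t.weighted_n_node_samples[left] / n_node * t.impurity[left]
            + t.weighted_n_node_samples[right] / n_node * t.impurity[right]
        )
        imp[t.feature[node]] += (n_node / n_total) * decrease
    return imp


def feature_scores(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int | None = None,
    bootstrap: bool = True,
) -> pd.Series:
    """Impurity-based feature scores, normalised to sum to 1.

    Default is an ensemble of ``n_trees`` Gini trees fitted on bootstrap
    resamples seeded from ``seed`` (scores from a single tree are noisy
    at the sample sizes this pipeline targets). ``n_trees=1,
    bootstrap=False`` gives the deterministic single-tree scores that
    can be verified by hand.
    """
    x = table[list(INDEX_NAMES)].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("feature scores need at least 2 classes")
    rng = np.random.default_rng(seed)
    total = np.zeros(len(INDEX_NAMES))
    for k in range(n_trees):
        if bootstrap and n_trees > 1:
            pick = rng.integers(0, len(x), size=len(x))
            xk, yk = x[pick], y[pick]
            if len(np.unique(yk)) < 2:
                continue
        else:
            xk, yk = x, y
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(xk, yk)
        raw = tree_importances(tree, len(INDEX_NAMES))
        if raw.sum() > 0:
            total += raw / raw.sum()
    if total.sum() == 0:
        raise ValueError("no tree produced a split; scores undefined")
    return pd.Series(total / total.sum(), index=list(INDEX_NAMES), name="score")


def select_features(scores: pd.Series, k: int = 4) -> list[str]:
    """The k highest-scoring features, descending.

    Ties at the cut are broken by the canonical feature order (logged),
    so selection is deterministic given the scores.
    """
    if not 1 <= k <= len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}]")
    order = {name: i for i, name in enumerate(INDEX_NAMES)}
    ranked = sorted(scores.index, key=lambda f: (-scores[f], order[f]))
    cut = scores[ranked[k - 1]]
    if k < len(ranked) and scores[ranked[k]] == cut:
        logger.info("tie at the selection cut (score %.6f); canonical order used", cut)
    return ranked[:k]
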