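"""Gini-importance ranking, threshold grouping and OOB-guided selection.

Feature importance is mean decrease in impurity: the Gini impurity drop
attributable to a feature, summed over every split of every tree in a
random forest, normalized so scores sum to one.  Features are grouped
by descending score thresholds (default 0.1 > 0.04 > 0.02 > 0, giving
nested groups A ⊂ B ⊂ C ⊂ D); the group with the best prediction
accuracy and the smallest out-of-bag (OOB) error — and the smallest
tree count on its accuracy plateau — wins.

Per tree, bootstrap resampling leaves roughly a 1 − (1 − 1/n)^n → 1 − 1/e
≈ 36.8 % of samples out of bag; the remaining ≈ 63.2 % distinct samples
train the tree.  :func:`bootstrap_inbag_fraction` estimates those
fractions by simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureGroup",
    "importance_scores",
    "group_by_thresholds",
    "oob_curve",
    "select_group",
    "bootstrap_inbag_fraction",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_TREE_GRID",
]

DEFAULT_THRESHOLDS = (0.1, 0.04, 0.02, 0.0)
DEFAULT_TREE_GRID = tuple(range(50, 1001, 50))
GROUP_LABELS = "ABCDEFGH"


def importance_scores(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank features by normalized Gini importance.

    Fits a seeded random forest and reports, per feature, the raw
    summed impurity decrease ``I_f`` and the normalized score
    ``S_f = I_f / sum(I_f)``, sorted descending with a 1-based rank.
    """
    labels = np.asarray(labels)
    if features.shape[0] == 0 or features.shape[1] == 0:
        raise ValueError("empty feature table")
    if len(np.unique(labels)) < 2:
        raise ValueError("importance ranking requires at least 2 classes")
    if features.isna().any().any():
        raise ValueError("feature table contains NaN; drop invalid pixels first")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(features.to_numpy(), labels)
    # sklearn normalizes per tree then averages; renormalize so S_f sums to 1
    raw = rf.feature_importances_ * n_trees
    s = raw / raw.sum()
    table = pd.DataFrame({"feature": features.columns, "importance": raw, "score": s})
    table = table.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass(frozen=True)
class FeatureGroup:
    label: str
    threshold: float
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


def group_by_thresholds(
    table: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> list[FeatureGroup]:
    """Nested feature groups: group g keeps features with score > threshold_g.

    Thresholds must be strictly decreasing, so the groups nest
    (A ⊆ B ⊆ C ⊆ ...).  An empty top group is dropped with a warning.
    """
    thresholds = tuple(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly decreasing, got {thresholds}")
    groups: list[FeatureGroup] = []
    for label, thr in zip(GROUP_LABELS, thresholds):
        members = tuple(table.loc[table["score"] > thr, "feature"])
        if not members:
            warnings.warn(f"group {label} (score > {thr}) is empty; dropped", stacklevel=2)
            continue
        groups.append(FeatureGroup(label=label, threshold=thr, members=members))
    if not groups:
        raise ValueError("all groups empty under the given thresholds")
    return groups


def oob_curve(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: list[FeatureGroup],
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    seed: int = 0,
    holdout_fraction: float = 0.3,
) -> pd.DataFrame:
    """OOB error and hold-out prediction accuracy per (group, n_trees).

    Prediction accuracy is measured on a seeded stratified hold-out of
    the training samples (default 30 %), keeping validation pixels
    untouched; OOB error comes from each forest's internal estimate on
    the per-tree out-of-bag samples.
    """
    if not tree_grid:
        raise ValueError("tree grid is empty")
    labels = np.asarray(labels)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        features, labels, test_size=holdout_fraction, stratify=labels, random_state=seed
    )
    rows = []
    for group in groups:
        cols = list(group.members)
        for n_trees in tree_grid:
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small forests may miss some OOB samples
                rf.fit(X_tr[cols].to_numpy(), y_tr)
            acc = float(np.mean(rf.predict(X_ho[cols].to_numpy()) == y_ho))
            rows.append(
                {
                    "group": group.label,
                    "n_trees": n_trees,
                    "prediction_accuracy": acc,
                    "oob_error": 1.0 - float(rf.oob_score_),
                }
            )
    return pd.DataFrame(rows)


def select_group(
    curves: pd.DataFrame,
    groups: list[FeatureGroup],
    plateau_tolerance: float = 0.002,
) -> tuple[FeatureGroup, int]:
    """Pick the feature group and tree count from selection curves.

    The winning group maximizes peak prediction accuracy; ties break by
    lower minimum OOB error, then by fewer features.  The tree count is
    the smallest one whose accuracy is within ``plateau_tolerance`` of
    the winner's peak.
    """
    if not np.isfinite(curves[["prediction_accuracy", "oob_error"]].to_numpy()).all():
        raise ValueError("selection curves contain non-finite values")
    by_label = {g.label: g for g in groups}
    grids = {tuple(sub["n_trees"]) for _, sub in curves.groupby("group")}
    if len(grids) != 1:
        raise ValueError("tree grid differs across groups")
    best = None
    for label, sub in curves.groupby("group"):
        peak = sub["prediction_accuracy"].max()
        min_oob = sub["oob_error"].min()
        key = (-peak, min_oob, len(by_label[label]))
        if best is None or key < best[0]:
            best = (key, label, peak, sub)
    _, label, peak, sub = best
    on_plateau = sub[sub["prediction_accuracy"] >= peak - plateau_tolerance]
    n_trees = int(on_plateau["n_trees"].min())
    return by_label[label], n_trees


def bootstrap_inbag_fraction(
    n: int = 10_000,
    n_replicates: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulated (in-bag distinct, out-of-bag) fractions of bootstrap resampling.

    Draws ``n_replicates`` resamples of size n with replacement and
    returns the mean fraction of distinct original samples appearing in
    a resample and the mean fraction never drawn.  Both converge to
    1 − 1/e ≈ 0.632 and 1/e ≈ 0.368 as n grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    distinct = np.empty(n_replicates)
    for r in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        distinct[r] = np.unique(idx).size / n
    inbag = float(distinct.mean())
    return inbag, 1.0 - inbag
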