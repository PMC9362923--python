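"""Importance ranking, threshold groups, OOB curves and bootstrap fractions."""

import numpy as np
import pandas as pd
import pytest

from tsvf.feature_selection import (
    bootstrap_inbag_fraction,
    group_by_thresholds,
    importance_scores,
    oob_curve,
    select_group,
    FeatureGroup,
)


@pytest.fixture(scope="module")
def labeled_table():
    """One feature fully determines the label; the rest are noise."""
    rng = np.random.default_rng(7)
    n = 300
    labels = rng.integers(0, 3, size=n)
    X = pd.DataFrame(
        {
            "decisive": labels + rng.normal(0, 0.01, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "noise3": rng.normal(size=n),
        }
    )
    return X, labels.astype(str)


def test_scores_sum_to_one_and_decisive_feature_ranks_first(labeled_table):
    X, y = labeled_table
    table = importance_scores(X, y, n_trees=100, seed=0)
    assert table["score"].sum() == pytest.approx(1.0, abs=1e-9)
    assert table["score"].mean() == pytest.approx(1.0 / X.shape[1], abs=1e-12)
    assert (table["score"] >= 0).all()
    assert table.iloc[0]["feature"] == "decisive"
    assert list(table["rank"]) == list(range(1, len(table) + 1))


def test_importance_requires_two_classes_and_no_nan(labeled_table):
    X, _ = labeled_table
    with pytest.raises(ValueError, match="2 classes"):
        importance_scores(X, np.zeros(len(X)), n_trees=10)
    Xn = X.copy()
    Xn.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        importance_scores(Xn, np.arange(len(X)) % 2, n_trees=10)
    with pytest.raises(ValueError, match="empty"):
        importance_scores(X.iloc[:0], np.array([]), n_trees=10)


def test_importance_is_seeded(labeled_table):
    X, y = labeled_table
    a = importance_scores(X, y, n_trees=50, seed=3)
    b = importance_scores(X, y, n_trees=50, seed=3)
    pd.testing.assert_frame_equal(a, b)


def _table(scores):
    return pd.DataFrame({"feature": [f"f{i}" for i in range(len(scores))], "score": scores})


def test_group_sizes_by_direct_filtering():
    groups = group_by_thresholds(_table([0.15, 0.05, 0.03, 0.01]), (0.1, 0.04, 0.02, 0.0))
    assert [len(g) for g in groups] == [1, 2, 3, 4]
    assert [g.label for g in groups] == ["A", "B", "C", "D"]


def test_groups_nest_under_decreasing_thresholds():
    rng = np.random.default_rng(0)
    scores = rng.dirichlet(np.ones(40))
    groups = group_by_thresholds(_table(scores), (0.08, 0.04, 0.01, 0.0))
    for small, big in zip(groups, groups[1:]):
        assert set(small.members) <= set(big.members)


def test_empty_top_group_warns_and_drops():
    with pytest.warns(UserWarning, match="empty"):
        groups = group_by_thresholds(_table([0.3, 0.7]), (0.9, 0.0))
    assert [g.label for g in groups] == ["B"]
    with pytest.raises(ValueError, match="decreasing"):
        group_by_thresholds(_table([0.5, 0.5]), (0.1, 0.1))


def test_select_group_brute_force_agreement():
    # two groups, known argmax: exhaustive scan over the grid must agree
    grid = [50, 100, 200]
    curves = pd.DataFrame(
        [
            {"group": "C", "n_trees": t, "prediction_accuracy": a, "oob_error": e}
            for t, a, e in zip(grid, [0.90, 0.95, 0.951], [0.10, 0.06, 0.055])
        ]
        + [
            {"group": "D", "n_trees": t, "prediction_accuracy": a, "oob_error": e}
            for t, a, e in zip(grid, [0.89, 0.93, 0.94], [0.11, 0.08, 0.07])
        ]
    )
    groups = [FeatureGroup("C", 0.02, ("a", "b")), FeatureGroup("D", 0.0, ("a", "b", "c"))]
    best_peak = max(curves.groupby("group")["prediction_accuracy"].max().items(), key=lambda kv: kv[1])
    selected, n_trees = select_group(curves, groups)
    assert selected.label == best_peak[0] == "C"
    # smallest tree count within 0.002 of the 0.951 peak is 100
    assert n_trees == 100


def test_select_group_tie_breaks_to_smaller_group():
    grid = [50, 100]
    rows = []
    for label in ("C", "D"):
        for t in grid:
            rows.append({"group": label, "n_trees": t, "prediction_accuracy": 0.9, "oob_error": 0.1})
    groups = [FeatureGroup("C", 0.02, ("a",)), FeatureGroup("D", 0.0, ("a", "b"))]
    selected, _ = select_group(pd.DataFrame(rows), groups)
    assert selected.label == "C"


def test_select_group_rejects_nonfinite():
    curves = pd.DataFrame([{"group": "C", "n_trees": 50, "prediction_accuracy": np.nan, "oob_error": 0.1}])
    with pytest.raises(ValueError, match="non-finite"):
        select_group(curves, [FeatureGroup("C", 0.0, ("a",))])


def test_oob_curve_schema_and_determinism(labeled_table):
    X, y = labeled_table
    groups = [FeatureGroup("A", 0.1, ("decisive",)), FeatureGroup("B", 0.0, tuple(X.columns))]
    a = oob_curve(X, y, groups, tree_grid=(25, 50), seed=1)
    b = oob_curve(X, y, groups, tree_grid=(25, 50), seed=1)
    pd.testing.assert_frame_equal(a, b)
    assert set(a.columns) == {"group", "n_trees", "prediction_accuracy", "oob_error"}
    assert len(a) == 4
    assert a[["prediction_accuracy", "oob_error"]].le(1).all().all()


@pytest.mark.parametrize("n,expected", [(1, 1.0), (2, 0.75)])
def test_bootstrap_small_n_matches_inclusion_probability(n, expected):
    # E[distinct fraction] = 1 - (1 - 1/n)^n
    inbag, oob = bootstrap_inbag_fraction(n=n, n_replicates=4000, seed=5)
    assert inbag == pytest.approx(expected, abs=0.02)
    assert inbag + oob == pytest.approx(1.0, abs=1e-12)


def test_bootstrap_large_n_approaches_1_minus_inv_e():
    inbag, oob = bootstrap_inbag_fraction(n=10_000, n_replicates=200, seed=0)
    assert inbag == pytest.approx(1 - np.exp(-1), abs=0.005)
    assert oob == pytest.approx(np.exp(-1), abs=0.005)
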