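"""Classifier contracts: RF voting, Gaussian discriminants, comparators."""

import numpy as np
import pandas as pd
import pytest

from tsvf.classifiers import (
    ClassMap,
    GaussianClassModel,
    LabeledSamples,
    predict_map,
    predict_samples,
    samples_checksum,
    train_ann,
    train_mlc,
    train_rf,
    train_svm,
)


@pytest.fixture
def toy_features():
    rng = np.random.default_rng(0)
    n = 120
    labels = np.repeat(["a", "b", "c"], n // 3)
    X = pd.DataFrame(
        {
            "f1": np.concatenate([rng.normal(m, 0.3, n // 3) for m in (0, 3, 6)]),
            "f2": rng.normal(size=n),
        }
    )
    return X, labels


def test_rf_memorizes_pure_training_set(toy_features):
    # a single unpruned tree grown on the full set memorizes it
    X, y = toy_features
    model = train_rf(X, y, n_trees=1, seed=0, bootstrap=False)
    assert (predict_samples(model, X) == y).mean() == 1.0


def test_rf_prediction_invariant_to_column_permutation(toy_features):
    X, y = toy_features
    model = train_rf(X, y, n_trees=25, seed=0)
    shuffled = X[["f2", "f1"]]
    np.testing.assert_array_equal(predict_samples(model, X), predict_samples(model, shuffled))


def test_rf_refuses_missing_feature(toy_features):
    X, y = toy_features
    model = train_rf(X, y, n_trees=5, seed=0)
    with pytest.raises(ValueError, match="missing features"):
        model.predict(X[["f1"]])


def test_rf_single_class_rejected(toy_features):
    X, _ = toy_features
    with pytest.raises(ValueError, match="2 classes"):
        train_rf(X, np.full(len(X), "a"), n_trees=5)


def test_rf_deterministic_given_seed(toy_features):
    X, y = toy_features
    a = train_rf(X, y, n_trees=30, seed=9)
    b = train_rf(X, y, n_trees=30, seed=9)
    np.testing.assert_array_equal(predict_samples(a, X), predict_samples(b, X))


# --- maximum likelihood -----------------------------------------------------

def _model_1d(means, variances, priors):
    classes = tuple(f"c{i}" for i in range(len(means)))
    return GaussianClassModel(
        classes,
        np.asarray(means, float).reshape(-1, 1),
        np.asarray(variances, float).reshape(-1, 1, 1),
        np.asarray(priors, float),
    )


def test_mlc_hand_computed_discriminant():
    # N(0,1) vs N(3,4), equal priors, x = 1: g1 = -0.5 beats g2 = -ln2 - 0.5
    m = _model_1d([0.0, 3.0], [1.0, 4.0], [0.5, 0.5])
    g = m.discriminants(np.array([[1.0]]))
    assert g[0, 0] - np.log(0.5) == pytest.approx(-0.5)
    assert g[0, 1] - np.log(0.5) == pytest.approx(-np.log(2) - 0.5)
    assert m.predict(np.array([[1.0]]))[0] == "c0"


def test_mlc_tie_breaks_to_first_class():
    # N(0,1), N(2,1): x = 1 is equidistant -> first class wins
    m = _model_1d([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
    assert m.predict(np.array([[1.0]]))[0] == "c0"


def test_mlc_equal_isotropic_covariance_is_nearest_mean():
    rng = np.random.default_rng(1)
    means = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    m = GaussianClassModel(
        ("a", "b", "c"), means, np.tile(np.eye(2) * 0.5, (3, 1, 1)), np.full(3, 1 / 3)
    )
    X = rng.normal(scale=3.0, size=(200, 2))
    nearest = np.argmin(((X[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1)
    np.testing.assert_array_equal(m.predict(X), np.array(["a", "b", "c"])[nearest])


def test_mlc_decision_boundary_is_perpendicular_bisector():
    m = GaussianClassModel(
        ("l", "r"), np.array([[0.0], [2.0]]), np.tile(np.eye(1), (2, 1, 1)), np.array([0.5, 0.5])
    )
    assert m.predict(np.array([[0.99]]))[0] == "l"
    assert m.predict(np.array([[1.01]]))[0] == "r"


def test_train_mlc_regularization_and_singular_error(toy_features):
    X, y = toy_features
    model = train_mlc(X, y, regularization=1e-6)
    assert (predict_samples(model, X) == y).mean() > 0.9
    Xs = X.copy()
    Xs["dup"] = Xs["f1"]  # exactly collinear -> singular covariance
    with pytest.raises(ValueError, match="singular covariance"):
        train_mlc(Xs, y, regularization=0.0)


# --- comparators ------------------------------------------------------------

def test_svm_separable_training_accuracy(toy_features):
    X, y = toy_features
    model = train_svm(X, y, seed=0)
    assert (predict_samples(model, X) == y).mean() == 1.0


def test_ann_deterministic_given_seed(toy_features):
    X, y = toy_features
    a = train_ann(X, y, seed=4, hidden_layer_sizes=(16,), max_iter=200)
    b = train_ann(X, y, seed=4, hidden_layer_sizes=(16,), max_iter=200)
    np.testing.assert_array_equal(predict_samples(a, X), predict_samples(b, X))


# --- map prediction ---------------------------------------------------------

def test_predict_map_nodata_propagation_and_tiling(toy_features):
    X, y = toy_features
    model = train_rf(X, y, n_trees=10, seed=0)
    H = W = 6
    rng = np.random.default_rng(2)
    stack = pd.DataFrame({"f1": rng.normal(3, 2, 30), "f2": rng.normal(size=30)})
    rows, cols = np.divmod(np.arange(30), W)
    stack["row"], stack["col"] = rows, cols
    full = predict_map(model, stack, (H, W))
    tiled = predict_map(model, stack, (H, W), tile_size=7)
    np.testing.assert_array_equal(full.codes, tiled.codes)
    assert (full.codes[5] == 0).all()  # last row never covered -> nodata
    stack_nan = stack.copy()
    stack_nan.loc[0, "f1"] = np.nan
    nanmap = predict_map(model, stack_nan, (H, W))
    assert nanmap.codes[0, 0] == 0


def test_samples_disjointness_enforced_and_checksum_stable():
    with pytest.raises(ValueError, match="overlap"):
        LabeledSamples(
            np.array([1, 1]), np.array([2, 2]), np.array(["a", "a"]), np.array(["train", "validate"])
        )
    s = LabeledSamples(np.array([0, 1]), np.array([0, 1]), np.array(["a", "b"]), np.array(["train", "validate"]))
    assert samples_checksum(s) == samples_checksum(s)


def test_class_map_legend_lookup():
    cmap = ClassMap(np.array([[0, 1], [2, 1]]), {1: "cultivated", 2: "water"})
    names = cmap.class_names()
    assert names[0, 1] == "cultivated" and names[1, 0] == "water" and names[0, 0] == ""
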