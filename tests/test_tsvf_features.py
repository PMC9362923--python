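"""Vector features: hand values, brute-force oracle, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsvf.tsvf_features import (
    FEATURE_KINDS,
    build_feature_table,
    extract_vector,
    feature_matrix_for_parameter,
    reference_vector,
    vector_features,
)
from tsvf.vegindex_bank import evaluate_indices
from tests.conftest import make_cube


def brute_force_features(v):
    """Loop-based oracle for Cos and Dis against the all-ones reference."""
    T = len(v)
    dot = sum(1.0 * v[t] for t in range(T))
    n0 = sum(1.0 for _ in range(T))
    nv = sum(v[t] * v[t] for t in range(T))
    cos = dot / (n0 * nv) ** 0.5
    dis = sum((1.0 - v[t]) ** 2 for t in range(T))
    return cos, dis


def test_hand_computed_features_unit_spike():
    # v = (1, 0, ..., 0) with T = 12
    v = np.zeros(12)
    v[0] = 1.0
    rec = vector_features(v)
    assert rec.Cos == pytest.approx(1 / np.sqrt(12))
    assert rec.Dis == pytest.approx(11.0)
    assert (rec.Max, rec.Min, rec.Ran) == (1.0, 0.0, 1.0)


def test_constant_vector_parallel_to_reference():
    rec = vector_features(np.full(8, 0.37))
    assert rec.Cos == pytest.approx(1.0)
    assert rec.Ran == 0.0


def test_reference_vector_identity():
    rec = vector_features(reference_vector(12))
    assert rec.Dis == 0.0
    assert rec.Cos == pytest.approx(1.0)


def test_oracle_agreement_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        T = rng.integers(2, 24)
        v = rng.uniform(0.001, 2.0, size=T)
        rec = vector_features(v)
        cos, dis = brute_force_features(v)
        assert rec.Cos == pytest.approx(cos, abs=1e-10)
        assert rec.Dis == pytest.approx(dis, abs=1e-10)


@settings(max_examples=200, derandomize=True)
@given(
    v=st.lists(st.floats(min_value=0.01, max_value=5.0), min_size=2, max_size=24),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_cos_scale_invariant_dis_and_ran_not(v, scale):
    v = np.asarray(v)
    a, b = vector_features(v), vector_features(scale * v)
    assert b.Cos == pytest.approx(a.Cos, abs=1e-9)
    if not np.isclose(scale, 1.0):
        if a.Ran > 1e-9:
            assert not np.isclose(b.Ran, a.Ran)
        # Dis changes unless v and scale*v are equidistant from the ones vector
        da, db = a.Dis, b.Dis
        assert (abs(da - db) > 1e-12) or np.isclose(np.sum((1 - v) ** 2), np.sum((1 - scale * v) ** 2))


@settings(max_examples=100, derandomize=True)
@given(
    v=st.lists(st.floats(min_value=0.01, max_value=5.0), min_size=2, max_size=12),
    seed=st.integers(0, 10_000),
)
def test_all_features_permutation_invariant(v, seed):
    # the reference vector is constant, so time order carries no information
    v = np.asarray(v)
    perm = np.random.default_rng(seed).permutation(len(v))
    a, b = vector_features(v), vector_features(v[perm])
    for kind in ("Max", "Min", "Ran", "Cos", "Dis"):
        assert getattr(b, kind) == pytest.approx(getattr(a, kind), abs=1e-12)


def test_cosine_bounds_and_zero_vector_error():
    with pytest.raises(ValueError, match="all-zero"):
        vector_features(np.zeros(5))
    with pytest.raises(ValueError, match="lengths differ"):
        vector_features(np.ones(4), np.ones(5))


def test_literal_cosine_and_rooted_distance_variants():
    v = np.array([1.0, 0.0, 0.0, 0.0])
    lit = vector_features(v, cosine_literal=True)
    assert lit.Cos == pytest.approx(1.0 / (4 * 1.0))  # no radical in denominator
    rooted = vector_features(v, rooted_distance=True)
    assert rooted.Dis == pytest.approx(np.sqrt(3.0))


def test_extract_vector_validation():
    assert extract_vector([1.0, 2.0, 3.0]).tolist() == [1.0, 2.0, 3.0]
    with pytest.raises(ValueError, match="length >= 2"):
        extract_vector([1.0])
    with pytest.raises(ValueError, match="non-finite"):
        extract_vector([1.0, np.nan, 2.0])


def test_feature_matrix_matches_scalar_path():
    rng = np.random.default_rng(3)
    series = rng.uniform(0.01, 1.0, size=(6, 50))
    mat = feature_matrix_for_parameter(series)
    for n in range(50):
        rec = vector_features(series[:, n])
        np.testing.assert_allclose(mat[n], [rec.Cos, rec.Dis, rec.Max, rec.Min, rec.Ran], atol=1e-12)


@pytest.mark.parametrize(
    "n_bands,n_indices,expected_cols",
    [(13, 23, 180), (1, 0, 5), (2, 3, 25)],
)
def test_feature_table_column_cardinality(n_bands, n_indices, expected_cols):
    all_bands = ["B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B9", "B10", "B11", "B12"]
    cube = make_cube(T=3, H=3, W=3, bands=all_bands[:n_bands], seed=1)
    index_cube = None
    if n_indices:
        cube_full = make_cube(T=3, H=3, W=3, bands=all_bands, seed=1)
        index_cube = evaluate_indices(cube_full)
        index_cube.values = index_cube.values[:, :n_indices]
        index_cube.index_names = index_cube.index_names[:n_indices]
        cube = cube_full if n_indices == 23 and n_bands == 13 else cube
    table = build_feature_table(cube, index_cube)
    feature_cols = [c for c in table.columns if c not in ("row", "col")]
    assert len(feature_cols) == expected_cols


def test_feature_table_column_order_and_naming():
    cube = make_cube(T=3, H=2, W=2, bands=("B4", "B8"))
    table = build_feature_table(cube)
    assert list(table.columns[:10]) == [f"B4_{k}" for k in FEATURE_KINDS] + [f"B8_{k}" for k in FEATURE_KINDS]


def test_feature_table_date_mismatch_errors():
    cube = make_cube(T=3, bands=("B2", "B3", "B4", "B5", "B6", "B7", "B8"))
    idx = evaluate_indices(cube)
    idx.dates = ["x"] * 3
    with pytest.raises(ValueError, match="dates"):
        build_feature_table(cube, idx)
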