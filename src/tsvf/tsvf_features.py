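"""Per-pixel time-series vectors and their five vector features.

For each parameter p (a spectral band or a vegetation index) a pixel's
values across the T acquisition dates form an ordered vector V_p.  Five
features summarize it:

* ``Max``, ``Min``, ``Ran`` — the extremes and their difference;
* ``Cos`` — the cosine of the angle between V_p and the all-ones
  reference vector V_0 (cosine similarity);
* ``Dis`` — the squared Euclidean distance between V_0 and V_p.

The squared (un-rooted) distance is kept as the default because a
monotone transform does not affect tree-based classifiers; a rooted
Euclidean variant is available.  A literal variant of the cosine
without the square root in the denominator is likewise available for
comparison but is not the default, as only the rooted form is a true
cosine bounded by 1.

Feature columns are named ``{parameter}_{Cos|Dis|Max|Min|Ran}``
(e.g. ``B12_Cos``, ``NDVI705_Min``), bands first, indices second,
features in the fixed order Cos, Dis, Max, Min, Ran within a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_KINDS",
    "FeatureRecord",
    "reference_vector",
    "extract_vector",
    "vector_features",
    "feature_matrix_for_parameter",
    "build_feature_table",
]

FEATURE_KINDS = ("Cos", "Dis", "Max", "Min", "Ran")


def reference_vector(length: int) -> np.ndarray:
    """The all-ones reference vector V_0."""
    return np.ones(length, dtype=np.float64)


def extract_vector(series: np.ndarray) -> np.ndarray:
    """Validate and return one pixel's time series for a parameter.

    Values must already be ordered by acquisition date ascending; any
    non-finite component flags the pixel invalid for this parameter.
    """
    v = np.asarray(series, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"time series vector requires length >= 2, got shape {v.shape}")
    if not np.isfinite(v).all():
        raise ValueError("time series vector contains non-finite components (pixel invalid)")
    return v


@dataclass(frozen=True)
class FeatureRecord:
    Max: float
    Min: float
    Ran: float
    Cos: float
    Dis: float


def vector_features(
    v: np.ndarray,
    v0: np.ndarray | None = None,
    cosine_literal: bool = False,
    rooted_distance: bool = False,
) -> FeatureRecord:
    """The five vector features of one time-series vector.

    ``cosine_literal`` drops the square root in the cosine denominator
    (sum of squares instead of its root); ``rooted_distance`` returns
    the Euclidean distance instead of its square.
    """
    v = np.asarray(v, dtype=np.float64)
    if v0 is None:
        v0 = reference_vector(v.size)
    v0 = np.asarray(v0, dtype=np.float64)
    if v.shape != v0.shape:
        raise ValueError(f"vector lengths differ: {v.shape} vs {v0.shape}")
    sq = float(np.dot(v, v))
    if sq == 0.0:
        raise ValueError("cosine undefined for the all-zero vector")
    denom = np.dot(v0, v0) * sq
    if not cosine_literal:
        denom = np.sqrt(denom)
    cos = float(np.dot(v0, v) / denom)
    dis = float(np.sum((v0 - v) ** 2))
    if rooted_distance:
        dis = float(np.sqrt(dis))
    mx, mn = float(v.max()), float(v.min())
    return FeatureRecord(Max=mx, Min=mn, Ran=mx - mn, Cos=cos, Dis=dis)


def feature_matrix_for_parameter(
    series: np.ndarray,
    cosine_literal: bool = False,
    rooted_distance: bool = False,
) -> np.ndarray:
    """Vectorized features for one parameter over many pixels.

    ``series`` is T x N (dates by pixels); returns N x 5 in the order
    Cos, Dis, Max, Min, Ran.  Pixels with any NaN yield NaN rows.
    """
    s = np.asarray(series, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("series must be T x N with T >= 2")
    T = s.shape[0]
    sq = np.einsum("tn,tn->n", s, s)
    ssum = s.sum(axis=0)
    denom = T * sq
    if not cosine_literal:
        denom = np.sqrt(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(sq > 0, ssum / denom, np.nan)
    dis = np.einsum("tn,tn->n", 1.0 - s, 1.0 - s)
    if rooted_distance:
        dis = np.sqrt(dis)
    mx = s.max(axis=0)
    mn = s.min(axis=0)
    bad = ~np.isfinite(s).all(axis=0)
    out = np.column_stack([cos, dis, mx, mn, mx - mn])
    out[bad] = np.nan
    return out


def build_feature_table(
    band_cube,
    index_cube=None,
    pixels: tuple[np.ndarray, np.ndarray] | None = None,
    cosine_literal: bool = False,
    rooted_distance: bool = False,
) -> pd.DataFrame:
    """Assemble the per-pixel feature table for bands and indices.

    With 13 bands and 23 indices this yields exactly 180 columns
    (5 features per parameter), bands first in cube order, indices
    second in registry order.  ``pixels`` restricts the table to
    (rows, cols) sample locations; otherwise every valid pixel is used
    and the returned frame carries ``row``/``col`` columns last.
    """
    if index_cube is not None and list(index_cube.dates) != list(band_cube.dates):
        raise ValueError("band cube and index cube have different acquisition dates")
    H, W = band_cube.values.shape[2:]
    if pixels is None:
        rows, cols = np.nonzero(band_cube.valid_mask)
    else:
        rows, cols = (np.asarray(pixels[0], dtype=int), np.asarray(pixels[1], dtype=int))
    params: list[tuple[str, np.ndarray]] = []
    for i, name in enumerate(band_cube.band_names):
        params.append((name, band_cube.values[:, i, rows, cols]))
    if index_cube is not None:
        for k, name in enumerate(index_cube.index_names):
            params.append((name, index_cube.values[:, k, rows, cols]))
    blocks, columns = [], []
    for name, series in params:
        blocks.append(feature_matrix_for_parameter(series, cosine_literal, rooted_distance))
        columns.extend(f"{name}_{kind}" for kind in FEATURE_KINDS)
    table = pd.DataFrame(np.hstack(blocks), columns=columns)
    table["row"] = rows
    table["col"] = cols
    return table
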