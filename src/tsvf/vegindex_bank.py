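"""Registry of the 23 vegetation indices computable from Sentinel-2-style bands.

Each index is a pure per-pixel, per-date band-algebra formula following
the Sentinel-2 toolbox (SNAP) conventions.  Empirical constants — the
soil-adjustment factor L of SAVI, the soil-line slope/intercept of
TSAVI/PVI, the WDVI slope g, the ARVI gamma — are declared per
definition and overridable, since published values vary by site.

Band identifiers follow Sentinel-2 naming: B2 blue, B3 green, B4 red,
B5-B7 red edge, B8 NIR (B8A narrow NIR), B11/B12 SWIR.  All indices are
unitless except S2REP, which is a red-edge inflection wavelength in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "IndexDefinition",
    "IndexRegistry",
    "IndexCube",
    "register_default_indices",
    "evaluate_indices",
    "DEFAULT_INDEX_ORDER",
]

# Canonical registration order (used for deterministic feature-column order).
DEFAULT_INDEX_ORDER = [
    "SAVI", "TSAVI", "MSAVI", "MSAVI2", "DVI", "RVI", "PVI", "IPVI", "WDVI",
    "TNDVI", "GNDVI", "GEMI", "ARVI", "NDI45", "MTCI", "MCARI", "S2REP",
    "IRECI", "PSSR", "NDVI", "NDVI705", "EVI", "EVI2",
]

# Name drift between published tables is absorbed by aliases.
DEFAULT_ALIASES = {"IECI": "IRECI", "PSSRA": "PSSR", "REIP": "S2REP"}


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: name, required bands, constants, formula.

    ``formula`` receives a dict of band arrays (or scalars) plus the
    constants as keyword arguments and returns the index value; it must
    be pure and vectorized.
    """

    name: str
    required_bands: tuple[str, ...]
    formula: Callable[..., np.ndarray]
    constants: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, bands: Mapping[str, np.ndarray], **overrides: float) -> np.ndarray:
        consts = {**self.constants, **overrides}
        missing = [b for b in self.required_bands if b not in bands]
        if missing:
            raise KeyError(f"index {self.name} requires bands {missing}")
        inputs = {b: np.asarray(bands[b], dtype=np.float64) for b in self.required_bands}
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.formula(**inputs, **consts)
        return np.where(np.isfinite(out), out, np.nan) if np.ndim(out) else (out if np.isfinite(out) else np.nan)


class IndexRegistry:
    """Ordered, alias-aware collection of index definitions."""

    def __init__(self) -> None:
        self._defs: dict[str, IndexDefinition] = {}
        self._aliases: dict[str, str] = {}

    def register(self, definition: IndexDefinition) -> None:
        if definition.name in self._defs:
            raise ValueError(f"index {definition.name!r} already registered")
        self._defs[definition.name] = definition

    def alias(self, alias: str, canonical: str) -> None:
        if canonical not in self._defs:
            raise KeyError(f"cannot alias {alias!r}: {canonical!r} not registered")
        self._aliases[alias] = canonical

    def __getitem__(self, name: str) -> IndexDefinition:
        return self._defs[self._aliases.get(name, name)]

    def __contains__(self, name: str) -> bool:
        return name in self._defs or name in self._aliases

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def names(self) -> list[str]:
        return list(self._defs)

    def items(self):
        return self._defs.items()


# --- formulas (SNAP / Sentinel-2 toolbox conventions) ----------------------

def _ndvi(B4, B8):
    return (B8 - B4) / (B8 + B4)


def _savi(B4, B8, L):
    return (1 + L) * (B8 - B4) / (B8 + B4 + L)


def _tsavi(B4, B8, s, a, X):
    return s * (B8 - s * B4 - a) / (a * B8 + B4 - a * s + X * (1 + s * s))


def _msavi(B4, B8, s):
    ndvi = (B8 - B4) / (B8 + B4)
    wdvi = B8 - s * B4
    L = 1 - 2 * s * ndvi * wdvi
    return (1 + L) * (B8 - B4) / (B8 + B4 + L)


def _msavi2(B4, B8):
    rad = (2 * B8 + 1) ** 2 - 8 * (B8 - B4)
    return np.where(rad >= 0, (2 * B8 + 1 - np.sqrt(np.maximum(rad, 0))) / 2, np.nan)


def _dvi(B4, B8):
    return B8 - B4


def _rvi(B4, B8):
    return B8 / B4


def _pvi(B4, B8, a, b):
    return (B8 - a * B4 - b) / np.sqrt(1 + a * a)


def _ipvi(B4, B8):
    return B8 / (B8 + B4)


def _wdvi(B4, B8, g):
    return B8 - g * B4


def _tndvi(B4, B8):
    rad = (B8 - B4) / (B8 + B4) + 0.5
    return np.where(rad >= 0, np.sqrt(np.maximum(rad, 0)), np.nan)


def _gndvi(B3, B8):
    return (B8 - B3) / (B8 + B3)


def _gemi(B4, B8):
    eta = (2 * (B8 * B8 - B4 * B4) + 1.5 * B8 + 0.5 * B4) / (B8 + B4 + 0.5)
    return eta * (1 - 0.25 * eta) - (B4 - 0.125) / (1 - B4)


def _arvi(B2, B4, B8, gamma):
    rb = B4 - gamma * (B2 - B4)
    return (B8 - rb) / (B8 + rb)


def _ndi45(B4, B5):
    return (B5 - B4) / (B5 + B4)


def _mtci(B4, B5, B6):
    return (B6 - B5) / (B5 - B4)


def _mcari(B3, B4, B5):
    return ((B5 - B4) - 0.2 * (B5 - B3)) * (B5 / B4)


def _s2rep(B4, B5, B6, B7):
    return 705.0 + 35.0 * ((B4 + B7) / 2 - B5) / (B6 - B5)


def _ireci(B4, B5, B6, B7):
    return (B7 - B4) / (B5 / B6)


def _pssr(B4, B7):
    return B7 / B4


def _ndvi705(B5, B6):
    return (B6 - B5) / (B6 + B5)


def _evi(B2, B4, B8):
    return 2.5 * (B8 - B4) / (B8 + 6 * B4 - 7.5 * B2 + 1)


def _evi2(B4, B8):
    return 2.5 * (B8 - B4) / (B8 + 2.4 * B4 + 1)


def register_default_indices(
    soil_slope: float = 0.5,
    soil_intercept: float = 0.5,
    tsavi_adjustment: float = 0.08,
    savi_L: float = 0.5,
    wdvi_slope: float = 0.5,
    arvi_gamma: float = 1.0,
) -> IndexRegistry:
    """Build the default registry of 23 vegetation indices.

    Soil-line constants (slope/intercept) feed TSAVI, MSAVI, PVI and
    WDVI; published defaults are used unless site-calibrated values are
    passed in.
    """
    reg = IndexRegistry()
    defs = [
        IndexDefinition("SAVI", ("B4", "B8"), _savi, {"L": savi_L}),
        IndexDefinition("TSAVI", ("B4", "B8"), _tsavi,
                        {"s": soil_slope, "a": soil_intercept, "X": tsavi_adjustment}),
        IndexDefinition("MSAVI", ("B4", "B8"), _msavi, {"s": soil_slope}),
        IndexDefinition("MSAVI2", ("B4", "B8"), _msavi2),
        IndexDefinition("DVI", ("B4", "B8"), _dvi),
        IndexDefinition("RVI", ("B4", "B8"), _rvi),
        IndexDefinition("PVI", ("B4", "B8"), _pvi, {"a": soil_slope, "b": soil_intercept}),
        IndexDefinition("IPVI", ("B4", "B8"), _ipvi),
        IndexDefinition("WDVI", ("B4", "B8"), _wdvi, {"g": wdvi_slope}),
        IndexDefinition("TNDVI", ("B4", "B8"), _tndvi),
        IndexDefinition("GNDVI", ("B3", "B8"), _gndvi),
        IndexDefinition("GEMI", ("B4", "B8"), _gemi),
        IndexDefinition("ARVI", ("B2", "B4", "B8"), _arvi, {"gamma": arvi_gamma}),
        IndexDefinition("NDI45", ("B4", "B5"), _ndi45),
        IndexDefinition("MTCI", ("B4", "B5", "B6"), _mtci),
        IndexDefinition("MCARI", ("B3", "B4", "B5"), _mcari),
        IndexDefinition("S2REP", ("B4", "B5", "B6", "B7"), _s2rep),
        IndexDefinition("IRECI", ("B4", "B5", "B6", "B7"), _ireci),
        IndexDefinition("PSSR", ("B4", "B7"), _pssr),
        IndexDefinition("NDVI", ("B4", "B8"), _ndvi),
        IndexDefinition("NDVI705", ("B5", "B6"), _ndvi705),
        IndexDefinition("EVI", ("B2", "B4", "B8"), _evi),
        IndexDefinition("EVI2", ("B4", "B8"), _evi2),
    ]
    for d in defs:
        reg.register(d)
    for alias, canonical in DEFAULT_ALIASES.items():
        reg.alias(alias, canonical)
    return reg


@dataclass
class IndexCube:
    """T x K x H x W index values with per-index NaN tallies."""

    values: np.ndarray
    index_names: list[str]
    dates: list[str]
    nan_counts: dict[str, int] = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


def evaluate_indices(cube, registry: IndexRegistry | None = None, names: list[str] | None = None) -> IndexCube:
    """Evaluate registered indices on every date and pixel of a cube.

    Division by zero and domain violations (negative radicands) yield
    NaN at the offending pixel; counts are recorded per index.  A
    missing required band raises a configuration error naming both the
    band and the index.
    """
    from tsvf.raster_timeseries import ConfigurationError

    if registry is None:
        registry = register_default_indices()
    names = names or registry.names
    band_arrays = {}
    for name in names:
        for b in registry[name].required_bands:
            if b not in cube.band_names:
                raise ConfigurationError(f"index {name} requires band {b!r}, absent from cube")
            band_arrays.setdefault(b, cube.band(b))
    T = cube.values.shape[0]
    out = np.empty((T, len(names)) + cube.values.shape[2:], dtype=np.float64)
    nan_counts: dict[str, int] = {}
    invalid = ~cube.valid_mask
    for k, name in enumerate(names):
        vals = registry[name](band_arrays)  # T x H x W
        vals = np.where(invalid[None], np.nan, vals)
        out[:, k] = vals
        nan_counts[name] = int(np.isnan(vals[:, cube.valid_mask]).sum())
    return IndexCube(values=out, index_names=list(names), dates=list(cube.dates), nan_counts=nan_counts)
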