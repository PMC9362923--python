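"""Multi-date raster stacks: reading, alignment and normalization.

Scenes are stored one file per acquisition date as multiband TIFFs.
Georeferencing (CRS string, affine transform, band names, nodata value)
travels in the TIFF ImageDescription tag as JSON, so every raster this
package writes is self-describing and round-trips bit-exactly.

The central container is :class:`TimeSeriesCube`, a ``T x B x H x W``
reflectance array with an acquisition-date axis, a shared pixel grid and
a single validity mask (a pixel is valid only if it is valid on every
date — gap filling is out of scope).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Grid",
    "AcquisitionManifest",
    "TimeSeriesCube",
    "read_raster",
    "write_raster",
    "read_manifest",
    "write_manifest",
    "assemble_cube",
    "normalize_bands",
]


class AlignmentError(ValueError):
    """Rasters do not share a common grid and cannot be aligned."""


class ConfigurationError(ValueError):
    """A requested band or parameter is unavailable."""


@dataclass(frozen=True)
class Grid:
    """Pixel grid: CRS plus a north-up affine transform.

    ``transform`` is the GDAL-style 6-tuple ``(a, b, c, d, e, f)`` with
    ``x = c + (col + 0.5) * a`` and ``y = f + (row + 0.5) * e`` at pixel
    centers (b = d = 0 for north-up rasters).
    """

    crs: str
    transform: tuple[float, float, float, float, float, float]
    width: int
    height: int

    def xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b, c, d, e, f = self.transform
        x = c + (np.asarray(col) + 0.5) * a
        y = f + (np.asarray(row) + 0.5) * e
        return x, y

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b, c, d, e, f = self.transform
        col = np.floor((np.asarray(x) - c) / a).astype(int)
        row = np.floor((np.asarray(y) - f) / e).astype(int)
        return row, col

    @property
    def pixel_size(self) -> float:
        return abs(self.transform[0])


def default_grid(width: int, height: int, pixel_size: float = 10.0, crs: str = "EPSG:32650") -> Grid:
    """A synthetic UTM-like grid with the given pixel size (meters)."""
    return Grid(crs=crs, transform=(pixel_size, 0.0, 0.0, 0.0, -pixel_size, 0.0), width=width, height=height)


@dataclass(frozen=True)
class AcquisitionManifest:
    """Ordered (date, raster path) entries; dates strictly increasing."""

    entries: tuple[tuple[str, Path], ...]

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.entries]
        if len(dates) < 2:
            raise ValueError(f"a time series requires at least 2 acquisition dates, got {len(dates)}")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("acquisition dates must be distinct and strictly increasing")

    @property
    def dates(self) -> list[str]:
        return [d for d, _ in self.entries]

    @property
    def paths(self) -> list[Path]:
        return [p for _, p in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def read_manifest(path: str | Path) -> AcquisitionManifest:
    """Read a ``date,path`` manifest (CSV with header, or JSON list)."""
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    if path.suffix.lower() == ".json":
        for rec in json.loads(path.read_text()):
            entries.append((rec["date"], path.parent / rec["path"]))
    else:
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                entries.append((rec["date"], path.parent / rec["path"]))
    return AcquisitionManifest(tuple(entries))


def write_manifest(path: str | Path, dates: Sequence[str], raster_paths: Sequence[Path]) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "path"])
        for d, p in zip(dates, raster_paths):
            writer.writerow([d, Path(p).name if Path(p).parent == path.parent else str(p)])


@dataclass
class TimeSeriesCube:
    """T x B x H x W reflectance stack with dates, band names and a validity mask."""

    values: np.ndarray  # float, NaN on invalid pixels
    band_names: list[str]
    dates: list[str]
    grid: Grid
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError("cube values must be T x B x H x W")
        T, B, H, W = self.values.shape
        if len(self.dates) != T:
            raise ValueError("dates length must equal the time axis")
        if len(self.band_names) != B:
            raise ValueError("band_names length must equal the band axis")
        if len(set(self.band_names)) != B:
            raise ValueError("band names must be unique")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values).all(axis=(0, 1))
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (H, W):
            raise ValueError("valid_mask must be H x W")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def band(self, name: str) -> np.ndarray:
        """T x H x W slice for one band."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise ConfigurationError(f"band {name!r} not in cube (have {self.band_names})") from None
        return self.values[:, i]


# ---------------------------------------------------------------------------
# TIFF I/O

def write_raster(
    path: str | Path,
    values: np.ndarray,
    band_names: Sequence[str],
    grid: Grid,
    nodata: float | None = None,
) -> None:
    """Write a B x H x W array as a multiband TIFF with JSON grid metadata."""
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    meta = {
        "bands": list(band_names),
        "crs": grid.crs,
        "transform": list(grid.transform),
        "nodata": nodata,
    }
    tifffile.imwrite(str(path), values, description=json.dumps(meta), photometric="minisblack")


def read_raster(path: str | Path) -> tuple[np.ndarray, list[str], Grid, float | None]:
    """Read a raster written by :func:`write_raster`.

    Returns ``(values, band_names, grid, nodata)`` with values B x H x W.
    """
    with tifffile.TiffFile(str(path)) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    if values.ndim == 2:
        values = values[None]
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    bands = meta.get("bands") or [f"band{i + 1}" for i in range(values.shape[0])]
    transform = tuple(meta.get("transform", (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)))
    grid = Grid(crs=meta.get("crs", "unknown"), transform=transform, width=values.shape[2], height=values.shape[1])
    return values, list(bands), grid, meta.get("nodata")


def _resample(band: np.ndarray, out_shape: tuple[int, int], method: str) -> np.ndarray:
    """Resample a single 2-D band to out_shape (bilinear or nearest)."""
    zoom = (out_shape[0] / band.shape[0], out_shape[1] / band.shape[1])
    order = 1 if method == "bilinear" else 0
    return ndimage.zoom(band, zoom, order=order, mode="nearest", grid_mode=True)


# ---------------------------------------------------------------------------
# Cube assembly and normalization

def assemble_cube(
    manifest: AcquisitionManifest,
    band_selection: Sequence[str],
    resampling: str = "bilinear",
) -> TimeSeriesCube:
    """Stack the manifest's rasters into an aligned time-series cube.

    Every raster must carry all requested bands.  Bands stored at a
    coarser resolution than the finest raster grid are resampled onto it
    (bilinear by default, nearest by flag).  The cube's validity mask is
    the per-pixel conjunction over all dates and bands: any nodata at any
    date invalidates the pixel.
    """
    if resampling not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling {resampling!r}")
    band_selection = list(band_selection)
    per_date: list[np.ndarray] = []
    ref_grid: Grid | None = None
    for date, path in manifest.entries:
        values, bands, grid, nodata = read_raster(path)
        missing = [b for b in band_selection if b not in bands]
        if missing:
            raise ConfigurationError(f"raster for {date} ({path}) is missing bands {missing}")
        if ref_grid is None:
            ref_grid = grid
        elif grid.crs != ref_grid.crs:
            raise AlignmentError(f"CRS mismatch: {grid.crs} vs {ref_grid.crs} for {path}")
        sel = np.stack([values[bands.index(b)] for b in band_selection]).astype(np.float64)
        if nodata is not None:
            sel[sel == nodata] = np.nan
        if sel.shape[1:] != (ref_grid.height, ref_grid.width):
            h_ratio = ref_grid.height / sel.shape[1]
            w_ratio = ref_grid.width / sel.shape[2]
            if not np.isclose(h_ratio, w_ratio, rtol=0.01):
                raise AlignmentError(
                    f"raster {path} shape {sel.shape[1:]} cannot be aligned to "
                    f"({ref_grid.height}, {ref_grid.width}) by isotropic resampling"
                )
            sel = np.stack([_resample(b, (ref_grid.height, ref_grid.width), resampling) for b in sel])
        per_date.append(sel)
    values = np.stack(per_date)  # T x B x H x W
    return TimeSeriesCube(values=values, band_names=band_selection, dates=manifest.dates, grid=ref_grid)


def normalize_bands(cube: TimeSeriesCube, method: str = "scale10000") -> TimeSeriesCube:
    """Normalize band values to unitless reflectance in [0, 1].

    ``scale10000`` divides stored digital numbers by 10 000 (the L2A
    surface-reflectance convention).  ``minmax_per_band`` maps each
    band's valid values to [0, 1] using that band's min/max pooled over
    all dates; it is idempotent.  Nodata (NaN) is untouched either way.
    """
    values = cube.values.copy()
    if method == "scale10000":
        values /= 10000.0
    elif method == "minmax_per_band":
        for i, name in enumerate(cube.band_names):
            band = values[:, i]
            finite = band[np.isfinite(band)]
            if finite.size == 0:
                continue
            lo, hi = finite.min(), finite.max()
            if hi == lo:
                raise ValueError(f"band {name!r} is constant ({lo}); min-max normalization undefined")
            values[:, i] = (band - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(cube, values=values, valid_mask=cube.valid_mask.copy())
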