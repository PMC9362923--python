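"""Seeded synthetic multi-date multispectral scenes with known truth.

The generator emulates the study conditions the pipeline targets: a
12-date (monthly, October through September) stack of 13
Sentinel-2-style bands over a patch mosaic of six land-cover classes.
Each class owns a seasonal vegetation-fraction profile; per-pixel
reflectance at date t is a linear mix of a class-specific background
spectrum and a green-vegetation spectrum weighted by that fraction,
plus i.i.d. Gaussian noise, clipped to (0, 1):

* cultivated land follows a winter-wheat / summer-corn rotation — two
  green peaks per year (April and August);
* woodland has one broad summer peak of high amplitude;
* grassland one low-amplitude summer peak;
* water is persistently dark, with near-zero NIR;
* artificial surfaces are bright and aseasonal, bare soil duller and
  likewise flat — so at any single date cultivated land is easily
  confused with bare soil (off season) or grassland/woodland (in
  season), while its annual trajectory is unique.

Background (substrate) brightness varies patch to patch — soil
moisture and surface material differ across fields — so brightness
alone cannot separate the aseasonal classes from off-season cropland
on a single date; the temporal trajectory can.

The class mosaic is a seeded Voronoi tessellation of random points.
Pixels near a Voronoi boundary mix the two adjacent class profiles
linearly (mixed-pixel emulation); the truth label stays the nearer
class.  All randomness flows from one root seed through named
substreams (mosaic, noise, sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from tsvf.classifiers import CLASS_CODES, CLASS_SCHEME, ClassMap, LabeledSamples
from tsvf.raster_timeseries import (
    AcquisitionManifest,
    TimeSeriesCube,
    default_grid,
    write_manifest,
    write_raster,
)

__all__ = ["SceneConfig", "SyntheticScene", "generate", "draw_samples", "write_scene", "DEFAULT_BANDS", "DEFAULT_DATES"]

DEFAULT_BANDS = ["B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B9", "B10", "B11", "B12"]

# Monthly acquisitions spanning one agricultural year (Oct..Sep).
DEFAULT_DATES = [
    "2019-10-15", "2019-11-15", "2019-12-15", "2020-01-15", "2020-02-15", "2020-03-15",
    "2020-04-15", "2020-05-15", "2020-06-15", "2020-07-15", "2020-08-15", "2020-09-15",
]

# Endmember spectra over the 13 default bands (surface reflectance).
_VEGETATION = np.array([0.05, 0.04, 0.08, 0.04, 0.15, 0.30, 0.40, 0.45, 0.47, 0.30, 0.05, 0.20, 0.10])
_SOIL = np.array([0.10, 0.12, 0.16, 0.22, 0.26, 0.28, 0.30, 0.32, 0.33, 0.30, 0.08, 0.40, 0.35])
_WATER = np.array([0.080, 0.060, 0.050, 0.030, 0.020, 0.015, 0.010, 0.008, 0.007, 0.005, 0.010, 0.004, 0.003])
_ARTIFICIAL = np.array([0.22, 0.25, 0.27, 0.30, 0.31, 0.32, 0.33, 0.34, 0.34, 0.30, 0.10, 0.38, 0.40])

# Vegetation-fraction trajectories, Oct..Sep.  Cultivated is double
# peaked (wheat in April, corn in August); the off-season troughs make
# it spectrally close to bare soil on single dates.
_VEG_FRACTION = {
    "cultivated": [0.10, 0.25, 0.35, 0.38, 0.40, 0.65, 0.85, 0.60, 0.15, 0.55, 0.80, 0.30],
    "woodland":   [0.45, 0.30, 0.20, 0.18, 0.22, 0.40, 0.60, 0.80, 0.88, 0.90, 0.85, 0.65],
    "grassland":  [0.25, 0.15, 0.08, 0.06, 0.10, 0.20, 0.32, 0.40, 0.42, 0.45, 0.40, 0.32],
    "water":      [0.0] * 12,
    "artificial": [0.0] * 12,
    "bare":       [0.0] * 12,
}

_BACKGROUND = {
    "cultivated": _SOIL,
    "woodland": _SOIL * 0.80,  # litter/shadow under canopy
    "grassland": _SOIL,
    "water": _WATER,
    "artificial": _ARTIFICIAL,
    "bare": _SOIL,  # same substrate as off-season cropland
}

DEFAULT_PROPORTIONS = {
    "cultivated": 0.40, "woodland": 0.15, "grassland": 0.15,
    "water": 0.10, "artificial": 0.10, "bare": 0.10,
}


@dataclass
class SceneConfig:
    """Synthetic-scene parameters; defaults are the reference study conditions."""

    width: int = 256
    height: int = 256
    dates: list[str] = field(default_factory=lambda: list(DEFAULT_DATES))
    bands: list[str] = field(default_factory=lambda: list(DEFAULT_BANDS))
    noise_sd: float = 0.02  # additive reflectance noise per band/date
    brightness_sd: float = 0.10  # per-patch background brightness spread
    boundary_width: float = 1.5  # mixed-pixel zone half-width, pixels
    mean_patch_area: float = 500.0  # pixels^2 per Voronoi patch
    class_proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_proportions) < 2:
            raise ValueError("at least 2 classes required")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.mean_patch_area > self.width * self.height:
            raise ValueError("mean patch area exceeds the scene size")
        for cls in self.class_proportions:
            if cls not in _VEG_FRACTION:
                raise ValueError(f"no profile defined for class {cls!r}")


@dataclass
class SyntheticScene:
    cube: TimeSeriesCube
    truth: ClassMap
    boundary_mask: np.ndarray  # pixels inside the mixed zone
    config: SceneConfig


def _class_profiles(config: SceneConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per class: (background component, vegetation component), each T x B.

    A pixel's noise-free spectrum is ``brightness * background + vegetation``
    where the patch-level brightness factor models substrate variability
    (soil moisture, surface material) that single-date classifiers
    cannot disentangle from vegetation cover.
    """
    band_idx = [DEFAULT_BANDS.index(b) for b in config.bands]
    T = len(config.dates)
    profiles = {}
    for cls in config.class_proportions:
        v = np.resize(np.asarray(_VEG_FRACTION[cls], dtype=float), T)[:, None]
        bg = (1.0 - v) * _BACKGROUND[cls][band_idx]
        veg = v * _VEGETATION[band_idx]
        profiles[cls] = (bg, veg)
    return profiles


def generate(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate a seeded scene: cube, truth map and mixed-pixel mask."""
    config = config or SceneConfig()
    H, W, T, B = config.height, config.width, len(config.dates), len(config.bands)
    ss_mosaic, ss_noise, _ = np.random.SeedSequence(config.seed).spawn(3)
    rng_mosaic = np.random.default_rng(ss_mosaic)
    rng_noise = np.random.default_rng(ss_noise)

    classes = list(config.class_proportions)
    n_patches = max(len(classes), int(round(H * W / config.mean_patch_area)))
    points = rng_mosaic.uniform(0, [H, W], size=(n_patches, 2))
    # every class gets at least one patch; the rest follow the proportions
    props = np.array([config.class_proportions[c] for c in classes], dtype=float)
    props /= props.sum()
    patch_cls = np.concatenate(
        [np.arange(len(classes)), rng_mosaic.choice(len(classes), size=n_patches - len(classes), p=props)]
    )
    patch_cls = patch_cls[rng_mosaic.permutation(n_patches)]

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pix = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    tree = cKDTree(points)
    dist, idx = tree.query(pix, k=2)
    lab1 = patch_cls[idx[:, 0]].reshape(H, W)
    lab2 = patch_cls[idx[:, 1]].reshape(H, W)
    gap = (dist[:, 1] - dist[:, 0]).reshape(H, W)

    w = config.boundary_width
    boundary = (gap < w) & (lab1 != lab2) if w > 0 else np.zeros((H, W), dtype=bool)
    # mixing weight of the second-nearest class, 0.5 exactly on the edge
    alpha = np.zeros((H, W))
    if w > 0:
        alpha = np.where(boundary, 0.5 * (1.0 - gap / w), 0.0)

    profiles = _class_profiles(config)
    bg_arr = np.stack([profiles[c][0] for c in classes])  # C x T x B
    veg_arr = np.stack([profiles[c][1] for c in classes])
    brightness = 1.0
    if config.brightness_sd > 0:
        brightness = np.clip(
            rng_mosaic.normal(1.0, config.brightness_sd, size=n_patches), 0.6, 1.4
        )
    patch1 = idx[:, 0].reshape(H, W)
    patch2 = idx[:, 1].reshape(H, W)
    b1 = brightness[patch1][None, None] if config.brightness_sd > 0 else 1.0
    values = b1 * bg_arr[lab1].transpose(2, 3, 0, 1) + veg_arr[lab1].transpose(2, 3, 0, 1)
    if w > 0:
        b2 = brightness[patch2][None, None] if config.brightness_sd > 0 else 1.0
        mixed = b2 * bg_arr[lab2].transpose(2, 3, 0, 1) + veg_arr[lab2].transpose(2, 3, 0, 1)
        values = (1.0 - alpha) * values + alpha * mixed
    if config.noise_sd > 0:
        values = values + rng_noise.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 1e-4, 1.0 - 1e-4)

    codes = np.zeros((H, W), dtype=np.int16)
    legend = {}
    for i, c in enumerate(classes):
        code = CLASS_CODES.get(c, i + 1)
        codes[lab1 == i] = code
        legend[code] = c
    truth = ClassMap(codes=codes, legend=legend)
    cube = TimeSeriesCube(
        values=values,
        band_names=list(config.bands),
        dates=list(config.dates),
        grid=default_grid(W, H),
    )
    return SyntheticScene(cube=cube, truth=truth, boundary_mask=boundary, config=config)


def draw_samples(
    scene: SyntheticScene,
    n_train_per_class: int | dict[str, int] | None = None,
    n_validate_per_class: int = 500,
    seed: int | None = None,
    pure_only: bool = True,
) -> LabeledSamples:
    """Stratified, disjoint train/validate pixel draws from the truth map.

    The default training count per class is 10x the number of bands
    (130 for 13 bands), with water and bare soil capped at 70 — the
    scarce-class regime of the reference sampling rule.  Reference
    samples are screened to pure (non-boundary) pixels by default,
    mirroring how ground-truth pixels are verified against imagery.
    """
    config = scene.config
    if seed is None:
        _, _, ss_sample = np.random.SeedSequence(config.seed).spawn(3)
        rng = np.random.default_rng(ss_sample)
    else:
        rng = np.random.default_rng(seed)
    default_train = 10 * len(config.bands)
    if n_train_per_class is None:
        n_train = {c: (70 if c in ("water", "bare") else default_train) for c in config.class_proportions}
    elif isinstance(n_train_per_class, int):
        n_train = {c: n_train_per_class for c in config.class_proportions}
    else:
        n_train = dict(n_train_per_class)

    rows, cols, labels, roles = [], [], [], []
    names = scene.truth.class_names()
    for cls in config.class_proportions:
        mask = names == cls
        if pure_only:
            mask &= ~scene.boundary_mask
        rr, cc = np.nonzero(mask)
        need = n_train[cls] + n_validate_per_class
        if len(rr) < need:
            raise ValueError(f"class {cls!r} has only {len(rr)} eligible pixels, need {need}")
        pick = rng.permutation(len(rr))[:need]
        rows.append(rr[pick])
        cols.append(cc[pick])
        labels.append(np.full(need, cls, dtype=object))
        roles.append(np.array(["train"] * n_train[cls] + ["validate"] * n_validate_per_class, dtype=object))
    return LabeledSamples(
        np.concatenate(rows), np.concatenate(cols),
        np.concatenate(labels).astype(str), np.concatenate(roles).astype(str),
    )


def write_scene(scene: SyntheticScene, out_dir: str | Path, samples: LabeledSamples | None = None) -> Path:
    """Write a scene in the pipeline's input contract.

    Per-date multiband TIFFs plus a ``manifest.csv``, a ``truth.tif``
    class raster, and optionally ``samples.csv``.  Returns the manifest
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, date in enumerate(scene.cube.dates):
        p = out_dir / f"scene_{date}.tif"
        write_raster(p, scene.cube.values[t], scene.cube.band_names, scene.cube.grid)
        paths.append(p)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest_path, scene.cube.dates, paths)
    write_raster(out_dir / "truth.tif", scene.truth.codes.astype(np.float64), ["class"], scene.cube.grid)
    if samples is not None:
        samples.to_frame(scene.cube.grid).to_csv(out_dir / "samples.csv", index=False)
    AcquisitionManifest(tuple(zip(scene.cube.dates, paths)))  # sanity: valid contract
    return manifest_path
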