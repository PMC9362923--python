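"""End-to-end workflow: scene -> features -> ranking -> selection -> map -> report.

The reference pipeline bundles the individual stages with sensible
desk-scale defaults so the whole method can run on a synthetic scene in
one call.  Every stage is also usable on its own (the CLI exposes them
as subcommands operating on plain CSV/TIFF/JSON artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tsvf.accuracy import AccuracyReport, confusion, metrics
from tsvf.classifiers import (
    FittedModel,
    LabeledSamples,
    predict_samples,
    samples_checksum,
    train_ann,
    train_mlc,
    train_rf,
    train_svm,
)
from tsvf.feature_selection import (
    DEFAULT_THRESHOLDS,
    FeatureGroup,
    group_by_thresholds,
    importance_scores,
    oob_curve,
    select_group,
)
from tsvf.raster_timeseries import TimeSeriesCube
from tsvf.synthetic_scene import SceneConfig, SyntheticScene, draw_samples, generate
from tsvf.tsvf_features import build_feature_table
from tsvf.vegindex_bank import evaluate_indices, register_default_indices

__all__ = [
    "PipelineResult",
    "sample_feature_table",
    "band_value_table",
    "evaluate_model",
    "run_reference_pipeline",
    "compare_models",
    "DESK_TREE_GRID",
]

# Desk-scale tree grid for selection curves; the full default grid
# (50..1000 step 50) remains available through feature_selection.
DESK_TREE_GRID = (50, 100, 200, 400)


def sample_feature_table(
    cube: TimeSeriesCube,
    samples: LabeledSamples | None = None,
    registry=None,
    undefined_fill: float | None = 0.0,
) -> pd.DataFrame:
    """Vector-feature table (bands + 23 indices) at sample pixels or scene-wide.

    Some indices are undefined on non-vegetated surfaces (negative
    TNDVI radicand over water, near-zero MTCI/S2REP denominators).
    Those NaNs are replaced with ``undefined_fill`` at valid pixels so
    no sample row is lost — for tree-based classifiers only the
    consistency of the convention matters, not the constant.  Pass
    ``undefined_fill=None`` to keep NaNs (rows then drop at training).
    """
    registry = registry or register_default_indices()
    index_cube = evaluate_indices(cube, registry)
    if undefined_fill is not None:
        fill = np.isnan(index_cube.values) & cube.valid_mask[None, None]
        index_cube.values[fill] = undefined_fill
    pixels = (samples.rows, samples.cols) if samples is not None else None
    return build_feature_table(cube, index_cube, pixels=pixels)


def band_value_table(
    cube: TimeSeriesCube,
    samples: LabeledSamples | None = None,
    date_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Raw band values as features (no temporal vector features).

    One column per (band, date): the representation a traditional
    single- or multi-date classifier consumes.  ``date_indices=None``
    stacks all dates; ``[0]`` gives the single-date baseline.
    """
    if samples is not None:
        rows, cols = samples.rows, samples.cols
    else:
        rows, cols = np.nonzero(cube.valid_mask)
    dates = list(date_indices) if date_indices is not None else list(range(len(cube.dates)))
    data, names = [], []
    for t in dates:
        for b, band in enumerate(cube.band_names):
            data.append(cube.values[t, b, rows, cols])
            names.append(f"{band}@{cube.dates[t]}")
    table = pd.DataFrame(np.column_stack(data), columns=names)
    table["row"] = rows
    table["col"] = cols
    return table


def evaluate_model(model: FittedModel, features: pd.DataFrame, samples: LabeledSamples) -> AccuracyReport:
    """Accuracy report of a fitted model on the validation samples."""
    val = samples.subset("validate")
    pred = predict_samples(model, features)
    ref = val.labels.astype(str)
    classes = tuple(sorted(set(ref) | set(pred)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, ([index[r] for r in ref], [index[p] for p in pred]), 1)
    from tsvf.accuracy import ConfusionMatrix

    return metrics(ConfusionMatrix(counts=counts, classes=classes))


@dataclass
class PipelineResult:
    scene: SyntheticScene
    samples: LabeledSamples
    importance: pd.DataFrame
    groups: list[FeatureGroup]
    curves: pd.DataFrame
    selected_group: FeatureGroup
    n_trees: int
    model: FittedModel
    report: AccuracyReport
    baseline_report: AccuracyReport | None = None
    extras: dict = field(default_factory=dict)

    @property
    def oa(self) -> float:
        return self.report.oa


def run_reference_pipeline(
    seed: int = 0,
    config: SceneConfig | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    tree_grid: tuple[int, ...] = DESK_TREE_GRID,
    importance_trees: int = 400,
    with_baseline: bool = True,
) -> PipelineResult:
    """The full method on a seeded synthetic scene.

    Generates the scene, draws stratified samples, extracts the
    180-feature vector-feature table, ranks features by normalized Gini
    importance, forms threshold groups, selects the group and tree
    count from prediction-accuracy/OOB curves, trains the final random
    forest and scores it on the held-out validation pixels.  With
    ``with_baseline`` a no-temporal-information comparator (first-date
    band values only, same samples, same forest size) is scored too.
    """
    config = config or SceneConfig(seed=seed)
    scene = generate(config)
    samples = draw_samples(scene)
    train = samples.subset("train")
    val = samples.subset("validate")

    features = sample_feature_table(scene.cube, samples)
    n = len(train)
    feat_cols = [c for c in features.columns if c not in ("row", "col")]
    # feature rows are in sample order, so the role mask aligns them
    role_mask = samples.roles == "train"
    train_X = features.loc[role_mask, feat_cols].reset_index(drop=True)
    val_X = features.loc[~role_mask, feat_cols].reset_index(drop=True)

    importance = importance_scores(train_X, train.labels, n_trees=importance_trees, seed=seed)
    groups = group_by_thresholds(importance, thresholds)
    curves = oob_curve(train_X, train.labels, groups, tree_grid=tree_grid, seed=seed)
    selected, n_trees = select_group(curves, groups)

    model = train_rf(train_X, train.labels, n_trees=n_trees, seed=seed, feature_names=list(selected.members))
    report = evaluate_model(model, val_X, samples)

    baseline_report = None
    if with_baseline:
        bands = band_value_table(scene.cube, samples, date_indices=[0])
        bcols = [c for c in bands.columns if c not in ("row", "col")]
        b_model = train_rf(bands.loc[role_mask, bcols], train.labels, n_trees=n_trees, seed=seed)
        baseline_report = evaluate_model(b_model, bands.loc[~role_mask, bcols], samples)

    return PipelineResult(
        scene=scene,
        samples=samples,
        importance=importance,
        groups=groups,
        curves=curves,
        selected_group=selected,
        n_trees=n_trees,
        model=model,
        report=report,
        baseline_report=baseline_report,
        extras={"samples_checksum": samples_checksum(samples), "n_train": n, "n_validate": len(val)},
    )


def compare_models(
    scene: SyntheticScene,
    samples: LabeledSamples,
    selected: FeatureGroup,
    n_trees: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark the vector-feature random forest against MLC, SVM and ANN.

    All models consume byte-identical train/validation splits (checksum
    in the ``samples_checksum`` attribute of the returned frame).  The
    comparators classify stacked multi-date band values — the standard
    representation without engineered temporal features; the MTVF model
    uses its selected vector features.
    """
    role_mask = samples.roles == "train"
    train = samples.subset("train")

    features = sample_feature_table(scene.cube, samples)
    feat_cols = [c for c in features.columns if c not in ("row", "col")]
    bands = band_value_table(scene.cube, samples)
    band_cols = [c for c in bands.columns if c not in ("row", "col")]

    tr_f = features.loc[role_mask, feat_cols].reset_index(drop=True)
    va_f = features.loc[~role_mask, feat_cols].reset_index(drop=True)
    tr_b = bands.loc[role_mask, band_cols].reset_index(drop=True)
    va_b = bands.loc[~role_mask, band_cols].reset_index(drop=True)

    models = {
        "MTVF": (train_rf(tr_f, train.labels, n_trees=n_trees, seed=seed, feature_names=list(selected.members)), va_f),
        "MLC": (train_mlc(tr_b, train.labels, regularization=1e-2), va_b),
        "SVM": (train_svm(tr_b, train.labels, seed=seed), va_b),
        "ANN": (train_ann(tr_b, train.labels, seed=seed), va_b),
    }
    rows = []
    for name, (model, val_X) in models.items():
        rep = evaluate_model(model, val_X, samples)
        rows.append(
            {
                "model": name,
                "OA": round(rep.oa * 100, 2),
                "PA_cultivated": round(rep.pa.get("cultivated", np.nan) * 100, 2),
                "UA_cultivated": round(rep.ua.get("cultivated", np.nan) * 100, 2),
                "kappa": round(rep.kappa, 4),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["samples_checksum"] = samples_checksum(samples)
    return out
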