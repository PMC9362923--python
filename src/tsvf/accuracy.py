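"""Confusion-matrix accuracy assessment: OA, PA, UA, kappa.

Orientation is fixed as rows = reference class, columns = predicted
class, so producer's accuracy (PA, recall) is row-wise and user's
accuracy (UA, precision) is column-wise.  Overall accuracy (OA) is
trace/total; kappa is the chance-corrected agreement
(p_o - p_e) / (1 - p_e) with p_e = sum_i row_i * col_i / total^2.

Sub-area evaluation binarizes to cultivated vs non-cultivated; merging
classes before or after counting gives the same 2x2 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tsvf.classifiers import ClassMap, LabeledSamples

__all__ = ["ConfusionMatrix", "AccuracyReport", "confusion", "metrics", "binarize_and_evaluate"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # C x C int, rows = reference, cols = predicted
    classes: tuple[str, ...]
    excluded: int = 0  # validation pixels off-grid or on nodata

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError("confusion matrix must be C x C matching the class list")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass
class AccuracyReport:
    oa: float
    kappa: float
    pa: dict[str, float]  # producer's accuracy per class (reference recall)
    ua: dict[str, float]  # user's accuracy per class (prediction precision)
    ground_truth_pixels: dict[str, int]
    matrix: ConfusionMatrix = field(repr=False)

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        rnd = (lambda v: round(v * scale, 2)) if percent else (lambda v: v)
        return {
            "oa": rnd(self.oa),
            "kappa": round(self.kappa, 4) if percent else self.kappa,
            "pa": {c: rnd(v) for c, v in self.pa.items()},
            "ua": {c: rnd(v) for c, v in self.ua.items()},
            "ground_truth_pixels": self.ground_truth_pixels,
        }


def confusion(class_map: ClassMap, samples: LabeledSamples, classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Tally validation samples against a predicted class map.

    Samples falling outside the grid or on nodata pixels are excluded
    and counted in ``excluded``.  Raises if no sample is usable.
    """
    val = samples.subset("validate") if (samples.roles == "validate").any() else samples
    H, W = class_map.codes.shape
    on_grid = (val.rows >= 0) & (val.rows < H) & (val.cols >= 0) & (val.cols < W)
    rows, cols, ref = val.rows[on_grid], val.cols[on_grid], val.labels[on_grid].astype(str)
    codes = class_map.codes[rows, cols]
    on_data = codes != 0
    excluded = int(len(val) - on_data.sum())
    if not on_data.any():
        raise ValueError("no validation pixels fall on valid map data")
    pred = np.array([class_map.legend[c] for c in codes[on_data]], dtype=object).astype(str)
    ref = ref[on_data]
    if classes is None:
        classes = tuple(sorted(set(ref) | set(pred)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, (np.array([index[r] for r in ref]), np.array([index[p] for p in pred])), 1)
    return ConfusionMatrix(counts=counts, classes=classes, excluded=excluded)


def metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """OA, per-class PA/UA, kappa and ground-truth tallies from a confusion matrix."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(row > 0, diag / row, np.nan)
        ua = np.where(col > 0, diag / col, np.nan)
    oa = float(diag.sum() / total)
    p_e = float((row * col).sum() / total**2)
    kappa = oa if p_e == 1.0 else (oa - p_e) / (1.0 - p_e)
    return AccuracyReport(
        oa=oa,
        kappa=float(kappa),
        pa={c: float(v) for c, v in zip(cm.classes, pa)},
        ua={c: float(v) for c, v in zip(cm.classes, ua)},
        ground_truth_pixels={c: int(r) for c, r in zip(cm.classes, cm.counts.sum(axis=1))},
        matrix=cm,
    )


def binarize_and_evaluate(
    class_map: ClassMap,
    samples: LabeledSamples,
    positive_class: str = "cultivated",
) -> AccuracyReport:
    """Cultivated vs non-cultivated 2x2 assessment of a multiclass map.

    Sample labels may already be binary ("1"/"0" or the class names);
    map classes other than the positive one merge into "non-cultivated"
    before counting.
    """
    if positive_class not in class_map.legend.values():
        raise ValueError(f"map legend lacks the positive class {positive_class!r}")
    neg = f"non-{positive_class}"
    legend2 = {k: (positive_class if v == positive_class else neg) for k, v in class_map.legend.items()}
    merged = ClassMap(codes=class_map.codes.copy(), legend=legend2)

    labels = samples.labels.astype(str)
    bin_labels = np.where(np.isin(labels, ["1", positive_class]), positive_class, neg)
    bin_samples = LabeledSamples(samples.rows, samples.cols, bin_labels, samples.roles)
    cm = confusion(merged, bin_samples, classes=(positive_class, neg))
    return metrics(cm)
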