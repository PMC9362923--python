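"""Classification models: random forest core, maximum likelihood, SVM, ANN.

The random forest is the workhorse (bootstrap-sampled trees, majority
vote); SVM and ANN are thin adapters over established implementations
with developer-recommended defaults, used as comparators on identical
train/validation splits.  The maximum-likelihood classifier (MLC) is
implemented from first principles because the remote-sensing form —
per-class Gaussian discriminants over band values — is not part of the
standard ML libraries:

    g_i(x) = ln pi_i - 1/2 ln|Sigma_i| - 1/2 (x - mu_i)^T Sigma_i^{-1} (x - mu_i)

with ties broken by class order.

All models store the feature-name contract at training time and refuse
prediction on mismatched columns.  Full-scene prediction is tiled so
memory stays bounded; tiling does not change the output.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASS_SCHEME",
    "LabeledSamples",
    "ClassMap",
    "GaussianClassModel",
    "FittedModel",
    "train_rf",
    "train_mlc",
    "train_svm",
    "train_ann",
    "predict_map",
    "predict_samples",
    "samples_checksum",
]

# Fixed 6-class scheme; integer codes are stable for rasters.
CLASS_SCHEME = ("cultivated", "woodland", "grassland", "water", "artificial", "bare")
CLASS_CODES = {name: i + 1 for i, name in enumerate(CLASS_SCHEME)}
NODATA_CODE = 0


@dataclass
class LabeledSamples:
    """Pixel sample points: grid location, class label, train/validate role."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # class names (str) or integer codes
    roles: np.ndarray  # "train" | "validate"

    def __post_init__(self) -> None:
        n = len(self.rows)
        if not (len(self.cols) == len(self.labels) == len(self.roles) == n):
            raise ValueError("sample arrays must have equal length")
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.labels = np.asarray(self.labels)
        self.roles = np.asarray(self.roles)
        train = set(zip(self.rows[self.roles == "train"], self.cols[self.roles == "train"]))
        val = set(zip(self.rows[self.roles == "validate"], self.cols[self.roles == "validate"]))
        if train & val:
            raise ValueError("train and validate samples overlap")

    def subset(self, role: str) -> "LabeledSamples":
        m = self.roles == role
        return LabeledSamples(self.rows[m], self.cols[m], self.labels[m], self.roles[m])

    def to_frame(self, grid=None) -> pd.DataFrame:
        df = pd.DataFrame({"row": self.rows, "col": self.cols, "class": self.labels, "role": self.roles})
        if grid is not None:
            x, y = grid.xy(self.rows, self.cols)
            df.insert(0, "y", y)
            df.insert(0, "x", x)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid=None) -> "LabeledSamples":
        if "row" in df.columns and "col" in df.columns:
            rows, cols = df["row"].to_numpy(int), df["col"].to_numpy(int)
        elif grid is not None and "x" in df.columns:
            rows, cols = grid.rowcol(df["x"].to_numpy(), df["y"].to_numpy())
        else:
            raise ValueError("sample table needs row/col columns, or x/y plus a grid")
        return cls(rows, cols, df["class"].to_numpy(), df["role"].to_numpy())

    def __len__(self) -> int:
        return len(self.rows)


def samples_checksum(samples: LabeledSamples) -> str:
    """Stable digest of a sample split, for logging identical-split guarantees."""
    h = hashlib.sha256()
    for arr in (samples.rows, samples.cols, samples.labels.astype(str), samples.roles.astype(str)):
        h.update(np.ascontiguousarray(arr).tobytes() if arr.dtype.kind in "iuf" else "\x1f".join(map(str, arr)).encode())
    return h.hexdigest()[:16]


@dataclass
class ClassMap:
    """H x W integer class raster with a legend; 0 is nodata."""

    codes: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def class_names(self) -> np.ndarray:
        lut = np.array([""] + [self.legend.get(i, "") for i in range(1, max(self.legend) + 1)], dtype=object)
        return lut[self.codes]


@dataclass
class FittedModel:
    """A trained classifier plus its feature-name contract."""

    estimator: object
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    kind: str
    seed: int | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"prediction input missing features {missing}")
        return self.estimator.predict(X[list(self.feature_names)].to_numpy())


def _check_training(features: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels and features disagree in length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")
    return labels


def train_rf(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = 400,
    seed: int = 0,
    feature_names: list[str] | None = None,
    **rf_kwargs,
) -> FittedModel:
    """Train the random-forest classifier on the selected feature columns.

    Trees are grown on bootstrap resamples of the training pixels and a
    pixel's class is the majority vote.  Extra keyword arguments pass
    through to the forest (e.g. ``bootstrap=False``).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    cols = list(feature_names) if feature_names is not None else list(features.columns)
    labels = _check_training(features[cols], labels)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1, **rf_kwargs)
    rf.fit(features[cols].to_numpy(), labels)
    return FittedModel(rf, tuple(cols), tuple(map(str, rf.classes_)), kind="rf", seed=seed)


# ---------------------------------------------------------------------------
# Maximum likelihood (Gaussian discriminants), from first principles

@dataclass
class GaussianClassModel:
    """Per-class Gaussian statistics backing the maximum-likelihood classifier."""

    classes: tuple[str, ...]
    means: np.ndarray  # C x D
    covariances: np.ndarray  # C x D x D, regularized SPD
    priors: np.ndarray  # C, sums to 1
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        chols, logdets = [], []
        for S in self.covariances:
            L = np.linalg.cholesky(S)
            chols.append(L)
            logdets.append(2.0 * np.log(np.diag(L)).sum())
        self._chol = np.stack(chols)
        self._logdet = np.asarray(logdets)

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """g_i(x) for every sample (N x C)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty((X.shape[0], len(self.classes)))
        for i in range(len(self.classes)):
            diff = (X - self.means[i]).T  # D x N
            w = solve_triangular(self._chol[i], diff, lower=True)
            maha = np.einsum("dn,dn->n", w, w)
            out[:, i] = np.log(self.priors[i]) - 0.5 * self._logdet[i] - 0.5 * maha
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        g = self.discriminants(X)
        # argmax takes the first maximum: ties break by class order
        idx = np.argmax(g, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]


class _MLCAdapter:
    def __init__(self, model: GaussianClassModel):
        self.model = model
        self.classes_ = np.asarray(model.classes)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def train_mlc(
    features: pd.DataFrame,
    labels: np.ndarray,
    regularization: float = 1e-6,
    priors: str = "uniform",
    feature_names: list[str] | None = None,
) -> FittedModel:
    """Fit per-class Gaussians and classify by the largest discriminant.

    Covariances get ``regularization * I`` added (scaled by the mean
    diagonal) so near-singular classes stay invertible; set it to 0 to
    require well-conditioned covariances.  ``priors`` is ``"uniform"``
    or ``"proportional"`` (to class sample counts).
    """
    cols = list(feature_names) if feature_names is not None else list(features.columns)
    labels = _check_training(features[cols], labels)
    X = features[cols].to_numpy(dtype=np.float64)
    classes = tuple(map(str, np.unique(labels)))
    means, covs, counts = [], [], []
    for c in classes:
        Xc = X[labels.astype(str) == c]
        counts.append(len(Xc))
        means.append(Xc.mean(axis=0))
        S = np.cov(Xc, rowvar=False, bias=False) if len(Xc) > 1 else np.zeros((X.shape[1], X.shape[1]))
        S = np.atleast_2d(S)
        if regularization > 0:
            scale = max(np.trace(S) / S.shape[0], 1.0)
            S = S + regularization * scale * np.eye(S.shape[0])
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"singular covariance for class {c!r} "
                f"({counts[-1]} samples, {S.shape[0]} features); increase regularization"
            ) from None
        covs.append(S)
    if priors == "uniform":
        pi = np.full(len(classes), 1.0 / len(classes))
    elif priors == "proportional":
        pi = np.asarray(counts, dtype=float) / sum(counts)
    else:
        raise ValueError(f"unknown priors {priors!r}")
    model = GaussianClassModel(classes, np.stack(means), np.stack(covs), pi)
    return FittedModel(_MLCAdapter(model), tuple(cols), classes, kind="mlc")


# ---------------------------------------------------------------------------
# Comparators: thin adapters with developer-recommended defaults

def train_svm(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
    **svc_kwargs,
) -> FittedModel:
    """Support vector machine comparator (standardized inputs, RBF default)."""
    cols = list(feature_names) if feature_names is not None else list(features.columns)
    labels = _check_training(features[cols], labels)
    est = make_pipeline(StandardScaler(), SVC(random_state=seed, **svc_kwargs))
    est.fit(features[cols].to_numpy(), labels)
    return FittedModel(est, tuple(cols), tuple(map(str, est.classes_)), kind="svm", seed=seed)


def train_ann(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
    **mlp_kwargs,
) -> FittedModel:
    """Multilayer-perceptron comparator; non-convergence warns, never fails."""
    cols = list(feature_names) if feature_names is not None else list(features.columns)
    labels = _check_training(features[cols], labels)
    mlp_kwargs.setdefault("max_iter", 500)
    est = make_pipeline(StandardScaler(), MLPClassifier(random_state=seed, **mlp_kwargs))
    with warnings.catch_warnings():
        warnings.filterwarnings("always")
        est.fit(features[cols].to_numpy(), labels)
    return FittedModel(est, tuple(cols), tuple(map(str, est.classes_)), kind="ann", seed=seed)


# ---------------------------------------------------------------------------
# Full-scene prediction

def predict_samples(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """Predict class names for a feature table (sample points)."""
    return model.predict(features).astype(str)


def predict_map(
    model: FittedModel,
    feature_stack: pd.DataFrame,
    shape: tuple[int, int],
    legend: dict[int, str] | None = None,
    tile_size: int = 65_536,
) -> ClassMap:
    """Classify every valid pixel of a scene into a class raster.

    ``feature_stack`` is a feature table carrying ``row``/``col``
    columns (as produced by the feature builder over a whole scene);
    pixels absent from it stay nodata.  Prediction runs in tiles of
    ``tile_size`` pixels; tiling is output-invariant.
    """
    if legend is None:
        legend = {CLASS_CODES[c]: c for c in model.classes if c in CLASS_CODES}
        if len(legend) != len(model.classes):  # non-scheme labels: enumerate
            legend = {i + 1: c for i, c in enumerate(model.classes)}
    name_to_code = {v: k for k, v in legend.items()}
    codes = np.full(shape, NODATA_CODE, dtype=np.int16)
    rows = feature_stack["row"].to_numpy(int)
    cols = feature_stack["col"].to_numpy(int)
    X = feature_stack[list(model.feature_names)]
    ok = np.isfinite(X.to_numpy()).all(axis=1)
    for start in range(0, len(feature_stack), tile_size):
        sl = slice(start, start + tile_size)
        m = ok[sl]
        if not m.any():
            continue
        pred = model.predict(X.iloc[sl][m]).astype(str)
        codes[rows[sl][m], cols[sl][m]] = [name_to_code[p] for p in pred]
    return ClassMap(codes=codes, legend=legend)
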