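"""Classifier heads and training-set augmentation.

Three heads operate on the 256-dim image feature vectors: an RBF-kernel SVM
(one-vs-rest ensemble of binary machines), a k-nearest-neighbour rule with
k = 1 and Euclidean distance, and the dropout MLP of :mod:`brainstage.mlp`.
Each head is a scikit-learn pipeline whose first step standardises features
using training-fold statistics only.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy import ndimage
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .mlp import MLPDropoutClassifier
from .preprocessing import SliceImage

__all__ = [
    "LabeledFeatureSet",
    "SvmConfig",
    "KnnConfig",
    "DnnConfig",
    "AugmentationSpec",
    "TieBreakKNN",
    "make_classifier",
    "train_svm",
    "train_knn",
    "build_and_train_dnn",
    "predict",
    "augment",
]


@dataclass
class LabeledFeatureSet:
    """n_samples × n_features matrix with class labels and provenance ids."""

    matrix: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.ids is None:
            self.ids = np.array([f"sample{i}" for i in range(len(self.labels))])
        if not len(self.matrix) == len(self.labels) == len(self.ids):
            raise ValueError("matrix rows, labels and ids must align")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing/non-finite values")


@dataclass
class SvmConfig:
    kernel: str = "rbf"  # linear | poly | rbf | sigmoid
    C: float = 1.0
    gamma: float | str = "scale"  # 1 / (n_features * X.var()) by default
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class KnnConfig:
    k: int = 1  # the protocol's choice

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class DnnConfig:
    input_width: int = 256
    hidden_layers: int = 9
    hidden_width: int = 128
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 50
    dropout: float = 0.3
    l2: float = 0.001
    early_stop_patience: int = 10
    output_width: int = 3
    seed: int = 0


class TieBreakKNN(KNeighborsClassifier):
    """KNeighborsClassifier whose majority-vote ties go to the label of the
    single nearest neighbour (instead of the lowest class index)."""

    def predict(self, X):
        dist, idx = self.kneighbors(X)
        y = self._y[idx]  # (n_queries, k) label indices
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for i in range(len(X)):
            counts = np.bincount(y[i], minlength=len(self.classes_))
            top = counts.max()
            tied = np.flatnonzero(counts == top)
            if len(tied) == 1:
                out[i] = self.classes_[tied[0]]
            else:
                # nearest neighbour whose label is among the tied labels
                for j in np.argsort(dist[i], kind="stable"):
                    if y[i][j] in tied:
                        out[i] = self.classes_[y[i][j]]
                        break
        return out


def make_classifier(cfg: SvmConfig | KnnConfig | DnnConfig) -> Pipeline:
    """Build the standardise-then-classify pipeline for a head config."""
    if isinstance(cfg, SvmConfig):
        est = OneVsRestClassifier(
            SVC(
                kernel=cfg.kernel,
                C=cfg.C,
                gamma=cfg.gamma,
                degree=cfg.degree,
                coef0=cfg.coef0,
            )
        )
    elif isinstance(cfg, KnnConfig):
        est = TieBreakKNN(n_neighbors=cfg.k, metric="euclidean")
    elif isinstance(cfg, DnnConfig):
        est = MLPDropoutClassifier(
            hidden_layers=cfg.hidden_layers,
            hidden_units=cfg.hidden_width,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            dropout=cfg.dropout,
            l2=cfg.l2,
            patience=cfg.early_stop_patience,
            random_state=cfg.seed,
        )
    else:
        raise TypeError(f"unknown classifier config {type(cfg).__name__}")
    return Pipeline([("standardize", StandardScaler()), ("clf", est)])


def _fit(data: LabeledFeatureSet, cfg) -> Pipeline:
    if len(np.unique(data.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    model = make_classifier(cfg)
    model.fit(data.matrix, data.labels)
    return model


def train_svm(data: LabeledFeatureSet, cfg: SvmConfig | None = None) -> Pipeline:
    return _fit(data, cfg or SvmConfig())


def train_knn(data: LabeledFeatureSet, cfg: KnnConfig | None = None) -> Pipeline:
    cfg = cfg or KnnConfig()
    if cfg.k > len(data.labels):
        raise ValueError(f"k={cfg.k} exceeds the {len(data.labels)} training samples")
    return _fit(data, cfg)


def build_and_train_dnn(data: LabeledFeatureSet, cfg: DnnConfig | None = None) -> Pipeline:
    cfg = cfg or DnnConfig()
    if data.matrix.shape[1] != cfg.input_width:
        raise ValueError(
            f"feature width {data.matrix.shape[1]} != configured input width "
            f"{cfg.input_width}"
        )
    return _fit(data, cfg)


def predict(model: Pipeline, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus one score per class per row.

    Scores are softmax probabilities for the MLP, one-vs-rest decision values
    for the SVM and neighbour-vote fractions for KNN; all are usable for
    one-vs-rest ROC analysis.
    """
    features = np.asarray(features, dtype=np.float64)
    clf = model.named_steps["clf"]
    n_classes = len(clf.classes_)
    if features.shape[0] == 0:
        return np.empty(0, dtype=clf.classes_.dtype), np.empty((0, n_classes))
    labels = model.predict(features)
    if hasattr(clf, "predict_proba"):
        scores = model.predict_proba(features)
    else:
        scores = model.decision_function(features)
        if scores.ndim == 1:  # binary: expand to per-class columns
            scores = np.column_stack([-scores, scores])
    return labels, scores


# ----------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentationSpec:
    """Seeded random augmentation of training slices.

    Ops: rotate (±degrees), flip (horizontal mirror), shift (± fraction of
    side), scale (zoom range), crop (crop-and-resize fraction),
    gaussian_noise (additive σ).  Magnitudes default to gentle values; all
    sampling is driven by ``seed``.
    """

    ops: tuple[str, ...] = ("rotate", "flip", "shift", "scale", "crop", "gaussian_noise")
    rotate_deg: float = 15.0
    shift_frac: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    crop_frac: float = 0.9
    noise_sigma: float = 0.02
    seed: int = 0

    _KNOWN = ("rotate", "flip", "shift", "scale", "crop", "gaussian_noise")

    def __post_init__(self) -> None:
        for op in self.ops:
            if op not in self._KNOWN:
                raise ValueError(f"unknown augmentation op {op!r}")
        if not self.ops:
            raise ValueError("at least one op required")


def _apply_op(img: np.ndarray, op: str, spec: AugmentationSpec, rng: np.random.Generator) -> np.ndarray:
    if op == "rotate":
        ang = rng.uniform(-spec.rotate_deg, spec.rotate_deg)
        return ndimage.rotate(img, ang, reshape=False, order=1, mode="nearest")
    if op == "flip":
        return img[:, ::-1].copy()
    if op == "shift":
        H, W = img.shape
        dr = rng.uniform(-spec.shift_frac, spec.shift_frac) * H
        dc = rng.uniform(-spec.shift_frac, spec.shift_frac) * W
        return ndimage.shift(img, (dr, dc), order=1, mode="nearest")
    if op == "scale":
        f = rng.uniform(*spec.scale_range)
        zoomed = ndimage.zoom(img, f, order=1, mode="nearest")
        return _fit_to(zoomed, img.shape)
    if op == "crop":
        H, W = img.shape
        h, w = int(round(H * spec.crop_frac)), int(round(W * spec.crop_frac))
        r0 = rng.integers(0, H - h + 1)
        c0 = rng.integers(0, W - w + 1)
        crop = img[r0 : r0 + h, c0 : c0 + w]
        return ndimage.zoom(crop, (H / h, W / w), order=1, mode="nearest")
    if op == "gaussian_noise":
        return np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape), 0.0, 1.0)
    raise ValueError(op)


def _fit_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre-crop or zero-pad to a target shape."""
    out = np.zeros(shape)
    H, W = img.shape
    th, tw = shape
    sr, tr = max(0, (H - th) // 2), max(0, (th - H) // 2)
    sc, tc = max(0, (W - tw) // 2), max(0, (tw - W) // 2)
    h, w = min(H, th), min(W, tw)
    out[tr : tr + h, tc : tc + w] = img[sr : sr + h, sc : sc + w]
    return out


def augment(
    images: list[SliceImage],
    spec: AugmentationSpec,
    n_out: int,
    labels: list[str] | None = None,
) -> tuple[list[SliceImage], list[str] | None]:
    """Grow a training set to ``n_out`` images by seeded random ops.

    Originals are preserved in order; extras cycle through the originals
    (so every original is augmented before any is augmented twice), each
    with a randomly chosen op (uniform over ``spec.ops``), inheriting the
    original's label.  Must only ever receive training-fold images — the
    cross-validation harness enforces this by provenance id.
    """
    if not images:
        raise ValueError("cannot augment an empty image list")
    if n_out < len(images):
        raise ValueError("n_out must be >= number of input images")
    rng = np.random.default_rng(spec.seed)
    out = list(images)
    out_labels = list(labels) if labels is not None else None
    for j in range(n_out - len(images)):
        i = j % len(images)
        op = spec.ops[int(rng.integers(0, len(spec.ops)))]
        aug = _apply_op(images[i].pixels, op, spec, rng)
        out.append(
            SliceImage(
                aug,
                images[i].spacing,
                provenance=f"{images[i].provenance or 'img'}+aug{j}:{op}",
            )
        )
        if out_labels is not None:
            out_labels.append(labels[i])
    return out, out_labels
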