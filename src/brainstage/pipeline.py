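"""End-to-end runs: simulate/load → preprocess → features → cross-validate.

``RunConfig`` mirrors every stage's parameters, round-trips losslessly
through YAML and rejects unknown keys.  One global seed deterministically
derives a per-stage seed by hashing the stage name, so individual stages can
be rerun in isolation with the same randomness.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import (
    AugmentationSpec,
    DnnConfig,
    KnnConfig,
    SvmConfig,
    augment,
    make_classifier,
)
from .evaluate import EvalReport, cross_validate, make_folds
from .features import HarrisHogExtractor
from .phantoms import CLASSES, make_dataset
from .preprocessing import SliceImage

logger = logging.getLogger("brainstage")

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "load_manifest"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31 - 1)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_per_class: int = 150
    size: int = 128
    seed_dataset: int | None = None  # default: derived from the global seed


class FeatureConfig(_Strict):
    kernel_size: int = 5
    sigma: float = 1.0
    harris_k: float = 0.04
    harris_window: int = 5
    rel_threshold: float = 0.01
    nms_radius: float = 5.0
    max_points: int = 200
    pool: str = "mean_max"
    shift_code: bool = False
    min_object_px: int = 0


class ClassifierConfig(_Strict):
    models: list[str] = Field(default_factory=lambda: ["svm", "knn", "dnn"])
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    knn_k: int = 1
    dnn_hidden_layers: int = 9
    dnn_hidden_width: int = 128
    dnn_learning_rate: float = 0.01
    dnn_batch_size: int = 32
    dnn_epochs: int = 50
    dnn_dropout: float = 0.3
    dnn_l2: float = 0.001
    dnn_patience: int = 10
    augment: bool = False  # protocol default: off
    augment_factor: float = 2.0


class EvalConfig(_Strict):
    n_folds: int = 5


class RunConfig(_Strict):
    seed: int = 7
    out_dir: str = "runs/latest"
    verbosity: str = "INFO"
    manifest: str | None = None  # load instead of simulating when set
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    classifiers: ClassifierConfig = Field(default_factory=ClassifierConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def load_manifest(manifest: str | Path) -> tuple[list[SliceImage], list[str]]:
    """Read a (path, label) manifest CSV; paths are relative to the CSV."""
    import pandas as pd
    from imageio.v3 import imread

    from .preprocessing import read_volume, extract_slices

    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    images: list[SliceImage] = []
    labels: list[str] = []
    for _, row in df.iterrows():
        path = manifest.parent / row["path"]
        label = str(row["label"])
        if label not in CLASSES:
            raise ValueError(f"unknown class label {label!r} in manifest")
        if path.suffix in (".nii", ".gz"):
            vol = read_volume(path)
            from .preprocessing import SlicePolicy

            n0 = vol.shape[0]
            for sl in extract_slices(vol, SlicePolicy(axis=0, center_window=min(9, n0))):
                images.append(sl)
                labels.append(label)
        else:
            arr = np.asarray(imread(path), dtype=np.float64)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            images.append(SliceImage(arr / max(arr.max(), 1.0), provenance=str(path)))
            labels.append(label)
    return images, labels


def _classifier_factories(cfg: ClassifierConfig, seed: int):
    factories = {}
    for name in cfg.models:
        if name == "svm":
            c = SvmConfig(kernel="rbf", C=cfg.svm_C, gamma=cfg.svm_gamma)
        elif name == "knn":
            c = KnnConfig(k=cfg.knn_k)
        elif name == "dnn":
            c = DnnConfig(
                hidden_layers=cfg.dnn_hidden_layers,
                hidden_width=cfg.dnn_hidden_width,
                learning_rate=cfg.dnn_learning_rate,
                batch_size=cfg.dnn_batch_size,
                epochs=cfg.dnn_epochs,
                dropout=cfg.dnn_dropout,
                l2=cfg.dnn_l2,
                early_stop_patience=cfg.dnn_patience,
                seed=derive_seed(seed, f"dnn-init"),
            )
        else:
            raise ValueError(f"unknown model {name!r}")
        factories[name] = (lambda cc=c: make_classifier(cc))
    return factories


def run_pipeline(cfg: RunConfig) -> dict[str, EvalReport]:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Outputs: features.csv, metrics.json (one entry per head), per-fold
    confusion CSVs, ROC point CSVs, the effective config and a log of every
    derived seed.
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    if cfg.manifest:
        logger.info("loading manifest %s", cfg.manifest)
        images, labels = load_manifest(cfg.manifest)
    else:
        ds_seed = (
            cfg.simulate.seed_dataset
            if cfg.simulate.seed_dataset is not None
            else derive_seed(cfg.seed, "simulate")
        )
        logger.info("simulating %d phantoms/class (seed %d)", cfg.simulate.n_per_class, ds_seed)
        ds = make_dataset(cfg.simulate.n_per_class, seed=ds_seed, size=cfg.simulate.size)
        images, labels = ds.images, ds.labels

    extractor = HarrisHogExtractor(**cfg.features.model_dump())
    logger.info("extracting features from %d slices", len(images))
    X = extractor.fit_transform(images)
    y = np.asarray(labels)

    import pandas as pd

    feat_df = pd.DataFrame(X)
    feat_df["label"] = y
    feat_df.to_csv(out / "features.csv", index=False)

    folds = make_folds(y, cfg.evaluation.n_folds, derive_seed(cfg.seed, "folds"))

    augmenter = None
    if cfg.classifiers.augment:
        # image-level augmentation of the training fold only: augmented
        # slices are rendered from the fold's originals and their features
        # re-extracted, so test folds are never involved.
        spec = AugmentationSpec(seed=derive_seed(cfg.seed, "augment"))
        factor = cfg.classifiers.augment_factor

        def augmenter(tr_idx, _spec=spec, _factor=factor):
            originals = [images[i] for i in tr_idx]
            n_out = int(round(len(originals) * _factor))
            augmented, _ = augment(originals, _spec, n_out)
            extras = augmented[len(originals):]
            source = [tr_idx[i % len(tr_idx)] for i in range(len(extras))]
            X_extra = extractor.transform(extras) if extras else np.empty((0, X.shape[1]))
            y_extra = y[np.asarray(source, dtype=int)] if extras else np.empty(0, dtype=y.dtype)
            return X_extra, y_extra, np.asarray(source, dtype=int)

    reports: dict[str, EvalReport] = {}
    metrics_json: dict[str, dict] = {}
    for name, factory in _classifier_factories(cfg.classifiers, cfg.seed).items():
        logger.info("cross-validating %s head", name)
        rep = cross_validate(X, y, factory, folds=folds, augmenter=augmenter)
        reports[name] = rep
        metrics_json[name] = rep.as_dict()
        for f, cm in enumerate(rep.fold_confusions):
            pd.DataFrame(
                cm.counts, index=list(cm.class_order), columns=list(cm.class_order)
            ).to_csv(out / f"confusion_{name}_fold{f}.csv")
        roc_rows = []
        for curve in rep.roc:
            if curve.defined:
                for fp, tp in zip(curve.fpr, curve.tpr):
                    roc_rows.append({"class": curve.class_label, "fpr": fp, "tpr": tp})
        pd.DataFrame(roc_rows).to_csv(out / f"roc_{name}.csv", index=False)

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics_json, fh, indent=2, sort_keys=True)
    with open(out / "seeds.json", "w") as fh:
        json.dump(
            {
                "global": cfg.seed,
                "simulate": derive_seed(cfg.seed, "simulate"),
                "folds": derive_seed(cfg.seed, "folds"),
                "dnn-init": derive_seed(cfg.seed, "dnn-init"),
            },
            fh,
            indent=2,
        )
    logger.info("wrote artifacts to %s", out)
    return reports
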