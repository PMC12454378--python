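"""Image → fixed-length feature vector, as a scikit-learn transformer.

``HarrisHogExtractor`` runs the whole feature side of the pipeline on each
slice: Gaussian smoothing, Harris interest-point detection, 16×16 patch
extraction and oriented-gradient description, then pools patch descriptors
into one fixed-length vector per image (mean ‖ max → 256 values by default).
It is stateless (``fit`` only validates), so it never leaks information
across cross-validation folds.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .classify import LabeledFeatureSet
from .descriptors import (
    DESCRIPTOR_LEN,
    aggregate_image_features,
    assemble_descriptor,
    default_cell_pairing,
)
from .harris import HarrisConfig, extract_patches, harris_detect
from .preprocessing import (
    SliceImage,
    gaussian_kernel,
    morphological_cleanup,
    normalize_intensity,
    smooth,
)

__all__ = ["HarrisHogExtractor", "extract_features"]


class HarrisHogExtractor(TransformerMixin, BaseEstimator):
    """Transform a list of 2D slices into an (n_images, n_features) matrix.

    Parameters mirror the stage configs: ``kernel_size``/``sigma`` for the
    Gaussian smoother, ``harris_*`` for the detector, ``pool`` for patch
    aggregation ("mean_max" → 256 features, "mean" → 128), ``shift_code``
    to append the 24 mean shift-code bit counts, ``min_object_px`` (> 0
    enables morphological cleanup before detection).
    """

    def __init__(
        self,
        kernel_size: int = 5,
        sigma: float = 1.0,
        harris_k: float = 0.04,
        harris_window: int = 5,
        harris_window_type: str = "rectangular",
        rel_threshold: float = 0.01,
        nms_radius: float = 5.0,
        max_points: int = 200,
        pool: str = "mean_max",
        shift_code: bool = False,
        signed_orientation: bool = True,
        min_object_px: int = 0,
    ) -> None:
        self.kernel_size = kernel_size
        self.sigma = sigma
        self.harris_k = harris_k
        self.harris_window = harris_window
        self.harris_window_type = harris_window_type
        self.rel_threshold = rel_threshold
        self.nms_radius = nms_radius
        self.max_points = max_points
        self.pool = pool
        self.shift_code = shift_code
        self.signed_orientation = signed_orientation
        self.min_object_px = min_object_px

    @property
    def n_features_out_(self) -> int:
        n = DESCRIPTOR_LEN * (2 if self.pool == "mean_max" else 1)
        if self.shift_code:
            n += len(default_cell_pairing())
        return n

    def _harris_config(self) -> HarrisConfig:
        return HarrisConfig(
            k=self.harris_k,
            window_size=self.harris_window,
            window_type=self.harris_window_type,
            rel_threshold=self.rel_threshold,
            nms_radius=self.nms_radius,
            max_points=self.max_points,
        )

    def fit(self, X, y=None) -> "HarrisHogExtractor":
        # stateless: nothing is learned from the data
        self._validate(X)
        return self

    def _validate(self, X) -> list[np.ndarray]:
        imgs = []
        for i, item in enumerate(X):
            arr = item.pixels if isinstance(item, SliceImage) else np.asarray(item, float)
            if arr.ndim != 2:
                raise ValueError(f"input {i} is not a 2D image")
            imgs.append(arr)
        return imgs

    def transform_one(self, img: SliceImage | np.ndarray) -> np.ndarray:
        sl = normalize_intensity(img if isinstance(img, np.ndarray) else img.pixels)
        sl = smooth(sl, gaussian_kernel(self.kernel_size, self.sigma))
        if self.min_object_px > 0:
            sl = morphological_cleanup(sl, self.min_object_px)
        cfg = self._harris_config()
        points = harris_detect(sl, cfg)
        patches = extract_patches(sl, points)
        descs = [
            assemble_descriptor(
                p, signed=self.signed_orientation, with_shift_code=self.shift_code
            )
            for p in patches
        ]
        fv = aggregate_image_features(
            descs, method=self.pool, include_shift_counts=self.shift_code
        )
        return fv.values

    def transform(self, X) -> np.ndarray:
        imgs = self._validate(X)
        import warnings as _w

        out = np.empty((len(imgs), self.n_features_out_))
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # empty-detection warnings per image
            for i, img in enumerate(imgs):
                out[i] = self.transform_one(img)
        return out


def extract_features(
    images: list[SliceImage],
    labels: list[str] | None = None,
    extractor: HarrisHogExtractor | None = None,
) -> LabeledFeatureSet:
    """Functional wrapper: images (+labels) → :class:`LabeledFeatureSet`."""
    extractor = extractor or HarrisHogExtractor()
    matrix = extractor.fit_transform(images)
    ids = np.array(
        [
            (img.provenance if isinstance(img, SliceImage) and img.provenance else f"img{i}")
            for i, img in enumerate(images)
        ]
    )
    return LabeledFeatureSet(
        matrix=matrix,
        labels=np.asarray(labels) if labels is not None else np.array([""] * len(images)),
        ids=ids,
    )
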