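"""Harris corner detection and fixed-size patch extraction.

The detector scores every pixel with R = det(M) − k·trace(M)², where M is the
windowed second-moment (structure) tensor of the image gradients.  Pixels
whose R exceeds a fraction of the global maximum, survive non-maximum
suppression and sit far enough from the border to carry a 16×16 patch become
interest points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocessing import SliceImage, gaussian_kernel

PATCH_SIZE = 16
_HALF = PATCH_SIZE // 2

__all__ = [
    "PATCH_SIZE",
    "GradientField",
    "HarrisConfig",
    "InterestPoint",
    "Patch",
    "image_gradients",
    "structure_tensor",
    "harris_response",
    "detect_interest_points",
    "extract_patches",
]


@dataclass
class GradientField:
    """Central-difference gradients: gx along columns (x, rightward) and gy
    along rows measured upward, i.e. gy(r,c) = I(r−1,c) − I(r+1,c)."""

    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        if self.gx.shape != self.gy.shape:
            raise ValueError("gradient components must share a shape")


@dataclass
class HarrisConfig:
    k: float = 0.04
    window_size: int = 5
    window_type: str = "rectangular"  # or "gaussian"
    rel_threshold: float = 0.01
    nms_radius: float = 5.0
    max_points: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 0.25:
            raise ValueError(f"k must lie in (0, 0.25), got {self.k}")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if not 0.0 < self.rel_threshold <= 1.0:
            raise ValueError("rel_threshold must lie in (0, 1]")
        if self.window_type not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown window_type {self.window_type!r}")


@dataclass(frozen=True)
class InterestPoint:
    row: int
    col: int
    response: float


@dataclass
class Patch:
    """A 16×16 window centred (top-left at centre −8) on an interest point."""

    pixels: np.ndarray = field(repr=False)
    center: InterestPoint | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.pixels.shape}"
            )


def _pixels(img: SliceImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, SliceImage) else np.asarray(img, float)


def image_gradients(img: SliceImage | np.ndarray) -> GradientField:
    """gx = I(r,c+1) − I(r,c−1), gy = I(r−1,c) − I(r+1,c), replicate borders."""
    I = _pixels(img)
    if I.shape[0] < 3 or I.shape[1] < 3:
        raise ValueError(f"image too small for gradients: {I.shape}")
    P = np.pad(I, 1, mode="edge")
    gx = P[1:-1, 2:] - P[1:-1, :-2]
    gy = P[:-2, 1:-1] - P[2:, 1:-1]
    return GradientField(gx=gx, gy=gy)


def _window_weights(cfg: HarrisConfig) -> np.ndarray:
    if cfg.window_type == "rectangular":
        return np.ones((cfg.window_size, cfg.window_size))
    return gaussian_kernel(cfg.window_size, cfg.window_size / 5.0).weights


def structure_tensor(grad: GradientField, cfg: HarrisConfig | None = None) -> np.ndarray:
    """Per-pixel windowed 2×2 tensor [[Σgx², Σgxgy], [Σgxgy, Σgy²]].

    Returns an array of shape (H, W, 2, 2); window sums use replicate padding
    so border tensors stay positive semi-definite.
    """
    if cfg is None:
        cfg = HarrisConfig()
    if not (np.all(np.isfinite(grad.gx)) and np.all(np.isfinite(grad.gy))):
        raise ValueError("gradient field contains non-finite values")
    w = _window_weights(cfg)
    xx = ndimage.convolve(grad.gx * grad.gx, w, mode="nearest")
    xy = ndimage.convolve(grad.gx * grad.gy, w, mode="nearest")
    yy = ndimage.convolve(grad.gy * grad.gy, w, mode="nearest")
    M = np.empty(xx.shape + (2, 2))
    M[..., 0, 0] = xx
    M[..., 0, 1] = xy
    M[..., 1, 0] = xy
    M[..., 1, 1] = yy
    return M


def harris_response(M: np.ndarray, k: float = 0.04) -> np.ndarray:
    """R = det(M) − k·trace(M)², evaluated per pixel.

    det(M) = λ1·λ2 and trace(M) = λ1+λ2 for the tensor eigenvalues, so an
    isotropic tensor λI scores λ²(1−4k) > 0 for k < 0.25 while a pure edge
    (one zero eigenvalue) scores −k·λ² ≤ 0.
    """
    xx, xy, yy = M[..., 0, 0], M[..., 0, 1], M[..., 1, 1]
    det = xx * yy - xy * xy
    trace = xx + yy
    return det - k * trace * trace


def detect_interest_points(
    R: np.ndarray, cfg: HarrisConfig | None = None
) -> list[InterestPoint]:
    """Threshold + 3×3 local-maximum test + greedy radius NMS + border filter.

    Points keep only if R ≥ rel_threshold·max(R), R is a strict 3×3 local
    maximum, no stronger accepted point lies within ``nms_radius`` px, and the
    point is at least 8 px from every border (so a 16×16 patch fits).  At most
    ``max_points`` strongest points are returned.
    """
    if cfg is None:
        cfg = HarrisConfig()
    R = np.asarray(R, dtype=np.float64)
    if not np.all(np.isfinite(R)):
        raise ValueError("response map contains non-finite values")
    rmax = R.max()
    if rmax <= 0:
        warnings.warn("no positive Harris response: no interest points")
        return []
    thresh = cfg.rel_threshold * rmax
    local_max = R == ndimage.maximum_filter(R, size=3, mode="nearest")
    rows, cols = np.nonzero((R >= thresh) & local_max)
    resp = R[rows, cols]
    H, W = R.shape
    inside = (
        (rows >= _HALF)
        & (rows <= H - _HALF)
        & (cols >= _HALF)
        & (cols <= W - _HALF)
        # top-left at (row-8, col-8), extent 16: row+7 <= H-1 and col+7 <= W-1
        & (rows + _HALF - 1 <= H - 1)
        & (cols + _HALF - 1 <= W - 1)
    )
    rows, cols, resp = rows[inside], cols[inside], resp[inside]
    order = np.argsort(-resp, kind="stable")
    accepted: list[InterestPoint] = []
    acc_rc: list[tuple[int, int]] = []
    r2 = cfg.nms_radius**2
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if any((r - ar) ** 2 + (c - ac) ** 2 < r2 for ar, ac in acc_rc):
            continue
        accepted.append(InterestPoint(row=r, col=c, response=float(resp[i])))
        acc_rc.append((r, c))
        if len(accepted) >= cfg.max_points:
            break
    if not accepted:
        warnings.warn("all candidate points suppressed: no interest points")
    return accepted


def harris_detect(
    img: SliceImage | np.ndarray, cfg: HarrisConfig | None = None
) -> list[InterestPoint]:
    """Convenience: gradients → structure tensor → response → detection."""
    if cfg is None:
        cfg = HarrisConfig()
    grad = image_gradients(img)
    M = structure_tensor(grad, cfg)
    R = harris_response(M, cfg.k)
    return detect_interest_points(R, cfg)


def extract_patches(
    img: SliceImage | np.ndarray, points: list[InterestPoint]
) -> list[Patch]:
    """Cut one 16×16 patch per point, top-left at (row−8, col−8)."""
    I = _pixels(img)
    H, W = I.shape
    patches: list[Patch] = []
    for p in points:
        r0, c0 = p.row - _HALF, p.col - _HALF
        if r0 < 0 or c0 < 0 or r0 + PATCH_SIZE > H or c0 + PATCH_SIZE > W:
            raise ValueError(
                f"point ({p.row}, {p.col}) too close to border of {I.shape} "
                f"for a {PATCH_SIZE}x{PATCH_SIZE} patch"
            )
        patches.append(
            Patch(pixels=I[r0 : r0 + PATCH_SIZE, c0 : c0 + PATCH_SIZE].copy(), center=p)
        )
    return patches
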