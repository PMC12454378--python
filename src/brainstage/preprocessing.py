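"""Reading, normalising and denoising MR images.

All raster grids in this package are row-major, 0-based, indexed ``(row, col)``;
``row`` increases downward, ``col`` increases rightward.  Slices are stored as
float64 arrays; after :func:`normalize_intensity` values lie in ``[0, 1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import footprint_rectangle, opening

__all__ = [
    "VolumeImage",
    "SliceImage",
    "GaussianKernel",
    "SlicePolicy",
    "read_volume",
    "resample_volume",
    "normalize_intensity",
    "gaussian_kernel",
    "smooth",
    "morphological_cleanup",
    "extract_slices",
]


@dataclass
class VolumeImage:
    """A 3D intensity grid with per-axis physical voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class SliceImage:
    """A 2D slice; ``pixels[row, col]``, spacing ``(row_mm, col_mm)``.

    ``provenance`` records where the slice came from (source path and slice
    index, or a fixture/phantom tag) so evaluation can trace every sample.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class GaussianKernel:
    """Discrete 2D Gaussian G(x, y) = exp(-(x²+y²)/2σ²) / (2πσ²) on the
    centred integer lattice, renormalised to unit sum."""

    size: int
    sigma: float
    weights: np.ndarray = field(repr=False)


@dataclass
class SlicePolicy:
    """Which slices of a volume feed the 2D pipeline.

    Either ``indices`` (explicit) or ``center_window`` (odd-or-even count of
    slices centred on the middle of ``axis``) must be given.
    """

    axis: int = 0
    indices: Sequence[int] | None = None
    center_window: int | None = None

    def resolve(self, n_slices: int) -> list[int]:
        if (self.indices is None) == (self.center_window is None):
            raise ValueError("give exactly one of indices / center_window")
        if self.indices is not None:
            idx = sorted(int(i) for i in self.indices)
        else:
            w = int(self.center_window)  # type: ignore[arg-type]
            if w < 1 or w > n_slices:
                raise IndexError(
                    f"center window of {w} does not fit in {n_slices} slices"
                )
            mid = n_slices // 2
            lo = mid - w // 2
            idx = list(range(lo, lo + w))
        for i in idx:
            if i < 0 or i >= n_slices:
                raise IndexError(f"slice index {i} out of range [0, {n_slices})")
        return idx


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI (.nii / .nii.gz) volume.

    Raises a descriptive error naming the file for missing, unparsable or
    non-3D inputs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"could not parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got payload of shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(
        voxels=data,
        spacing=tuple(float(z) for z in zooms),  # type: ignore[arg-type]
        affine=np.asarray(img.affine),
        source=str(path),
    )


def resample_volume(
    vol: VolumeImage, target_spacing: float | Sequence[float]
) -> VolumeImage:
    """Trilinear resample to a uniform target voxel spacing (mm per axis)."""
    if np.isscalar(target_spacing):
        target = (float(target_spacing),) * 3
    else:
        target = tuple(float(t) for t in target_spacing)  # type: ignore[union-attr]
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    factors = [s / t for s, t in zip(vol.spacing, target)]
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return VolumeImage(vol.voxels.copy(), target, vol.affine, vol.source)
    out_shape = [max(1, int(round(n * f))) for n, f in zip(vol.shape, factors)]
    # output voxel i sits at physical position i*target mm, i.e. input index
    # i*target/spacing — trilinear interpolation at exactly those positions
    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(out_shape, target, vol.spacing)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        vol.voxels, np.stack(grids), order=1, mode="nearest"
    )
    return VolumeImage(out, target, vol.affine, vol.source)


def normalize_intensity(
    img: np.ndarray | SliceImage,
    percentile_clip: tuple[float, float] | None = None,
) -> SliceImage:
    """Linear histogram stretch of a 2D grid to ``[0, 1]``.

    The map is monotone, so pixel ordering is preserved.  With
    ``percentile_clip=(lo, hi)`` the stretch endpoints are those intensity
    percentiles and values outside are clipped (robust to hot pixels).
    A constant image cannot be stretched: all zeros are returned with a
    warning.
    """
    if isinstance(img, SliceImage):
        pixels, spacing, prov = img.pixels, img.spacing, img.provenance
    else:
        pixels = np.asarray(img, dtype=np.float64)
        spacing, prov = (1.0, 1.0), None
    if percentile_clip is not None:
        lo, hi = np.percentile(pixels, percentile_clip)
    else:
        lo, hi = pixels.min(), pixels.max()
    if hi <= lo:
        warnings.warn("constant image: degenerate stretch, returning zeros")
        return SliceImage(np.zeros_like(pixels), spacing, prov)
    out = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    return SliceImage(out, spacing, prov)


def gaussian_kernel(size: int = 5, sigma: float = 1.0, normalize: bool = True) -> GaussianKernel:
    """Evaluate the 2D Gaussian on a ``size``×``size`` centred lattice.

    Unnormalised, the centre weight at σ=1 is 1/(2π); with ``normalize``
    (default) the weights are rescaled to sum to exactly 1 so that smoothing
    preserves the mean intensity.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    w = np.exp(-(x**2 + y**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    if normalize:
        w = w / w.sum()
    return GaussianKernel(size=size, sigma=sigma, weights=w)


def smooth(img: SliceImage | np.ndarray, kernel: GaussianKernel | None = None) -> SliceImage:
    """Convolve with a Gaussian kernel, replicate-padded at the borders."""
    if kernel is None:
        kernel = gaussian_kernel(5, 1.0)
    sl = img if isinstance(img, SliceImage) else SliceImage(np.asarray(img, float))
    if kernel.size > min(sl.shape):
        raise ValueError(
            f"kernel of size {kernel.size} larger than image {sl.shape}"
        )
    out = ndimage.convolve(sl.pixels, kernel.weights, mode="nearest")
    return SliceImage(out, sl.spacing, sl.provenance)


def morphological_cleanup(img: SliceImage, min_object_px: int = 64) -> SliceImage:
    """Suppress small bright objects and thin lines, keeping large structures.

    A binary support mask is obtained by Otsu thresholding, opened with a 3×3
    structuring element, and connected components smaller than
    ``min_object_px`` are identified.  Pixels belonging to removed components
    are zeroed; every other pixel (large objects and background) is untouched.
    """
    if min_object_px < 1:
        raise ValueError("min_object_px must be >= 1")
    pixels = img.pixels
    if pixels.max() <= pixels.min():  # no foreground/background contrast
        return SliceImage(pixels.copy(), img.spacing, img.provenance)
    mask = pixels > threshold_otsu(pixels)
    opened = opening(mask, footprint_rectangle((3, 3)))
    labels, n = cc_label(opened, return_num=True)
    keep = opened.copy()
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_object_px:
            keep[comp] = False
    # thin lines / specks are wiped both where opening removed them and where
    # a surviving component was too small
    removed = mask & ~keep
    out = pixels.copy()
    out[removed] = 0.0
    if not keep.any():
        warnings.warn("morphological cleanup removed all foreground objects")
    return SliceImage(out, img.spacing, img.provenance)


def extract_slices(vol: VolumeImage, policy: SlicePolicy | None = None) -> list[SliceImage]:
    """Cut 2D slices out of a volume per ``policy`` and min-max normalise each.

    Default policy: 9 axial slices centred on the middle of axis 0.
    """
    if policy is None:
        policy = SlicePolicy(axis=0, center_window=9)
    n = vol.shape[policy.axis]
    idx = policy.resolve(n)
    spacing3 = vol.spacing
    keep_axes = [a for a in range(3) if a != policy.axis]
    spacing2 = (spacing3[keep_axes[0]], spacing3[keep_axes[1]])
    out: list[SliceImage] = []
    for i in idx:
        plane = np.take(vol.voxels, i, axis=policy.axis)
        sl = normalize_intensity(plane)
        sl.spacing = spacing2
        sl.provenance = f"{vol.source or '<memory>'}[axis{policy.axis}:{i}]"
        out.append(sl)
    return out
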