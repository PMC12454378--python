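"""Synthetic brain-like phantom slices with class-dependent structure.

The three dementia stages are emulated by the gross structural changes a
radiologist would name: ventricular enlargement (bigger dark centre),
cortical thinning (narrower mid-gray ring) and sulcal widening (dark notches
cut into the cortical ring), ordered CN → MCI → AD.  Phantoms are concentric
— bright skull rim, mid-gray cortical ring, brighter white-matter annulus,
dark central ventricle — plus seeded notches and additive Gaussian noise.

These phantoms exercise every pipeline stage with known effect sizes; they
make no claim to anatomical realism (no tissue relaxometry, no acquisition
physics).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocessing import SliceImage, VolumeImage

CLASSES = ("CN", "MCI", "AD")

__all__ = [
    "CLASSES",
    "PhantomSpec",
    "PhantomDataset",
    "CLASS_PRESETS",
    "make_phantom",
    "make_dataset",
    "save_dataset",
    "dataset_to_volume",
    "corner_fixture",
    "gradient_fixture",
    "impulse_fixture",
]


@dataclass(frozen=True)
class PhantomSpec:
    class_label: str = "CN"
    size: int = 128
    ventricle_scale: float = 0.16  # ventricle radius / brain radius
    cortical_thickness: float = 13.0  # px
    irregularity: int = 1  # number of cortical notches
    noise_sigma: float = 0.03
    seed: int = 0
    center_jitter: float = 0.0  # px, applied to the brain centre

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("phantom size must be >= 64")
        if not 0.0 < self.ventricle_scale < 1.0:
            raise ValueError("ventricle_scale must lie in (0, 1)")


# Default per-class presets: ventricle grows and cortex thins CN -> MCI -> AD,
# with increasing sulcal irregularity.  Effect sizes are deliberately large
# relative to the 0.03 noise floor so the descriptor pipeline separates the
# classes cleanly; see docs/methods.md.
CLASS_PRESETS: dict[str, PhantomSpec] = {
    "CN": PhantomSpec(class_label="CN", ventricle_scale=0.16, cortical_thickness=13.0, irregularity=1),
    "MCI": PhantomSpec(class_label="MCI", ventricle_scale=0.26, cortical_thickness=10.0, irregularity=4),
    "AD": PhantomSpec(class_label="AD", ventricle_scale=0.38, cortical_thickness=7.0, irregularity=8),
}

# tissue intensities (arbitrary units in [0, 1])
_BG, _SKULL, _CORTEX, _WHITE, _VENTRICLE, _NOTCH = 0.05, 0.92, 0.55, 0.80, 0.10, 0.12


def make_phantom(spec: PhantomSpec) -> SliceImage:
    """Render one phantom slice; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    S = spec.size
    brain_r = 0.42 * S
    skull_w = max(2.0, 0.02 * S)
    if spec.cortical_thickness >= brain_r * (1.0 - spec.ventricle_scale):
        raise ValueError(
            f"cortical thickness {spec.cortical_thickness} cannot fit between "
            f"ventricle and skull at size {spec.size}"
        )
    cy = (S - 1) / 2.0 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    cx = (S - 1) / 2.0 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    yy, xx = np.mgrid[0:S, 0:S]
    r = np.hypot(yy - cy, xx - cx)

    img = np.full((S, S), _BG)
    img[r < brain_r + skull_w] = _SKULL
    img[r < brain_r] = _CORTEX
    img[r < brain_r - spec.cortical_thickness] = _WHITE
    vent_r = spec.ventricle_scale * brain_r
    img[r < vent_r] = _VENTRICLE

    # sulcal widening: dark notches centred on the cortical ring
    ring_r = brain_r - spec.cortical_thickness / 2.0
    notch_r = spec.cortical_thickness / 2.0 + 1.0
    for _ in range(spec.irregularity):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ny = cy + ring_r * np.sin(ang)
        nx = cx + ring_r * np.cos(ang)
        img[np.hypot(yy - ny, xx - nx) < notch_r] = _NOTCH

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return SliceImage(
        np.clip(img, 0.0, 1.0),
        provenance=f"phantom:{spec.class_label}:seed{spec.seed}",
    )


@dataclass
class PhantomDataset:
    images: list[SliceImage]
    labels: list[str]
    specs: list[PhantomSpec]
    manifest_path: Path | None = None

    def __post_init__(self) -> None:
        if not len(self.images) == len(self.labels) == len(self.specs):
            raise ValueError("images, labels and specs must have equal lengths")


def make_dataset(
    n_per_class: int,
    presets: dict[str, PhantomSpec] | None = None,
    seed: int = 7,
    size: int | None = None,
) -> PhantomDataset:
    """``n_per_class`` phantoms per class with seeded per-image jitter of the
    structural parameters (ventricle ±0.02, thickness ±1 px, centre ±2 px)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    presets = presets or CLASS_PRESETS
    rng = np.random.default_rng(seed)
    images, labels, specs = [], [], []
    for label in CLASSES:
        base = presets[label]
        if size is not None:
            base = replace(base, size=size)
        for _ in range(n_per_class):
            spec = replace(
                base,
                ventricle_scale=float(
                    np.clip(base.ventricle_scale + rng.uniform(-0.02, 0.02), 0.05, 0.9)
                ),
                cortical_thickness=float(
                    max(3.0, base.cortical_thickness + rng.uniform(-1.0, 1.0))
                ),
                center_jitter=2.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            images.append(make_phantom(spec))
            labels.append(label)
            specs.append(spec)
    return PhantomDataset(images=images, labels=labels, specs=specs)


def save_dataset(ds: PhantomDataset, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write images (PNG or single-slice NIfTI) plus a manifest CSV
    (path, label, seed); returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "seed"])
        for i, (img, label, spec) in enumerate(zip(ds.images, ds.labels, ds.specs)):
            if fmt == "png":
                from imageio.v3 import imwrite

                name = f"{i:05d}_{label}.png"
                imwrite(out_dir / name, (img.pixels * 255).round().astype(np.uint8))
            elif fmt == "nifti":
                name = f"{i:05d}_{label}.nii.gz"
                nib.save(
                    nib.Nifti1Image(img.pixels[None, :, :].astype(np.float32), np.eye(4)),
                    out_dir / name,
                )
            else:
                raise ValueError(f"unknown format {fmt!r}")
            writer.writerow([name, label, spec.seed])
    ds.manifest_path = manifest
    return manifest


def dataset_to_volume(spec: PhantomSpec, n_slices: int = 9, seed: int = 0) -> VolumeImage:
    """Stack jittered copies of a phantom into a thin 3D volume (axis 0),
    to exercise the NIfTI read/slice-extraction path."""
    rng = np.random.default_rng(seed)
    slices = [
        make_phantom(replace(spec, seed=int(rng.integers(0, 2**31 - 1)), center_jitter=1.0))
        for _ in range(n_slices)
    ]
    return VolumeImage(
        voxels=np.stack([s.pixels for s in slices]),
        spacing=(1.0, 1.0, 1.0),
    )


# ----------------------------------------------------------------------------
# analytic unit-test fixtures


def corner_fixture(
    size: int = 64,
    corner_pos: tuple[int, int] = (20, 20),
    extent: tuple[int, int] = (24, 24),
    high: float = 1.0,
    low: float = 0.0,
) -> SliceImage:
    """Bright axis-aligned rectangle on dark ground; its four corners are at
    analytically known positions (``corner_pos`` is the top-left)."""
    r0, c0 = corner_pos
    h, w = extent
    if r0 < 0 or c0 < 0 or r0 + h > size or c0 + w > size:
        raise ValueError("rectangle does not fit inside the image")
    img = np.full((size, size), low)
    img[r0 : r0 + h, c0 : c0 + w] = high
    return SliceImage(img, provenance="fixture:corner")


def gradient_fixture(theta: float, magnitude: float = 1.0, size: int = 16) -> SliceImage:
    """Planar ramp whose central-difference gradient is exactly
    (magnitude·cosθ, magnitude·sinθ) in the (gx, gy up) convention."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ramp = 0.5 * magnitude * (xx * np.cos(theta) - yy * np.sin(theta))
    return SliceImage(ramp, provenance="fixture:ramp")


def impulse_fixture(size: int = 11) -> SliceImage:
    """Single unit pixel at the centre of a zero image."""
    if size % 2 == 0:
        raise ValueError("impulse fixture size must be odd")
    img = np.zeros((size, size))
    img[size // 2, size // 2] = 1.0
    return SliceImage(img, provenance="fixture:impulse")
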