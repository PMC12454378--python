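"""Oriented-gradient patch descriptors and binarized orientation-shift codes.

Each 16×16 patch around a Harris interest point is described by a
128-dimensional vector: the patch is tiled into a 4×4 grid of 4×4-pixel
cells, each cell accumulates gradient magnitude into 8 orientation bins over
[0, 2π) with circular soft (two-bin) vote interpolation, and the 16
histograms are concatenated row-major (bins innermost).  Histograms are then
normalised in 2×2-cell blocks (L2 with an ε guard, clipped at 0.2,
renormalised) for illumination robustness.

A complementary binary channel compares pairs of cell histograms under all
8 cyclic orientation shifts ε: bit(k, ε) = 1 iff v_c1(k) ≥ v_c2((k+ε) mod 8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .harris import GradientField, Patch, image_gradients

N_BINS = 8
CELL_SIZE = 4
GRID = 4  # cells per side
DESCRIPTOR_LEN = GRID * GRID * N_BINS  # 128
BLOCK_CELLS = 2  # block side, in cells
_TWO_PI = 2.0 * np.pi

__all__ = [
    "N_BINS",
    "CELL_SIZE",
    "GRID",
    "DESCRIPTOR_LEN",
    "GradientPolarField",
    "CellHistogram",
    "PatchDescriptor",
    "ShiftBinaryCode",
    "ImageFeatureVector",
    "polar_gradients",
    "cell_histogram",
    "patch_cell_histograms",
    "assemble_descriptor",
    "shift_histogram",
    "binarize_pair",
    "default_cell_pairing",
    "patch_shift_code",
    "aggregate_image_features",
]


@dataclass
class GradientPolarField:
    """Gradient magnitude μ = √(gx²+gy²) and full-circle angle θ ∈ [0, 2π)."""

    magnitude: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.angle.shape:
            raise ValueError("magnitude/angle shapes differ")


@dataclass
class CellHistogram:
    """8 orientation-vote accumulators for one 4×4-pixel cell."""

    bins: np.ndarray
    cell_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"cell histogram must have {N_BINS} bins")


@dataclass
class PatchDescriptor:
    """128 ordered values (4×4 cells row-major, 8 bins innermost)."""

    vector: np.ndarray
    normalized: bool = True
    shift_code: "ShiftBinaryCode | None" = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.shape != (DESCRIPTOR_LEN,):
            raise ValueError(f"descriptor must have {DESCRIPTOR_LEN} entries")


@dataclass
class ShiftBinaryCode:
    """Per cell pair, an 8(k)×8(ε) binary comparison matrix."""

    pairs: list[tuple[int, int]]
    bits: np.ndarray = field(repr=False)  # (n_pairs, 8, 8) in {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.pairs), N_BINS, N_BINS):
            raise ValueError("bits shape must be (n_pairs, 8, 8)")


@dataclass
class ImageFeatureVector:
    """Fixed-length per-image aggregation of its patch descriptors."""

    values: np.ndarray
    n_patches: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def polar_gradients(patch: Patch | np.ndarray, signed: bool = True) -> GradientPolarField:
    """Central-difference gradients of the patch in polar form.

    θ is the quadrant-aware angle of (gx, gy) mapped to [0, 2π); with
    ``signed=False`` orientations are folded to [0, π) (unsigned mode, bins
    then span π/8 each).
    """
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch, float)
    g = image_gradients(pixels)
    mu = np.hypot(g.gx, g.gy)
    theta = np.arctan2(g.gy, g.gx) % _TWO_PI
    if not signed:
        theta = theta % np.pi
    return GradientPolarField(magnitude=mu, angle=theta)


def _soft_bin(theta: np.ndarray, signed: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circular two-bin interpolation.

    Fractional bin position p = θ/width − 0.5 (bin centres at (k+0.5)·width);
    the vote splits (1−frac, frac) between floor(p) mod 8 and floor(p)+1 mod 8.
    """
    width = (_TWO_PI if signed else np.pi) / N_BINS
    p = theta / width - 0.5
    b0 = np.floor(p).astype(np.int64)
    frac = p - b0
    return b0 % N_BINS, (b0 + 1) % N_BINS, frac


def cell_histogram(
    field_: GradientPolarField,
    cell_origin: tuple[int, int] = (0, 0),
    cell_size: int = CELL_SIZE,
    signed: bool = True,
) -> CellHistogram:
    """Soft-binned orientation histogram of one cell.

    Each pixel's magnitude is split linearly between the two orientation bins
    nearest its angle (circular wrap), so the total vote mass equals the
    cell's Σμ exactly.
    """
    r0, c0 = cell_origin
    H, W = field_.magnitude.shape
    if r0 < 0 or c0 < 0 or r0 + cell_size > H or c0 + cell_size > W:
        raise ValueError(f"cell at {cell_origin} not inside field {H}x{W}")
    mu = field_.magnitude[r0 : r0 + cell_size, c0 : c0 + cell_size].ravel()
    th = field_.angle[r0 : r0 + cell_size, c0 : c0 + cell_size].ravel()
    lo, hi, frac = _soft_bin(th, signed)
    bins = np.zeros(N_BINS)
    np.add.at(bins, lo, mu * (1.0 - frac))
    np.add.at(bins, hi, mu * frac)
    return CellHistogram(bins=bins, cell_origin=cell_origin)


def patch_cell_histograms(
    patch: Patch | np.ndarray, signed: bool = True
) -> list[CellHistogram]:
    """All 16 cell histograms of a 16×16 patch, row-major, in one vectorised
    pass (equivalent to 16 calls to :func:`cell_histogram`)."""
    field_ = polar_gradients(patch, signed=signed)
    mu, th = field_.magnitude, field_.angle
    lo, hi, frac = _soft_bin(th, signed)
    # cell index of every pixel in the 4x4 grid
    rows = np.arange(mu.shape[0])[:, None] // CELL_SIZE
    cols = np.arange(mu.shape[1])[None, :] // CELL_SIZE
    cell = (rows * GRID + cols).ravel()
    flat = np.zeros(GRID * GRID * N_BINS)
    np.add.at(flat, cell * N_BINS + lo.ravel(), (mu * (1.0 - frac)).ravel())
    np.add.at(flat, cell * N_BINS + hi.ravel(), (mu * frac).ravel())
    hists = flat.reshape(GRID * GRID, N_BINS)
    return [
        CellHistogram(bins=hists[i], cell_origin=((i // GRID) * CELL_SIZE, (i % GRID) * CELL_SIZE))
        for i in range(GRID * GRID)
    ]


def block_normalize(
    raw: np.ndarray, clip: float | None = 0.2, eps: float = 1e-6
) -> np.ndarray:
    """Normalise the 128-vector in 2×2-cell blocks.

    The 4×4 cell grid is tiled by four non-overlapping 2×2 blocks; each
    block's 32 values are L2-normalised (with an ε guard against empty
    blocks), clipped at ``clip`` (pass None to disable) and renormalised.
    """
    cells = raw.reshape(GRID, GRID, N_BINS)
    out = np.empty_like(cells)
    for br in range(0, GRID, BLOCK_CELLS):
        for bc in range(0, GRID, BLOCK_CELLS):
            block = cells[br : br + BLOCK_CELLS, bc : bc + BLOCK_CELLS]
            v = block / np.sqrt(np.sum(block**2) + eps**2)
            if clip is not None:
                v = np.minimum(v, clip)
                v = v / np.sqrt(np.sum(v**2) + eps**2)
            out[br : br + BLOCK_CELLS, bc : bc + BLOCK_CELLS] = v
    return out.reshape(-1)


def assemble_descriptor(
    patch: Patch | np.ndarray,
    normalize: bool = True,
    clip: float | None = 0.2,
    signed: bool = True,
    with_shift_code: bool = False,
) -> PatchDescriptor:
    """Build the 128-dim descriptor of a 16×16 patch.

    16 cells of 4×4 px scanned row-major, 8 orientation bins each,
    concatenated, then block-normalised (see :func:`block_normalize`).
    ``clip=None`` disables the clipping stage (useful when exact linearity
    of the normalisation matters, e.g. equivariance analyses).
    """
    hists = patch_cell_histograms(patch, signed=signed)
    raw = np.concatenate([h.bins for h in hists])
    vec = block_normalize(raw, clip=clip) if normalize else raw
    code = patch_shift_code(hists) if with_shift_code else None
    return PatchDescriptor(vector=vec, normalized=normalize, shift_code=code)


def shift_histogram(hist: CellHistogram, epsilon: int) -> CellHistogram:
    """Cyclically shift bins: out(k) = in((k+ε) mod 8), ε ∈ 0..7."""
    if not 0 <= epsilon < N_BINS:
        raise ValueError(f"shift must be in 0..{N_BINS - 1}, got {epsilon}")
    return CellHistogram(bins=np.roll(hist.bins, -epsilon), cell_origin=hist.cell_origin)


def binarize_pair(c1: CellHistogram, c2: CellHistogram) -> np.ndarray:
    """8×8 binary matrix: bit(k, ε) = 1 iff v_c1(k) ≥ v_c2((k+ε) mod 8).

    Ties yield 1 (the comparison is ≥).
    """
    k = np.arange(N_BINS)[:, None]
    eps = np.arange(N_BINS)[None, :]
    return (c1.bins[:, None] >= c2.bins[(k + eps) % N_BINS]).astype(np.uint8)


def default_cell_pairing() -> list[tuple[int, int]]:
    """Right- and down-neighbour pairs on the 4×4 cell grid (24 pairs)."""
    pairs: list[tuple[int, int]] = []
    for r in range(GRID):
        for c in range(GRID):
            i = r * GRID + c
            if c + 1 < GRID:
                pairs.append((i, i + 1))
            if r + 1 < GRID:
                pairs.append((i, i + GRID))
    return pairs


def patch_shift_code(
    cells: list[CellHistogram], pairing: list[tuple[int, int]] | None = None
) -> ShiftBinaryCode:
    """Binarised orientation-shift code over a cell pairing (default: 4-grid
    right/down adjacency, 24 pairs → 24×64 bits)."""
    if pairing is None:
        pairing = default_cell_pairing()
    n = len(cells)
    for a, b in pairing:
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"pair ({a}, {b}) references a cell outside 0..{n - 1}")
    bits = np.stack([binarize_pair(cells[a], cells[b]) for a, b in pairing])
    return ShiftBinaryCode(pairs=list(pairing), bits=bits)


def aggregate_image_features(
    descs: list[PatchDescriptor],
    method: str = "mean_max",
    label: str | None = None,
    include_shift_counts: bool = False,
) -> ImageFeatureVector:
    """Pool a slice's patch descriptors into one fixed-length vector.

    ``mean_max`` (default) concatenates the element-wise mean and max over
    patches → 256 values, the classifier input width; ``mean`` keeps the
    128-dim mean only.  Pooling is symmetric, so patch order is irrelevant.
    With ``include_shift_counts`` the mean per-pair bit count of each patch's
    shift code (24 extra values) is appended.
    """
    if method not in ("mean_max", "mean"):
        raise ValueError(f"unknown pooling method {method!r}")
    base = DESCRIPTOR_LEN * (2 if method == "mean_max" else 1)
    extra = len(default_cell_pairing()) if include_shift_counts else 0
    if not descs:
        warnings.warn("no patch descriptors: emitting a zero feature vector")
        return ImageFeatureVector(values=np.zeros(base + extra), n_patches=0, label=label)
    mat = np.stack([d.vector for d in descs])
    if mat.shape[1] != DESCRIPTOR_LEN:
        raise ValueError("inconsistent descriptor lengths")
    # column-sort before reducing so pooling is bitwise permutation-invariant
    mat = np.sort(mat, axis=0)
    parts = [mat.mean(axis=0)]
    if method == "mean_max":
        parts.append(mat.max(axis=0))
    if include_shift_counts:
        codes = []
        for d in descs:
            if d.shift_code is None:
                raise ValueError("include_shift_counts requires descriptors with shift codes")
            codes.append(d.shift_code.bits.reshape(len(d.shift_code.pairs), -1).sum(axis=1))
        parts.append(np.stack(codes).mean(axis=0) / (N_BINS * N_BINS))
    return ImageFeatureVector(
        values=np.concatenate(parts), n_patches=len(descs), label=label
    )
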