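"""Slide preprocessing: foreground detection, patch enumeration, encoding.

Coordinate conventions: 0-based, top-left origin, half-open rectangles
``[x, x+size) x [y, y+size)`` at level 0. Patches are non-overlapping
grid tiles of 896 px at the base magnification; before encoding each
patch is resized to 224 x 224 (an effective 4x downscale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import median
from skimage.morphology import disk

PATCH_SIZE = 896
ENCODER_INPUT_SIZE = 224
BASE_MAGNIFICATION = "40x"


@dataclass
class TissueMask:
    """Binary foreground raster at a (possibly downsampled) resolution."""

    mask: np.ndarray  # 2-D bool
    downsample_factor: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


@dataclass
class PatchGrid:
    """Level-0 top-left coordinates of the accepted grid patches."""

    coords: np.ndarray  # (n, 2) int64 columns (x, y), row-major order
    patch_size: int = PATCH_SIZE
    slide_id: str = ""
    magnification: str = BASE_MAGNIFICATION

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.coords) and self.coords.min() < 0:
            raise ValueError("patch coordinates must be non-negative")

    def __len__(self) -> int:
        return len(self.coords)

    def cell_indices(self) -> np.ndarray:
        """(row, col) grid cell of each patch (coords // patch_size)."""
        return self.coords[:, ::-1] // self.patch_size


@runtime_checkable
class PatchEncoder(Protocol):
    """Contract: deterministic map from an RGB patch to a D-vector."""

    dim: int

    def encode(self, patch: np.ndarray) -> np.ndarray: ...


class ToyEncoder:
    """Fixed random projection of an 8x8x8 joint RGB color histogram.

    Deterministic, seeded, with configurable output dimension; a stand-in
    for pretrained histopathology encoders honoring the same contract.
    """

    def __init__(self, dim: int = 768, seed: int = 0, bins: int = 8):
        self.dim = dim
        self.bins = bins
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((bins**3, dim)) / np.sqrt(bins**3)

    def histogram(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch)
        idx = (patch.reshape(-1, 3).astype(np.int64) * self.bins) // 256
        flat = (idx[:, 0] * self.bins + idx[:, 1]) * self.bins + idx[:, 2]
        hist = np.bincount(flat, minlength=self.bins**3).astype(np.float64)
        return hist / hist.sum()

    def encode(self, patch: np.ndarray) -> np.ndarray:
        return self.histogram(patch) @ self._projection


@runtime_checkable
class SlideReader(Protocol):
    """Minimal level-0 region reader."""

    dimensions: tuple[int, int]  # (width, height)

    def read_region(self, x: int, y: int, size: int) -> np.ndarray: ...


class ArraySlideReader:
    """Reader over an in-memory RGB array (tests and plain TIFF/PNG)."""

    def __init__(self, image: np.ndarray, slide_id: str = ""):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an HxWx3 RGB array")
        self.image = image
        self.slide_id = slide_id
        self.dimensions = (image.shape[1], image.shape[0])

    def read_region(self, x: int, y: int, size: int) -> np.ndarray:
        h, w = self.image.shape[:2]
        if x < 0 or y < 0 or x + size > w or y + size > h:
            raise ValueError(f"region [{x},{x + size})x[{y},{y + size}) out of bounds")
        return self.image[y : y + size, x : x + size]

    def thumbnail(self, factor: int = 1) -> np.ndarray:
        return self.image[::factor, ::factor]


def open_slide(path: str | Path) -> ArraySlideReader:
    """Open a plain-raster slide (PNG/TIFF) as a level-0 reader."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return ArraySlideReader(arr, slide_id=Path(path).stem)


def detect_tissue(
    thumbnail: np.ndarray,
    sat_threshold: int = 8,
    median_radius: int = 2,
    downsample_factor: float = 1.0,
) -> TissueMask:
    """Foreground via thresholding the median-blurred HSV saturation.

    The mask is 1 where the blurred saturation (0-255 scale) exceeds
    ``sat_threshold``; white background has zero saturation.
    """
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail")
    sat = (rgb2hsv(thumbnail)[:, :, 1] * 255).astype(np.uint8)
    if median_radius > 0:
        sat = median(sat, footprint=disk(median_radius))
    return TissueMask(mask=sat > sat_threshold, downsample_factor=downsample_factor)


def enumerate_patches(
    mask: TissueMask,
    slide_dims: tuple[int, int],
    patch_size: int = PATCH_SIZE,
    min_tissue_frac: float = 0.5,
    slide_id: str = "",
) -> PatchGrid:
    """All non-overlapping grid patches with tissue coverage >= threshold.

    Coverage of a patch is the mean of the mask over its footprint in
    mask space (level-0 coordinates scaled by the downsample factor).
    Patches are emitted in row-major order (y outer, x inner). A slide
    smaller than one patch yields an empty grid.
    """
    width, height = slide_dims
    f = mask.downsample_factor
    m = mask.mask.astype(np.float64)
    coords = []
    for y in range(0, height - patch_size + 1, patch_size):
        r0, r1 = int(y // f), max(int(y // f) + 1, int(np.ceil((y + patch_size) / f)))
        for x in range(0, width - patch_size + 1, patch_size):
            c0 = int(x // f)
            c1 = max(c0 + 1, int(np.ceil((x + patch_size) / f)))
            footprint = m[r0:r1, c0:c1]
            if footprint.size and footprint.mean() >= min_tissue_frac:
                coords.append((x, y))
    return PatchGrid(
        coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
        patch_size=patch_size,
        slide_id=slide_id,
    )


def read_patch_resized(reader: SlideReader, x: int, y: int, patch_size: int) -> np.ndarray:
    region = reader.read_region(x, y, patch_size)
    if patch_size == ENCODER_INPUT_SIZE:
        return region
    im = Image.fromarray(np.ascontiguousarray(region))
    im = im.resize((ENCODER_INPUT_SIZE, ENCODER_INPUT_SIZE), Image.BILINEAR)
    return np.asarray(im)


def encode_patches(
    grid: PatchGrid, reader: SlideReader, encoder: PatchEncoder
) -> np.ndarray:
    """Encode every grid patch (resized to 224 x 224) in grid order."""
    rows = np.empty((len(grid), encoder.dim), dtype=np.float32)
    for i, (x, y) in enumerate(grid.coords):
        try:
            patch = read_patch_resized(reader, int(x), int(y), grid.patch_size)
        except Exception as exc:
            raise RuntimeError(f"failed to read patch {i} at ({x}, {y})") from exc
        rows[i] = encoder.encode(patch)
    return rows
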