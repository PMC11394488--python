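"""Tumor-bulk restriction: patch scoring, mask refinement, bag filtering.

A patch classifier assigns each foreground patch a tumor probability;
thresholded scores form a binary mask at patch-grid resolution, which is
refined by binary closing, small-object removal and per-component
convex-hull filling before restricting bags to tumor-bulk rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image
from shapely.geometry import MultiPoint, Point
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, remove_small_objects

from damil.bags import EmbeddingBag
from damil.preprocess import PatchGrid, SlideReader


class SlideExcludedError(RuntimeError):
    """Raised when a slide retains no tumor-bulk patches."""


@dataclass
class TumorMask:
    """Binary raster aligned to the patch grid (one cell per patch)."""

    cells: np.ndarray  # 2-D bool, indexed (row, col) = (y, x) // patch_size
    provenance: str = "raw"  # raw | refined

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.ndim != 2:
            raise ValueError("mask cells must be 2-D")
        if self.provenance not in ("raw", "refined"):
            raise ValueError("provenance must be 'raw' or 'refined'")


@runtime_checkable
class PatchClassifier(Protocol):
    """Contract: RGB patch -> tumor probability in [0, 1]."""

    def score(self, patch: np.ndarray) -> float: ...


class MeanColorLogisticClassifier:
    """Logistic model on mean-RGB features; a toy stand-in classifier.

    ``weights`` has length 3 (per channel, on 0-1 scaled means) and
    ``bias`` is scalar. ``fit`` estimates both from labeled patches via
    scikit-learn's logistic regression.
    """

    def __init__(self, weights=(0.0, 0.0, 0.0), bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = float(bias)

    @staticmethod
    def _features(patch: np.ndarray) -> np.ndarray:
        return np.asarray(patch).reshape(-1, 3).mean(axis=0) / 255.0

    def score(self, patch: np.ndarray) -> float:
        logit = self._features(patch) @ self.weights + self.bias
        return float(1.0 / (1.0 + np.exp(-logit)))

    def fit(self, patches: list[np.ndarray], labels: list[int]) -> "MeanColorLogisticClassifier":
        from sklearn.linear_model import LogisticRegression

        X = np.stack([self._features(p) for p in patches])
        model = LogisticRegression(C=100.0).fit(X, np.asarray(labels))
        self.weights = model.coef_.ravel()
        self.bias = float(model.intercept_[0])
        return self


def score_patches(
    grid: PatchGrid, reader: SlideReader, classifier: PatchClassifier
) -> np.ndarray:
    """One tumor probability per grid patch, order preserved."""
    scores = np.empty(len(grid), dtype=np.float64)
    for i, (x, y) in enumerate(grid.coords):
        s = float(classifier.score(reader.read_region(int(x), int(y), grid.patch_size)))
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"classifier returned out-of-range score {s} for patch {i}")
        scores[i] = s
    return scores


def patches_to_mask(
    scores: np.ndarray, grid: PatchGrid, threshold: float = 0.5
) -> TumorMask:
    """Rasterize per-patch scores to a raw binary mask (cell=1 iff score >= t)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(grid),):
        raise ValueError(
            f"scores length {scores.shape} does not match grid size {len(grid)}"
        )
    if len(grid) == 0:
        return TumorMask(cells=np.zeros((0, 0), dtype=bool), provenance="raw")
    rc = grid.cell_indices()
    shape = (rc[:, 0].max() + 1, rc[:, 1].max() + 1)
    cells = np.zeros(shape, dtype=bool)
    cells[rc[:, 0], rc[:, 1]] = scores >= threshold
    return TumorMask(cells=cells, provenance="raw")


def _hull_fill(component: np.ndarray) -> np.ndarray:
    """Fill a single connected component with its convex hull.

    Membership is exact: a cell belongs iff its integer coordinate lies
    in (or on) the convex hull of the component's cell set.
    """
    rows, cols = np.nonzero(component)
    hull = MultiPoint(list(zip(cols.tolist(), rows.tolist()))).convex_hull
    out = np.zeros_like(component)
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            if hull.covers(Point(c, r)):
                out[r, c] = True
    return out


def refine_mask(
    mask: TumorMask,
    closing_radius: int = 1,
    min_object_cells: int = 8,
    use_convex_hull: bool = True,
) -> TumorMask:
    """Morphological refinement: closing, small-object removal, hull fill.

    Applied in that order; the hull is per connected component
    (8-connectivity) so multifocal tumors are never merged across the
    slide. Idempotent for fixed parameters.
    """
    def one_pass(cells: np.ndarray) -> np.ndarray:
        if closing_radius > 0:
            cells = closing(cells, footprint=disk(closing_radius))
        # drop components with fewer than min_object_cells cells
        cells = remove_small_objects(
            cells.astype(bool), max_size=min_object_cells - 1, connectivity=2
        )
        if use_convex_hull and cells.any():
            labeled = cc_label(cells, connectivity=2)
            out = np.zeros_like(cells)
            for lab in range(1, labeled.max() + 1):
                out |= _hull_fill(labeled == lab)
            cells = out
        return cells

    cells = mask.cells.copy()
    if cells.any():
        # iterate to a fixpoint: closing can bridge components whose hulls
        # approach within the structuring element, changing the next pass
        for _ in range(16):
            new = one_pass(cells)
            if np.array_equal(new, cells):
                break
            cells = new
    return TumorMask(cells=cells, provenance="refined")


def apply_mask_to_bag(
    bag: EmbeddingBag, mask: TumorMask, grid: PatchGrid
) -> EmbeddingBag:
    """Restrict a bag to rows whose patch cell is tumor in the mask.

    Row order is preserved. A slide retaining no rows is excluded, in
    line with dropping slides that fail preprocessing.
    """
    if bag.n_instances != len(grid):
        raise ValueError("bag rows do not correspond to grid patches")
    rc = grid.cell_indices()
    keep = mask.cells[rc[:, 0], rc[:, 1]]
    if not keep.any():
        raise SlideExcludedError(
            f"slide {bag.slide_id or '<unnamed>'}: no tumor-bulk patches survive"
        )
    return bag.subset(np.nonzero(keep)[0])


def save_mask(mask: TumorMask, grid: PatchGrid, path: str | Path) -> None:
    """Write the mask as a 0/255 PNG plus a JSON geometry sidecar."""
    path = Path(path)
    Image.fromarray((mask.cells * 255).astype(np.uint8)).save(path)
    sidecar = {
        "patch_size": int(grid.patch_size),
        "slide_id": grid.slide_id,
        "provenance": mask.provenance,
        "shape": list(mask.cells.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
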