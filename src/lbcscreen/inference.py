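"""Sliding-window inference, probability heatmaps and slide-level scoring.

A trained tile classifier is applied to every tissue tile on a half-overlap
stride lattice (tile 1024, stride 512 at full scale), producing a grid of
neoplasia probabilities; grid cells without tissue are missing (NaN).  The
slide-level score is the maximum over present cells — a single confidently
neoplastic field is enough to flag the whole slide for review.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

from .errors import GeometryError
from .slide_io import (
    Slide,
    TissueMask,
    compute_tissue_mask,
    enumerate_tissue_tiles,
    lattice_shape,
    read_region,
)

logger = logging.getLogger(__name__)


class TileModel(Protocol):
    """Anything that maps a batch of tiles to probabilities."""

    def predict_proba(self, batch: np.ndarray) -> np.ndarray: ...


@dataclass
class HeatmapGrid:
    """Stride-indexed tile probabilities; NaN marks non-tissue cells.

    Cell ``(i, j)`` corresponds to the tile with origin
    ``(j * stride, i * stride)``.
    """

    slide_id: str
    stride: int
    tile_size: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        present = self.grid[~np.isnan(self.grid)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise GeometryError("heatmap probabilities outside [0, 1]")

    def value_at(self, x: int, y: int) -> float | None:
        """Probability of the tile with origin (x, y); None if off-grid."""
        if x % self.stride or y % self.stride:
            raise GeometryError(
                f"origin ({x}, {y}) not on stride-{self.stride} lattice")
        i, j = y // self.stride, x // self.stride
        if not (0 <= i < self.grid.shape[0] and 0 <= j < self.grid.shape[1]):
            return None
        return float(self.grid[i, j])

    @property
    def n_present(self) -> int:
        return int((~np.isnan(self.grid)).sum())


@dataclass(frozen=True)
class WSIPrediction:
    slide_id: str
    score: float
    n_tiles: int
    argmax_x: int
    argmax_y: int


def predict_heatmap(model: TileModel, slide: Slide,
                    mask: TissueMask | None = None, tile_size: int = 1024,
                    stride: int = 512, min_fg_frac: float = 0.05,
                    batch_size: int = 32,
                    mask_downsample: int = 32) -> HeatmapGrid:
    """Probability for every tissue tile on the stride lattice."""
    if mask is None:
        mask = compute_tissue_mask(slide, downsample=mask_downsample)
    tiles = enumerate_tissue_tiles(mask, tile_size, stride, min_fg_frac,
                                   slide_id=slide.id,
                                   slide_width=slide.width,
                                   slide_height=slide.height)
    rows, cols = lattice_shape(slide.width, slide.height, tile_size, stride)
    grid = np.full((rows, cols), np.nan)
    if not tiles:
        warnings.warn(f"slide {slide.id!r}: no tissue tiles; empty heatmap")
        return HeatmapGrid(slide.id, stride, tile_size, grid)
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start:start + batch_size]
        batch = np.stack([read_region(slide, t) for t in chunk])
        probs = model.predict_proba(batch)
        for t, p in zip(chunk, probs):
            grid[t.y // stride, t.x // stride] = float(p)
    return HeatmapGrid(slide.id, stride, tile_size, grid)


def wsi_score(grid: HeatmapGrid) -> WSIPrediction:
    """Max-aggregated slide score; argmax tie broken first in row-major.

    An empty grid (no tissue, e.g. a blank or unreadably faint slide) scores
    0.0 — screen-negative — with a logged warning.
    """
    present = ~np.isnan(grid.grid)
    n = int(present.sum())
    if n == 0:
        logger.warning("slide %s: empty heatmap, default score 0.0",
                       grid.slide_id)
        return WSIPrediction(grid.slide_id, 0.0, 0, 0, 0)
    flat = np.where(present, grid.grid, -np.inf).ravel()
    k = int(flat.argmax())  # first occurrence on ties (row-major)
    i, j = divmod(k, grid.grid.shape[1])
    return WSIPrediction(grid.slide_id, float(grid.grid[i, j]), n,
                         j * grid.stride, i * grid.stride)


def export_heatmap(grid: HeatmapGrid, path: str | Path, cell_px: int = 16,
                   cmap: str = "viridis") -> None:
    """Colormapped PNG of the lattice (missing cells transparent) + CSV.

    The sidecar ``<path>.csv`` stores exact (x, y, prob) rows so the
    rendered image is never the numerical record.
    """
    path = Path(path)
    cm = colormaps[cmap]
    rgba = (cm(np.nan_to_num(grid.grid, nan=0.0)) * 255).astype(np.uint8)
    rgba[..., 3] = np.where(np.isnan(grid.grid), 0, 255)
    up = np.kron(rgba, np.ones((cell_px, cell_px, 1), dtype=np.uint8))
    Image.fromarray(up, "RGBA").save(path)
    write_heatmap_csv(grid, path.with_suffix(path.suffix + ".csv"))


def write_heatmap_csv(grid: HeatmapGrid, path: str | Path) -> None:
    rows = []
    for i in range(grid.grid.shape[0]):
        for j in range(grid.grid.shape[1]):
            v = grid.grid[i, j]
            if not np.isnan(v):
                rows.append({"x": j * grid.stride, "y": i * grid.stride,
                             "prob": v})
    pd.DataFrame(rows, columns=["x", "y", "prob"]).to_csv(path, index=False)


def read_heatmap_csv(path: str | Path, slide_id: str, stride: int,
                     tile_size: int, rows: int, cols: int) -> HeatmapGrid:
    df = pd.read_csv(path)
    grid = np.full((rows, cols), np.nan)
    for r in df.itertuples():
        grid[int(r.y) // stride, int(r.x) // stride] = r.prob
    return HeatmapGrid(slide_id, stride, tile_size, grid)


def write_predictions(preds: list[WSIPrediction], path: str | Path) -> None:
    pd.DataFrame([{"slide_id": p.slide_id, "score": p.score,
                   "n_tiles": p.n_tiles, "argmax_x": p.argmax_x,
                   "argmax_y": p.argmax_y} for p in preds]
                 ).to_csv(path, index=False)
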