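"""Weakly-supervised tile sampling with epoch-end hard-negative mining.

Positive tiles come from the stride lattice of annotated neoplastic slides —
any lattice tile in which at least one annotated cell is visible is a
candidate.  Negative tiles come from the tissue lattice of NILM slides.
Batches are exactly class-balanced and strictly interleaved (P,N,P,N,...).

After each training epoch, sliding-window inference over the NILM slides
yields a predicted probability ``p`` for every negative tile; its sampling
weight becomes ``w = 1 + gamma * p``, so confidently false-positive tiles
are drawn up to ``1 + gamma`` times more often while no tile ever starves.
``gamma = 0`` recovers uniform negative sampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError
from .slide_io import (
    NEOPLASTIC,
    AnnotationRegion,
    Slide,
    Tile,
    polygon_intersects_tile,
)

if TYPE_CHECKING:  # pragma: no cover
    from .inference import HeatmapGrid

logger = logging.getLogger(__name__)

#: default hard-mining strength; a tile predicted at p=1 becomes 10x as
#: likely to be drawn as a tile at p=0.
DEFAULT_GAMMA = 9.0


@dataclass
class SamplerState:
    """Candidate pools plus per-negative-tile sampling weights."""

    positive_pool: list[Tile]
    negative_pool: list[Tile]
    negative_weights: np.ndarray
    tile_size: int
    stride: int
    epoch: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.negative_weights = np.asarray(self.negative_weights, float)
        if len(self.negative_weights) != len(self.negative_pool):
            raise ConfigError("weights misaligned with negative pool")
        if len(self.negative_weights) and (
                not np.all(np.isfinite(self.negative_weights))
                or np.any(self.negative_weights < 0)
                or not self.negative_weights.any()):
            raise ConfigError("weights must be finite, >= 0, not all zero")

    @classmethod
    def build(cls, positive_pool: Sequence[Tile],
              negative_pool: Sequence[Tile], tile_size: int, stride: int,
              rng_seed: int = 0) -> "SamplerState":
        return cls(list(positive_pool), list(negative_pool),
                   np.ones(len(negative_pool)), tile_size, stride,
                   rng_seed=rng_seed)


@dataclass(frozen=True)
class BatchSpec:
    """An ordered, exactly class-balanced, alternating list of tiles."""

    items: tuple[tuple[Tile, int], ...]

    def __post_init__(self) -> None:
        labels = [lab for _, lab in self.items]
        if labels.count(1) != labels.count(0):
            raise ConfigError("batch not class-balanced")
        if any(a == b for a, b in zip(labels, labels[1:])):
            raise ConfigError("batch labels not strictly alternating")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


def positive_candidate_tiles(slide: Slide,
                             regions: Sequence[AnnotationRegion],
                             tile_size: int,
                             stride: int | None = None) -> list[Tile]:
    """Lattice tiles in which at least one annotated cell is visible."""
    if slide.label != NEOPLASTIC or not regions:
        raise ConfigError(
            f"slide {slide.id!r}: positive tiles require a neoplastic slide "
            "with at least one annotation")
    stride = stride or tile_size // 2
    polys = [r.shapely() for r in regions]
    # bounding boxes prune the lattice scan
    bounds = [p.bounds for p in polys]
    tiles = []
    for y in range(0, slide.height - tile_size + 1, stride):
        for x in range(0, slide.width - tile_size + 1, stride):
            hit = False
            for (bx0, by0, bx1, by1), region in zip(bounds, regions):
                if (bx1 <= x or bx0 >= x + tile_size
                        or by1 <= y or by0 >= y + tile_size):
                    continue
                t = Tile(slide.id, x, y, tile_size)
                if polygon_intersects_tile(region, t):
                    hit = True
                    break
            if hit:
                tiles.append(Tile(slide.id, x, y, tile_size))
    if not tiles:
        warnings.warn(f"slide {slide.id!r}: no lattice tile intersects any "
                      "annotation")
    return tiles


def jitter_tile(tile: Tile, regions: Sequence[AnnotationRegion],
                slide_width: int, slide_height: int,
                rng: np.random.Generator,
                max_offset: int | None = None, tries: int = 8) -> Tile:
    """Random offset up to ±tile/4 that keeps an annotated cell visible.

    Approximates drawing positives "randomly from the annotated regions"
    rather than only at lattice positions; falls back to the original tile
    if no jittered placement keeps the intersection.
    """
    max_offset = max_offset if max_offset is not None else tile.size // 4
    for _ in range(tries):
        dx, dy = rng.integers(-max_offset, max_offset + 1, size=2)
        x = int(np.clip(tile.x + dx, 0, slide_width - tile.size))
        y = int(np.clip(tile.y + dy, 0, slide_height - tile.size))
        cand = Tile(tile.slide_id, x, y, tile.size)
        if any(polygon_intersects_tile(r, cand) for r in regions):
            return cand
    return tile


def sample_balanced_batch(state: SamplerState, batch_size: int,
                          rng: np.random.Generator,
                          regions_by_slide: Mapping[str, Sequence[AnnotationRegion]] | None = None,
                          slide_dims: Mapping[str, tuple[int, int]] | None = None,
                          jitter: bool = False) -> BatchSpec:
    """Draw an interleaved 50/50 batch (positives uniform, negatives ∝ w)."""
    if batch_size % 2:
        raise ConfigError("batch_size must be even")
    if not state.positive_pool or not state.negative_pool:
        raise ConfigError("sampler pools must be non-empty")
    half = batch_size // 2
    pos_idx = rng.integers(len(state.positive_pool), size=half)
    probs = state.negative_weights / state.negative_weights.sum()
    neg_idx = rng.choice(len(state.negative_pool), size=half, p=probs)
    items = []
    for pi, ni in zip(pos_idx, neg_idx):
        pos = state.positive_pool[pi]
        if jitter and regions_by_slide is not None and slide_dims is not None:
            w, h = slide_dims[pos.slide_id]
            pos = jitter_tile(pos, regions_by_slide[pos.slide_id], w, h, rng)
        items.append((pos, 1))
        items.append((state.negative_pool[ni], 0))
    return BatchSpec(tuple(items))


def update_hard_mining_weights(state: SamplerState,
                               nilm_heatmaps: Mapping[str, "HeatmapGrid"],
                               gamma: float = DEFAULT_GAMMA) -> SamplerState:
    """Re-weight negatives as ``w = 1 + gamma * p``; advance the epoch.

    ``p`` is the tile's predicted neoplasia probability from the epoch-end
    sliding-window pass over the NILM slides.  Tiles absent from the
    heatmaps keep their previous weight.  A tile whose origin does not sit
    on a heatmap's lattice raises :class:`GeometryError`.
    """
    new_weights = state.negative_weights.copy()
    for i, tile in enumerate(state.negative_pool):
        grid = nilm_heatmaps.get(tile.slide_id)
        if grid is None:
            continue
        if grid.stride != state.stride or grid.tile_size != state.tile_size:
            raise GeometryError(
                f"heatmap lattice ({grid.tile_size}/{grid.stride}) does not "
                f"match sampler lattice ({state.tile_size}/{state.stride})")
        p = grid.value_at(tile.x, tile.y)
        if p is None or np.isnan(p):
            continue
        new_weights[i] = 1.0 + gamma * p
    return replace(state, negative_weights=new_weights,
                   epoch=state.epoch + 1)


def save_sampler_checkpoint(state: SamplerState, path: str | Path) -> None:
    """Negative-pool weights as CSV (slide_id, x, y, weight)."""
    rows = [{"slide_id": t.slide_id, "x": t.x, "y": t.y, "weight": w}
            for t, w in zip(state.negative_pool, state.negative_weights)]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sampler_checkpoint(state: SamplerState,
                            path: str | Path) -> SamplerState:
    df = pd.read_csv(path)
    lookup = {(r.slide_id, r.x, r.y): r.weight for r in df.itertuples()}
    weights = np.array([lookup.get((t.slide_id, t.x, t.y), w)
                        for t, w in zip(state.negative_pool,
                                        state.negative_weights)])
    return replace(state, negative_weights=weights)
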