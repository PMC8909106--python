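"""Slide abstraction, tissue masking, tile geometry and annotation I/O.

A *slide* here is an RGB raster of a liquid-based cytology (LBC) preparation:
a pale, near-white background with scattered cell material.  Everything
downstream works on fixed-size square *tiles* cut from the slide on a regular
stride lattice, restricted to tissue as found by Otsu thresholding of the
greyscale image (tissue is darker than the white background).

Coordinates are 0-based level-0 pixels; tile squares are half-open
``[x, x+size) x [y, y+size)``.  Tiles that would extend past the slide edge
are skipped rather than padded.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, box
from skimage.filters import threshold_otsu

from .errors import (
    AnnotationParseError,
    BoundsError,
    ConfigError,
    InvalidAnnotationError,
)

logger = logging.getLogger(__name__)

#: Labels a slide can carry. ``None`` means unknown.
NILM = "NILM"
NEOPLASTIC = "neoplastic"

# ITU-R 601 luma weights, as used by skimage's rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class Slide:
    """An RGB slide image with geometry metadata.

    ``levels`` lists ``(downsample, width, height)`` pyramid levels with
    strictly increasing downsample factors starting at 1.  Plain PNG slides
    have a single level.  Pixel data is loaded lazily and cached.
    """

    id: str
    width: int
    height: int
    levels: list[tuple[int, int, int]] = field(default_factory=list)
    label: str | None = None
    magnification: float | None = None
    path: Path | None = None
    _image: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError(f"slide {self.id!r}: non-positive dimensions")
        if not self.levels:
            self.levels = [(1, self.width, self.height)]
        factors = [f for f, _, _ in self.levels]
        if factors[0] != 1 or any(a >= b for a, b in zip(factors, factors[1:])):
            raise ConfigError(
                f"slide {self.id!r}: level downsamples must strictly increase from 1"
            )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_array(cls, image: np.ndarray, slide_id: str = "array",
                   label: str | None = None) -> "Slide":
        image = _as_rgb_u8(image)
        h, w = image.shape[:2]
        return cls(id=slide_id, width=w, height=h, label=label, _image=image)

    @classmethod
    def open(cls, path: str | Path, slide_id: str | None = None,
             label: str | None = None) -> "Slide":
        """Open a PNG or (possibly tiled/pyramidal) TIFF slide.

        Only the base level is used for pixel access; pyramid levels are
        recorded as metadata.  SVS support can be added by registering the
        file with an external reader and using :meth:`from_array`.
        """
        path = Path(path)
        if not path.exists():
            raise IOError(f"slide file not found: {path}")
        sid = slide_id or path.stem
        suffix = path.suffix.lower()
        if suffix in {".tif", ".tiff", ".svs"}:
            try:
                with tifffile.TiffFile(path) as tf:
                    series = tf.series[0]
                    base = series.levels[0].shape if series.levels else series.shape
                    h, w = int(base[0]), int(base[1])
                    levels = []
                    for lv in series.levels or [series]:
                        lh, lw = int(lv.shape[0]), int(lv.shape[1])
                        levels.append((round(w / lw), lw, lh))
            except Exception as exc:  # pragma: no cover - corrupt files
                raise IOError(f"cannot read TIFF slide {path}: {exc}") from exc
            slide = cls(id=sid, width=w, height=h, levels=levels, label=label,
                        path=path)
        else:
            try:
                with Image.open(path) as im:
                    w, h = im.size
            except Exception as exc:
                raise IOError(f"cannot read slide {path}: {exc}") from exc
            slide = cls(id=sid, width=w, height=h, label=label, path=path)
        return slide

    # -- pixel access ------------------------------------------------------
    @property
    def image(self) -> np.ndarray:
        """Full-resolution HxWx3 uint8 raster (lazy-loaded, cached)."""
        if self._image is None:
            if self.path is None:
                raise IOError(f"slide {self.id!r} has no backing file")
            suffix = self.path.suffix.lower()
            if suffix in {".tif", ".tiff", ".svs"}:
                arr = tifffile.imread(self.path)
            else:
                with Image.open(self.path) as im:
                    arr = np.asarray(im.convert("RGB"))
            self._image = _as_rgb_u8(arr)
        return self._image


def _as_rgb_u8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[-1] == 4:
        image = image[..., :3]
    if image.ndim != 3 or image.shape[-1] != 3:
        raise IOError(f"expected an RGB raster, got shape {image.shape}")
    if image.dtype != np.uint8:
        image = np.clip(image, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(image)


@dataclass(frozen=True)
class Tile:
    """A square crop with level-0 top-left origin ``(x, y)``."""

    slide_id: str
    x: int
    y: int
    size: int = 1024

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.size <= 0:
            raise BoundsError(f"invalid tile geometry: {self}")

    def bounds(self) -> tuple[int, int, int, int]:
        """(xmin, ymin, xmax, ymax), half-open."""
        return self.x, self.y, self.x + self.size, self.y + self.size


@dataclass
class TissueMask:
    """Binary foreground raster at a fixed integer downsample of level 0."""

    mask: np.ndarray
    downsample: int
    otsu_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0 <= self.otsu_threshold <= 255:
            raise ConfigError("Otsu threshold outside [0, 255]")

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def tile_foreground_fraction(self, tile: Tile) -> float:
        """Foreground fraction of the mask window covering the tile."""
        d = self.downsample
        r0, r1 = tile.y // d, math.ceil((tile.y + tile.size) / d)
        c0, c1 = tile.x // d, math.ceil((tile.x + tile.size) / d)
        window = self.mask[r0:r1, c0:c1]
        return float(window.mean()) if window.size else 0.0


@dataclass
class AnnotationRegion:
    """Free-hand polygon around a neoplastic cell or cluster.

    Vertices are level-0 pixel coordinates; the polygon must enclose a
    positive area.
    """

    slide_id: str
    polygon: list[tuple[float, float]]
    label: str = NEOPLASTIC

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise InvalidAnnotationError(
                f"polygon for slide {self.slide_id!r} has "
                f"{len(self.polygon)} vertices; need at least 3"
            )
        if self.shapely().area <= 0:
            raise InvalidAnnotationError(
                f"degenerate polygon (zero area) for slide {self.slide_id!r}"
            )

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_region(slide: Slide, tile: Tile) -> np.ndarray:
    """Read the tile's pixels as a ``size x size x 3`` uint8 raster."""
    x0, y0, x1, y1 = tile.bounds()
    if x1 > slide.width or y1 > slide.height:
        raise BoundsError(
            f"tile {tile} exceeds slide {slide.id!r} "
            f"({slide.width}x{slide.height})"
        )
    return slide.image[y0:y1, x0:x1].copy()


def compute_tissue_mask(slide: Slide, downsample: int = 32) -> TissueMask:
    """Foreground mask by Otsu thresholding of the greyscale thumbnail.

    The RGB image is mean-pooled to the requested downsample (output dims
    ``ceil(dim / downsample)``), converted to luminance, and thresholded by
    Otsu's method; foreground is the *dark* side of the split (grey at or
    below the threshold) because LBC tissue is darker than the white slide
    background.  A zero-variance image yields an empty mask with a logged
    warning.
    """
    if downsample < 1:
        raise ConfigError("downsample must be >= 1")
    grey = _downsampled_grey(slide.image, downsample)
    grey_u8 = np.clip(np.round(grey), 0, 255).astype(np.uint8)
    if grey_u8.min() == grey_u8.max():
        logger.warning(
            "slide %s: uniform image, empty tissue mask", slide.id)
        return TissueMask(np.zeros(grey_u8.shape, bool), downsample,
                          float(grey_u8.min()))
    thr = float(threshold_otsu(grey_u8, nbins=256))
    # skimage's convention puts the bright class strictly above thr, so the
    # dark (tissue) class includes the threshold bin itself
    return TissueMask(grey_u8 <= thr, downsample, thr)


def _downsampled_grey(image: np.ndarray, d: int) -> np.ndarray:
    """Luminance image mean-pooled by factor ``d`` (edge blocks partial)."""
    grey = image.astype(np.float64) @ _LUMA
    if d == 1:
        return grey
    h, w = grey.shape
    ph, pw = math.ceil(h / d) * d, math.ceil(w / d) * d
    # pad with edge values so partial border blocks keep their local mean
    padded = np.pad(grey, ((0, ph - h), (0, pw - w)), mode="edge")
    return padded.reshape(ph // d, d, pw // d, d).mean(axis=(1, 3))


def enumerate_tissue_tiles(mask: TissueMask, tile_size: int, stride: int,
                           min_fg_frac: float = 0.05,
                           slide_id: str = "", slide_width: int | None = None,
                           slide_height: int | None = None) -> list[Tile]:
    """Tiles on the stride lattice whose foreground fraction clears the bar.

    Origins are ``(i*stride, j*stride)`` with the whole tile inside the
    slide; ordering is row-major (y outer, x inner).  Slide dimensions
    default to ``mask dims * downsample`` when not given.
    """
    if stride < 1 or tile_size < stride:
        raise ConfigError("require tile_size >= stride >= 1")
    d = mask.downsample
    sw = slide_width if slide_width is not None else mask.mask.shape[1] * d
    sh = slide_height if slide_height is not None else mask.mask.shape[0] * d
    if tile_size > sw or tile_size > sh:
        warnings.warn("tile_size exceeds slide dimensions; no tiles emitted")
        return []
    tiles = []
    for y in range(0, sh - tile_size + 1, stride):
        for x in range(0, sw - tile_size + 1, stride):
            t = Tile(slide_id, x, y, tile_size)
            if mask.tile_foreground_fraction(t) >= min_fg_frac:
                tiles.append(t)
    return tiles


def lattice_shape(width: int, height: int, tile_size: int,
                  stride: int) -> tuple[int, int]:
    """(rows, cols) of the full tile lattice for a W x H slide."""
    if tile_size > width or tile_size > height:
        return 0, 0
    return ((height - tile_size) // stride + 1,
            (width - tile_size) // stride + 1)


def polygon_intersects_tile(region: AnnotationRegion, tile: Tile) -> bool:
    """True iff the polygon overlaps the tile square with positive area."""
    poly = region.shapely()
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.area <= 0:
        raise InvalidAnnotationError(
            f"degenerate polygon for slide {region.slide_id!r}")
    x0, y0, x1, y1 = tile.bounds()
    return poly.intersection(box(x0, y0, x1, y1)).area > 0


# ---------------------------------------------------------------------------
# Annotation + manifest I/O
# ---------------------------------------------------------------------------

def save_annotations(regions: Sequence[AnnotationRegion],
                     path: str | Path) -> None:
    """Write regions as a GeoJSON FeatureCollection (level-0 pixel coords)."""
    features = []
    for r in regions:
        coords = [list(map(float, v)) for v in r.polygon]
        if coords[0] != coords[-1]:
            coords = coords + [coords[0]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [coords]},
            "properties": {"slide_id": r.slide_id, "label": r.label},
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_annotations(path: str | Path) -> list[AnnotationRegion]:
    """Load a GeoJSON FeatureCollection of polygon annotations."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(
            f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if payload.get("type") != "FeatureCollection":
        raise AnnotationParseError(f"{path}: not a GeoJSON FeatureCollection")
    regions = []
    for i, feat in enumerate(payload.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise AnnotationParseError(
                f"{path}: feature {i}: expected Polygon geometry")
        try:
            ring = geom["coordinates"][0]
        except (KeyError, IndexError) as exc:
            raise AnnotationParseError(
                f"{path}: feature {i}: missing coordinates") from exc
        verts = [tuple(map(float, v)) for v in ring]
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        props = feat.get("properties") or {}
        try:
            regions.append(AnnotationRegion(
                slide_id=str(props.get("slide_id", "")),
                polygon=verts,
                label=str(props.get("label", NEOPLASTIC)),
            ))
        except InvalidAnnotationError as exc:
            raise AnnotationParseError(f"{path}: feature {i}: {exc}") from exc
    return regions


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Slide manifest CSV with columns slide_id, path, label, split."""
    df = pd.read_csv(path, dtype=str)
    missing = {"slide_id", "path", "label"} - set(df.columns)
    if missing:
        raise IOError(f"manifest {path} missing columns: {sorted(missing)}")
    if "split" not in df.columns:
        df["split"] = "all"
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def open_manifest_slides(manifest: pd.DataFrame,
                         root: str | Path | None = None) -> dict[str, Slide]:
    """Open every slide in a manifest, resolving relative paths at ``root``."""
    root = Path(root) if root is not None else None
    slides = {}
    for row in manifest.itertuples():
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = root / p
        slides[row.slide_id] = Slide.open(p, slide_id=row.slide_id,
                                          label=row.label)
    return slides
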