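"""Synthetic liquid-based-cytology slide generator.

Emulates the visual cues a screening model must learn from LBC preparations:
a pale near-white background, scattered epithelial cells drawn as ellipse
pairs (large pale cytoplasm, smaller darker nucleus), and two ways a cell can
look suspicious:

* **neoplastic cells** — high nuclear/cytoplasmic (N/C) area ratio *and*
  hyperchromatic (dark) nuclei; each emits one polygon annotation around its
  cytoplasm ellipse, mimicking coarse free-hand annotation;
* **confuser clusters** — tight clusters of small benign cells with a high
  N/C ratio but only moderately dark nuclei, the synthetic analogue of the
  parabasal-cell clusters that cause false positives in real screening.
  Confusers are never annotated and occur on NILM slides too, so
  hard-negative mining has genuine work to do.

A slide's label is neoplastic iff at least one neoplastic cell was placed.
Generation is fully deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse

from .errors import ConfigError
from .slide_io import (
    NEOPLASTIC,
    NILM,
    AnnotationRegion,
    save_annotations,
    write_manifest,
)


@dataclass(frozen=True)
class SyntheticSlideConfig:
    """Study conditions for one synthetic slide.

    N/C intervals are area ratios; nucleus darkness intervals are grey
    intensities (lower = darker).  Defaults model clearly separable classes:
    normal squamous cells have small, moderately stained nuclei; neoplastic
    cells have enlarged, hyperchromatic nuclei.
    """

    width: int = 4096
    height: int = 4096
    n_cells: int = 7680
    neoplastic_fraction_of_cells: float = 0.05
    normal_nc_ratio: tuple[float, float] = (0.10, 0.30)
    neoplastic_nc_ratio: tuple[float, float] = (0.55, 0.90)
    normal_nucleus_grey: tuple[float, float] = (120.0, 170.0)
    neoplastic_nucleus_grey: tuple[float, float] = (40.0, 90.0)
    confuser_nucleus_grey: tuple[float, float] = (100.0, 140.0)
    confuser_cluster_rate: int = 2
    cell_radius: tuple[float, float] = (14.0, 24.0)
    background_grey: float = 245.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("slide dimensions must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        for iv in (self.normal_nc_ratio, self.neoplastic_nc_ratio):
            if not (0 < iv[0] <= iv[1] < 1):
                raise ConfigError(f"N/C interval {iv} outside (0, 1)")
        if not (0 <= self.neoplastic_fraction_of_cells <= 1):
            raise ConfigError("neoplastic_fraction_of_cells outside [0, 1]")
        if (np.mean(self.neoplastic_nc_ratio)
                <= np.mean(self.normal_nc_ratio)):
            raise ConfigError(
                "neoplastic N/C interval must exceed normal on average")

    @classmethod
    def desk_scale(cls, **overrides) -> "SyntheticSlideConfig":
        """Conditions scaled 8x down (512 px slides, proportional density).

        Pairs with 128 px tiles at stride 64, the reduced-scale analogue of
        1024 px tiles at stride 512 on full slides.  Cell size is physical
        and does not scale.
        """
        base = dict(width=512, height=512, n_cells=120)
        base.update(overrides)
        return cls(**base)


@dataclass
class CellRecord:
    """Generator metadata for one placed cell (used by tests/diagnostics)."""

    cx: float
    cy: float
    cell_area: float
    nucleus_area: float
    kind: str  # "normal" | "neoplastic" | "confuser"

    @property
    def nc_ratio(self) -> float:
        return self.nucleus_area / self.cell_area


@dataclass
class SyntheticSlide:
    image: np.ndarray
    regions: list[AnnotationRegion]
    label: str
    cells: list[CellRecord] = field(default_factory=list)

    def __iter__(self):  # (raster, regions, label) convenience unpacking
        return iter((self.image, self.regions, self.label))


# pale Pap-stain-ish cytoplasm tints, one picked per cell
_CYTO_TINTS = np.array([
    [205, 218, 228],   # pale cyanophilic
    [224, 205, 215],   # pale eosinophilic
    [214, 214, 222],
], dtype=float)


def _draw_cell(img: np.ndarray, rng: np.random.Generator, cx: float,
               cy: float, r_cell: float, nc_ratio: float,
               nucleus_grey: float) -> tuple[float, float]:
    """Draw one cytoplasm+nucleus ellipse pair; returns (cell, nucleus) areas."""
    h, w = img.shape[:2]
    aspect = rng.uniform(0.7, 1.0)
    theta = rng.uniform(0, math.pi)
    ra, rb = r_cell, r_cell * aspect
    tint = _CYTO_TINTS[rng.integers(len(_CYTO_TINTS))]
    tint = np.clip(tint + rng.normal(0, 4, 3), 0, 255)
    rr, cc = ellipse(cy, cx, rb, ra, shape=(h, w), rotation=theta)
    img[rr, cc] = (0.65 * img[rr, cc] + 0.35 * tint).astype(np.uint8)
    # nucleus area = nc_ratio * cell area, same aspect/orientation
    scale = math.sqrt(nc_ratio)
    nrr, ncc = ellipse(cy, cx, rb * scale, ra * scale, shape=(h, w),
                       rotation=theta)
    ngrey = np.clip(nucleus_grey + rng.normal(0, 5), 5, 250)
    ncol = np.array([ngrey * 0.85, ngrey * 0.75, ngrey])  # violet cast
    img[nrr, ncc] = (0.15 * img[nrr, ncc] + 0.85 * ncol).astype(np.uint8)
    return math.pi * ra * rb, math.pi * (ra * scale) * (rb * scale)


def _ellipse_polygon(cx: float, cy: float, ra: float, rb: float,
                     n_vertices: int = 12) -> list[tuple[float, float]]:
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    return [(cx + ra * math.cos(a), cy + rb * math.sin(a)) for a in ang]


def generate_slide(config: SyntheticSlideConfig,
                   slide_id: str = "synthetic") -> SyntheticSlide:
    """Render one synthetic slide with its annotations and label."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    img = np.full((h, w, 3), config.background_grey, dtype=float)
    img += rng.normal(0, 2.0, size=(h, w, 3))
    img = np.clip(img, 0, 255).astype(np.uint8)

    n_neo = int(round(config.n_cells * config.neoplastic_fraction_of_cells))
    kinds = ["neoplastic"] * n_neo + ["normal"] * (config.n_cells - n_neo)
    rng.shuffle(kinds)

    margin = config.cell_radius[1] + 2
    cells: list[CellRecord] = []
    regions: list[AnnotationRegion] = []

    for kind in kinds:
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        r_cell = rng.uniform(*config.cell_radius)
        if kind == "neoplastic":
            nc = rng.uniform(*config.neoplastic_nc_ratio)
            grey = rng.uniform(*config.neoplastic_nucleus_grey)
        else:
            nc = rng.uniform(*config.normal_nc_ratio)
            grey = rng.uniform(*config.normal_nucleus_grey)
        ca, na = _draw_cell(img, rng, cx, cy, r_cell, nc, grey)
        cells.append(CellRecord(cx, cy, ca, na, kind))
        if kind == "neoplastic":
            # coarse annotation: cytoplasm ellipse outline, slightly dilated
            poly = _ellipse_polygon(cx, cy, r_cell * 1.15, r_cell * 1.15)
            poly = [(min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0))
                    for x, y in poly]
            regions.append(AnnotationRegion(slide_id, poly, NEOPLASTIC))

    # benign confuser clusters: small, crowded, high-N/C cells
    for _ in range(config.confuser_cluster_rate):
        ccx = rng.uniform(margin, w - margin)
        ccy = rng.uniform(margin, h - margin)
        for _ in range(rng.integers(5, 10)):
            dx, dy = rng.normal(0, 12, 2)
            cx = min(max(ccx + dx, margin), w - margin)
            cy = min(max(ccy + dy, margin), h - margin)
            r_cell = rng.uniform(7.0, 11.0)
            nc = rng.uniform(*config.neoplastic_nc_ratio)
            grey = rng.uniform(*config.confuser_nucleus_grey)
            ca, na = _draw_cell(img, rng, cx, cy, r_cell, nc, grey)
            cells.append(CellRecord(cx, cy, ca, na, "confuser"))

    label = NEOPLASTIC if regions else NILM
    return SyntheticSlide(image=img, regions=regions, label=label,
                          cells=cells)


def generate_cohort(out_dir: str | Path, n_slides: int,
                    neoplastic_slide_fraction: float,
                    config: SyntheticSlideConfig | None = None,
                    seed: int = 0, split: str = "all") -> pd.DataFrame:
    """Write a labelled cohort of synthetic slides to ``out_dir``.

    Exactly ``round(n * fraction)`` slides are neoplastic (the rest NILM
    with ``neoplastic_fraction_of_cells`` forced to 0, confusers kept).
    Writes PNG slides, per-slide GeoJSON annotations for neoplastic slides,
    and ``manifest.csv``; per-slide seeds derive from the master seed, so
    the cohort is reproducible.
    """
    if not 0 <= neoplastic_slide_fraction <= 1:
        raise ConfigError("neoplastic_slide_fraction outside [0, 1]")
    config = config or SyntheticSlideConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_neo = int(round(n_slides * neoplastic_slide_fraction))
    labels = [NEOPLASTIC] * n_neo + [NILM] * (n_slides - n_neo)
    # interleave labels deterministically so splits stay balanced
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_slides)
    labels = [labels[i] for i in order]

    if n_neo and int(round(config.n_cells
                           * config.neoplastic_fraction_of_cells)) < 1:
        raise ConfigError(
            "config places no neoplastic cells but neoplastic slides were "
            "requested; raise n_cells or neoplastic_fraction_of_cells")

    seeds = np.random.SeedSequence(seed).generate_state(n_slides) % (2**31)
    rows = []
    for i, label in enumerate(labels):
        sid = f"synth_{split}_{i:04d}"
        cfg = replace(config, seed=int(seeds[i]),
                      neoplastic_fraction_of_cells=(
                          config.neoplastic_fraction_of_cells
                          if label == NEOPLASTIC else 0.0))
        slide = generate_slide(cfg, slide_id=sid)
        png = out / f"{sid}.png"
        Image.fromarray(slide.image).save(png)
        ann_path = ""
        if slide.regions:
            ann_path = f"{sid}.geojson"
            save_annotations(slide.regions, out / ann_path)
        assert slide.label == label
        rows.append({"slide_id": sid, "path": png.name, "label": label,
                     "split": split, "annotations": ann_path})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
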