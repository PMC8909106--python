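"""End-to-end glue: cohort loading, sampler construction, training runs and
cohort scoring.  The CLI and the examples are thin wrappers over this."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ConfigError
from .inference import WSIPrediction, predict_heatmap, wsi_score
from .model import (
    ModelConfig,
    TileClassifier,
    TrainConfig,
    TrainResult,
    build_model,
    train_model,
)
from .sampling import SamplerState, positive_candidate_tiles
from .slide_io import (
    NEOPLASTIC,
    NILM,
    AnnotationRegion,
    Slide,
    Tile,
    compute_tissue_mask,
    enumerate_tissue_tiles,
    load_annotations,
    read_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    manifest: pd.DataFrame
    slides: dict[str, Slide]
    regions: dict[str, list[AnnotationRegion]]

    def split(self, name: str) -> "Cohort":
        sub = self.manifest[self.manifest["split"] == name]
        if sub.empty:
            raise ConfigError(f"no slides in split {name!r}")
        ids = set(sub["slide_id"])
        return Cohort(sub.reset_index(drop=True),
                      {k: v for k, v in self.slides.items() if k in ids},
                      {k: v for k, v in self.regions.items() if k in ids})

    def labels(self) -> dict[str, int]:
        return {r.slide_id: int(r.label == NEOPLASTIC)
                for r in self.manifest.itertuples()}


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a manifest.csv cohort with slides and GeoJSON annotations."""
    root = Path(cohort_dir)
    manifest = read_manifest(root / "manifest.csv")
    slides, regions = {}, {}
    for row in manifest.itertuples():
        p = root / row.path
        slides[row.slide_id] = Slide.open(p, slide_id=row.slide_id,
                                          label=row.label)
        ann = getattr(row, "annotations", "")
        if isinstance(ann, str) and ann:
            regions[row.slide_id] = load_annotations(root / ann)
        else:
            regions[row.slide_id] = []
    return Cohort(manifest, slides, regions)


def build_sampler(cohort: Cohort, tile_size: int, stride: int,
                  min_fg_frac: float = 0.05, mask_downsample: int = 8,
                  rng_seed: int = 0) -> SamplerState:
    """Positive pool from annotated slides, negative pool from NILM tissue."""
    positives: list[Tile] = []
    negatives: list[Tile] = []
    for sid, slide in cohort.slides.items():
        if slide.label == NEOPLASTIC and cohort.regions.get(sid):
            positives += positive_candidate_tiles(
                slide, cohort.regions[sid], tile_size, stride)
        elif slide.label == NILM:
            mask = compute_tissue_mask(slide, downsample=mask_downsample)
            negatives += enumerate_tissue_tiles(
                mask, tile_size, stride, min_fg_frac, slide_id=sid,
                slide_width=slide.width, slide_height=slide.height)
    if not positives or not negatives:
        raise ConfigError("cohort yields an empty sampler pool "
                          f"({len(positives)} pos / {len(negatives)} neg)")
    return SamplerState.build(positives, negatives, tile_size, stride,
                              rng_seed=rng_seed)


def validation_tiles(cohort: Cohort, tile_size: int, stride: int,
                     n_per_class: int = 32, seed: int = 0,
                     min_fg_frac: float = 0.05,
                     mask_downsample: int = 8) -> list[tuple[Tile, int]]:
    """A fixed balanced tile set drawn once from validation slides."""
    state = build_sampler(cohort, tile_size, stride, min_fg_frac,
                          mask_downsample)
    rng = np.random.default_rng(seed)
    pos = [state.positive_pool[i] for i in
           rng.choice(len(state.positive_pool),
                      size=min(n_per_class, len(state.positive_pool)),
                      replace=False)]
    neg = [state.negative_pool[i] for i in
           rng.choice(len(state.negative_pool),
                      size=min(n_per_class, len(state.negative_pool)),
                      replace=False)]
    k = min(len(pos), len(neg))
    return [(t, 1) for t in pos[:k]] + [(t, 0) for t in neg[:k]]


def run_training(train_cohort: Cohort, val_cohort: Cohort,
                 model_config: ModelConfig, train_config: TrainConfig,
                 tile_size: int, stride: int,
                 mask_downsample: int = 8) -> TrainResult:
    """Build sampler + model and run the training loop."""
    state = build_sampler(train_cohort, tile_size, stride,
                          mask_downsample=mask_downsample,
                          rng_seed=train_config.seed)
    val = validation_tiles(val_cohort, tile_size, stride,
                           seed=train_config.seed,
                           mask_downsample=mask_downsample)
    model = build_model(model_config, seed=train_config.seed)
    slides = dict(train_cohort.slides)
    slides.update(val_cohort.slides)
    return train_model(model, state, slides, val, train_config,
                       regions_by_slide=train_cohort.regions)


def score_cohort(model: TileClassifier, cohort: Cohort, tile_size: int,
                 stride: int, min_fg_frac: float = 0.05,
                 mask_downsample: int = 8
                 ) -> tuple[list[WSIPrediction], np.ndarray]:
    """Sliding-window score for every slide; returns predictions + labels."""
    preds, labels = [], []
    lab = cohort.labels()
    for sid, slide in cohort.slides.items():
        grid = predict_heatmap(model, slide, tile_size=tile_size,
                               stride=stride, min_fg_frac=min_fg_frac,
                               mask_downsample=mask_downsample)
        preds.append(wsi_score(grid))
        labels.append(lab[sid])
    return preds, np.array(labels)
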