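"""The tile classifier (CNN -> max-pool -> GRU -> logistic head) and its
weakly-supervised training loop.

The backbone turns a square RGB tile into a ``g x g x c`` feature map
(``g = input_size / downsample``).  A 7x7 max pool with stride 5 condenses
it to ``g' = floor((g - 7) / 5) + 1`` per side; the pooled map is read out
row-major (top-left to bottom-right) as a sequence of ``g'^2`` feature
vectors into a GRU of hidden size 128, whose final state feeds a single
logistic unit: the probability that the tile contains neoplastic cells.

The production-scale reference architecture is an ImageNet-pretrained
EfficientNetB0 at input 1024 (grid 32 -> pooled 6x6 -> sequence 36).  This
package ships its own numpy backbones with the same interface and geometry:
``tiny-cnn`` (downsample 8) for reduced-scale work and ``cnn32``
(downsample 32) matching the reference feature-grid geometry.  The
identifier ``efficientnet-b0`` is accepted for geometry computations only.

Under *partial fine-tuning* only the batch-norm affine parameters of the
backbone train, together with the whole GRU and head; convolution kernels
stay frozen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import nn
from .errors import ConfigError
from .inference import predict_heatmap
from .sampling import (
    DEFAULT_GAMMA,
    SamplerState,
    sample_balanced_batch,
    update_hard_mining_weights,
)
from .slide_io import NILM, AnnotationRegion, Slide, Tile, read_region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackboneSpec:
    downsample: int
    widths: tuple[int, ...]
    buildable: bool = True


BACKBONES: dict[str, BackboneSpec] = {
    # 3 stride-2 blocks: input 128 -> grid 16
    "tiny-cnn": BackboneSpec(8, (8, 16, 32)),
    # 5 stride-2 blocks: input 1024 -> grid 32, reference geometry
    "cnn32": BackboneSpec(32, (8, 16, 32, 64, 64)),
    # production reference architecture; geometry only, not bundled
    "efficientnet-b0": BackboneSpec(32, (), buildable=False),
}


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny-cnn"
    input_size: int = 128
    pool_kernel: int = 7
    pool_stride: int = 5
    rnn_hidden: int = 128
    scan_order: str = "row-major"

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigError(f"unknown backbone {self.backbone!r}; "
                              f"known: {sorted(BACKBONES)}")
        if self.rnn_hidden <= 0:
            raise ConfigError("rnn_hidden must be positive")
        if self.scan_order != "row-major":
            raise ConfigError("only row-major scan order is implemented")
        spec = BACKBONES[self.backbone]
        if self.input_size % spec.downsample:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by backbone "
                f"downsample {spec.downsample}")
        if self.feature_grid < self.pool_kernel:
            raise ConfigError(
                f"backbone feature grid {self.feature_grid} smaller than "
                f"pool kernel {self.pool_kernel}")

    @property
    def feature_grid(self) -> int:
        return self.input_size // BACKBONES[self.backbone].downsample

    @property
    def pooled_grid(self) -> int:
        return pooled_grid(self.feature_grid, self.pool_kernel,
                           self.pool_stride)

    @property
    def sequence_length(self) -> int:
        return self.pooled_grid ** 2


def pooled_grid(g: int, kernel: int = 7, stride: int = 5) -> int:
    """Pooled side length: floor((g - kernel) / stride) + 1."""
    if g < kernel:
        raise ConfigError(f"grid {g} smaller than pool kernel {kernel}")
    return (g - kernel) // stride + 1


@dataclass(frozen=True)
class AugmentRanges:
    """Photometric jitter ranges; collapse to identity at (0, [1,1], [1,1])."""

    brightness: float = 0.2                      # additive, fraction of 255
    saturation: tuple[float, float] = (0.8, 1.2)  # multiplicative
    contrast: tuple[float, float] = (0.8, 1.2)    # multiplicative


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay: float = 0.95
    decay_every: int = 2          # epochs between decay applications
    patience: int = 10            # early-stop patience on validation loss
    batch_size: int = 8
    max_epochs: int = 50
    steps_per_epoch: int = 32
    seed: int = 0
    partial_finetune: bool = True
    augment: bool = True
    augment_ranges: AugmentRanges = field(default_factory=AugmentRanges)
    hard_mining: bool = True
    gamma: float = DEFAULT_GAMMA
    mining_min_fg_frac: float = 0.05
    mask_downsample: int = 32

    def __post_init__(self) -> None:
        if self.lr <= 0 or not (0 < self.lr_decay <= 1) or self.patience < 1:
            raise ConfigError("require lr > 0, 0 < lr_decay <= 1, "
                              "patience >= 1")
        if self.batch_size % 2:
            raise ConfigError("batch_size must be even (balanced batches)")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.lr * self.lr_decay ** (epoch // self.decay_every)


class TileClassifier:
    """CNN backbone -> 7/5 max pool -> row-major GRU -> logistic head."""

    def __init__(self, config: ModelConfig,
                 rng: np.random.Generator) -> None:
        spec = BACKBONES[config.backbone]
        if not spec.buildable:
            raise ConfigError(
                f"backbone {config.backbone!r} is the production reference "
                "architecture and is not bundled; use 'cnn32' for the same "
                "feature-grid geometry")
        self.config = config
        layers: list[nn.Layer] = []
        cin = 3
        for i, cout in enumerate(spec.widths):
            layers += [
                nn.Conv2d(cin, cout, kernel=3, stride=2, pad=1, rng=rng,
                          name=f"backbone.{i}.conv"),
                nn.BatchNorm2d(cout, name=f"backbone.{i}.bn"),
                nn.ReLU(),
            ]
            cin = cout
        self.backbone = nn.Sequential(*layers)
        self.pool = nn.MaxPool2d(config.pool_kernel, config.pool_stride)
        self.gru = nn.GRU(cin, config.rnn_hidden, rng=rng)
        self.head = nn.Linear(config.rnn_hidden, 1, rng=rng, tag="head")
        self.feature_channels = cin
        self._pool_shape: tuple | None = None

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        return (self.backbone.parameters() + self.gru.parameters()
                + self.head.parameters())

    def backbone_parameters(self) -> list[nn.Parameter]:
        return self.backbone.parameters()

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (N, H, W, 3) uint8 or (N, 3, H, W) float batch."""
        x = self._to_input(x)
        feat = self.backbone.forward(x, train=train)
        pooled = self.pool.forward(feat, train=train)
        n, c, gp, _ = pooled.shape
        # row-major scan: (i, j) cells left->right, top->bottom
        seq = np.ascontiguousarray(
            pooled.transpose(0, 2, 3, 1)).reshape(n, gp * gp, c)
        self._pool_shape = (n, c, gp)
        h = self.gru.forward(seq, train=train)
        return self.head.forward(h, train=train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits[:, None])
        dseq = self.gru.backward(dh)
        n, c, gp = self._pool_shape
        dpooled = np.ascontiguousarray(
            dseq.reshape(n, gp, gp, c).transpose(0, 3, 1, 2))
        dfeat = self.pool.backward(dpooled)
        self.backbone.backward(dfeat)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Probabilities in (0, 1) for a batch of tiles (eval mode)."""
        return nn.sigmoid(self.forward_logits(batch, train=False))

    @staticmethod
    def _to_input(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 4:
            raise ConfigError("expected a 4-D batch")
        if x.shape[-1] == 3 and x.shape[1] != 3:
            x = x.transpose(0, 3, 1, 2)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        return np.ascontiguousarray(x, dtype=np.float32)

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for layer in self.backbone.layers:
            if isinstance(layer, nn.BatchNorm2d):
                state[f"{layer.gamma.name}.running_mean"] = \
                    layer.running_mean.copy()
                state[f"{layer.gamma.name}.running_var"] = \
                    layer.running_var.copy()
        return state

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.array(state[p.name], dtype=np.float32)
        for layer in self.backbone.layers:
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = np.array(
                    state[f"{layer.gamma.name}.running_mean"],
                    dtype=np.float32)
                layer.running_var = np.array(
                    state[f"{layer.gamma.name}.running_var"],
                    dtype=np.float32)


def build_model(config: ModelConfig, seed: int = 0) -> TileClassifier:
    """Instantiate a tile classifier with seeded initial weights."""
    return TileClassifier(config, np.random.default_rng(seed))


def trainable_parameters(model: TileClassifier,
                         partial_finetune: bool) -> list[nn.Parameter]:
    """Parameters Adam updates.

    With partial fine-tuning, backbone training is restricted to the
    batch-norm affine scale/shift; the GRU and head always train.
    """
    if not partial_finetune:
        return model.parameters()
    norm = [p for p in model.backbone_parameters() if p.tag == "norm_affine"]
    if not norm:
        raise ConfigError("partial fine-tuning requires a backbone with "
                          "normalisation layers")
    return norm + model.gru.parameters() + model.head.parameters()


def augment_tile(raster: np.ndarray, rng: np.random.Generator,
                 ranges: AugmentRanges = AugmentRanges()) -> np.ndarray:
    """Photometric augmentation: brightness, then saturation, then contrast.

    Brightness adds a uniform shift of up to ±``brightness`` of full scale;
    saturation blends toward/away from the per-pixel luminance; contrast
    scales deviation from the image mean.  Output is clipped uint8.
    """
    x = raster.astype(np.float32)
    b = rng.uniform(-ranges.brightness, ranges.brightness) * 255.0
    x = x + b
    s = rng.uniform(*ranges.saturation)
    grey = (x @ np.array([0.2125, 0.7154, 0.0721],
                         dtype=np.float32))[..., None]
    x = grey + s * (x - grey)
    c = rng.uniform(*ranges.contrast)
    mean = x.mean()
    x = mean + c * (x - mean)
    return np.clip(x, 0, 255).astype(np.uint8)


@dataclass
class TrainResult:
    model: TileClassifier
    history: list[dict]
    best_epoch: int
    best_val_loss: float


def _validation_loss(model: TileClassifier, x_val: np.ndarray,
                     y_val: np.ndarray, batch_size: int = 32) -> float:
    losses, counts = [], []
    for s in range(0, len(x_val), batch_size):
        xb, yb = x_val[s:s + batch_size], y_val[s:s + batch_size]
        logits = model.forward_logits(xb, train=False)
        loss, _ = nn.bce_with_logits(logits, yb)
        losses.append(loss)
        counts.append(len(xb))
    return float(np.average(losses, weights=counts))


def train_model(model: TileClassifier, state: SamplerState,
                slides: Mapping[str, Slide],
                val_tiles: Sequence[tuple[Tile, int]],
                config: TrainConfig,
                regions_by_slide: Mapping[str, Sequence[AnnotationRegion]] | None = None,
                jitter: bool = False) -> TrainResult:
    """Adam/BCE training with balanced batches, lr decay, hard mining and
    early stopping; returns the weights of the best-validation epoch.

    One epoch is ``steps_per_epoch`` balanced batches (weak supervision has
    no finite epoch); at epoch end the NILM slides in ``slides`` get a full
    sliding-window pass to refresh hard-mining weights.
    """
    rng = np.random.default_rng(config.seed)
    params = trainable_parameters(model, config.partial_finetune)
    opt = nn.Adam(params, lr=config.lr, beta1=config.beta1,
                  beta2=config.beta2)
    slide_dims = {sid: (s.width, s.height) for sid, s in slides.items()}

    x_val = np.stack([read_region(slides[t.slide_id], t)
                      for t, _ in val_tiles])
    y_val = np.array([lab for _, lab in val_tiles], dtype=np.float32)

    nilm_slides = [s for s in slides.values() if s.label == NILM]
    history: list[dict] = []
    best_val, best_epoch = np.inf, -1
    best_state = model.state_dict()

    for epoch in range(config.max_epochs):
        opt.lr = config.lr_at_epoch(epoch)
        train_losses = []
        for _ in range(config.steps_per_epoch):
            batch = sample_balanced_batch(
                state, config.batch_size, rng,
                regions_by_slide=regions_by_slide,
                slide_dims=slide_dims, jitter=jitter)
            rasters, labels = [], []
            for tile, lab in batch:
                r = read_region(slides[tile.slide_id], tile)
                if config.augment:
                    r = augment_tile(r, rng, config.augment_ranges)
                rasters.append(r)
                labels.append(lab)
            xb = np.stack(rasters)
            yb = np.array(labels, dtype=np.float32)
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch} "
                    f"(lr={opt.lr:.2g}, batch={len(xb)})")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            train_losses.append(loss)

        val_loss = _validation_loss(model, x_val, y_val)
        if config.hard_mining and nilm_slides:
            heatmaps = {
                s.id: predict_heatmap(
                    model, s, tile_size=state.tile_size, stride=state.stride,
                    min_fg_frac=config.mining_min_fg_frac,
                    mask_downsample=config.mask_downsample)
                for s in nilm_slides}
            state = update_hard_mining_weights(state, heatmaps,
                                               gamma=config.gamma)
        history.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss,
        })
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch,
                        best_epoch)
            break

    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val))


# ---------------------------------------------------------------------------
# Checkpoint and config files
# ---------------------------------------------------------------------------

def save_checkpoint(model: TileClassifier, path_prefix: str | Path,
                    history: list[dict] | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with config and history."""
    prefix = Path(path_prefix)
    np.savez(prefix.with_suffix(".npz"), **model.state_dict())
    sidecar = {"model_config": asdict(model.config),
               "history": history or []}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path_prefix: str | Path) -> tuple[TileClassifier, list]:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["model_config"])
    model = build_model(config)
    with np.load(prefix.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, sidecar.get("history", [])


def load_train_config(path: str | Path) -> tuple[ModelConfig, TrainConfig]:
    """YAML file with optional ``model:`` and ``train:`` sections."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    mc = ModelConfig(**(payload.get("model") or {}))
    tc_kwargs = dict(payload.get("train") or {})
    if "augment_ranges" in tc_kwargs:
        tc_kwargs["augment_ranges"] = AugmentRanges(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in tc_kwargs["augment_ranges"].items()})
    tc = TrainConfig(**tc_kwargs)
    return mc, tc
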