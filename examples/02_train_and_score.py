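"""Train the tiny CNN-GRU tile classifier on synthetic slides and score a
held-out cohort.

A reduced-scale version of the full workflow: 512 px slides, 128 px tiles
at stride 64, balanced positive/negative tile batches with hard-negative
mining, then sliding-window inference with max aggregation.  Runs in about
a minute on one CPU.
"""

from pathlib import Path

from lbcscreen.evaluation import roc_curve_and_auc
from lbcscreen.model import ModelConfig, TrainConfig
from lbcscreen.pipeline import load_cohort, run_training, score_cohort
from lbcscreen.synthetic import SyntheticSlideConfig, generate_cohort

root = Path("example_output/train_demo")
cfg = SyntheticSlideConfig.desk_scale()
generate_cohort(root / "train", 12, 0.5, cfg, seed=7, split="train")
generate_cohort(root / "val", 6, 0.5, cfg, seed=107, split="val")
generate_cohort(root / "test", 10, 0.5, cfg, seed=207, split="test")

tc = TrainConfig(seed=7, max_epochs=10, steps_per_epoch=24, batch_size=8,
                 partial_finetune=False, augment=False, mask_downsample=8)
result = run_training(load_cohort(root / "train"), load_cohort(root / "val"),
                      ModelConfig(input_size=128), tc,
                      tile_size=128, stride=64, mask_downsample=8)
print(f"best epoch {result.best_epoch}, "
      f"validation BCE {result.best_val_loss:.3f}")

preds, labels = score_cohort(result.model, load_cohort(root / "test"),
                             128, 64, mask_downsample=8)
for p, y in zip(preds, labels):
    print(f"  {p.slide_id}  score={p.score:.2f}  "
          f"label={'neoplastic' if y else 'NILM'}")
auc = roc_curve_and_auc([p.score for p in preds], labels).auc
print(f"held-out slide-level ROC AUC = {auc:.3f}")
print("The slide score is the max tile probability: one confidently"
      "\nneoplastic field flags the whole slide.")
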