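"""Slide-level screening metrics.

Confusion counts at a probability threshold (a call is positive when the
slide score is >= the threshold), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) = 1 - FPR, accuracy, ROC curve with trapezoidal
AUC, mean binary log loss, and percentile-bootstrap confidence intervals
(1000 resamples, 2.5/97.5 percentiles).

A bundled fixture carries the published five-cohort confusion matrices of
the cervical LBC screening study this package models (full-agreement,
clinical-balance and equal-balance test sets plus their reviewed variants),
so threshold metrics can be recomputed without any slide data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ConfigError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray   # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float] | None = None


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float = 0.5) -> ConfusionMatrix:
    """Counts with the >= rule: score exactly at threshold calls positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ConfigError("scores and labels differ in length")
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ConfigError("scores outside [0, 1]")
    pred = s >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))), fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))), fn=int(np.sum(~pred & (y == 1))))


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy; ``None`` when undefined."""
    if cm.total == 0:
        raise ConfigError("empty confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    acc = (cm.tp + cm.tn) / cm.total
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def roc_curve_and_auc(scores: Sequence[float],
                      labels: Sequence[int]) -> RocResult:
    """ROC by threshold sweep over all distinct scores; trapezoidal AUC.

    The trapezoidal area over the empirical ROC equals the Mann-Whitney
    statistic (concordant pairs plus half ties over n_pos * n_neg).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ConfigError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def log_loss(scores: Sequence[float], labels: Sequence[int],
             eps: float = 1e-15) -> float:
    """Mean binary cross-entropy (natural log), probabilities clipped."""
    p = np.clip(np.asarray(scores, dtype=float), eps, 1 - eps)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def bootstrap_ci(statistic: Callable[[np.ndarray, np.ndarray], float],
                 scores: Sequence[float], labels: Sequence[int],
                 n_boot: int = 1000, seed: int = 0,
                 max_retries: int = 100) -> tuple[float, float]:
    """95% percentile bootstrap interval for ``statistic(scores, labels)``.

    Pairs are resampled with replacement; a resample on which the statistic
    is undefined (e.g. single-class for AUC) is redrawn up to
    ``max_retries`` times.  If more than half the resamples fail outright
    the interval is not reported.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    values, failures = [], 0
    for _ in range(n_boot):
        ok = False
        for _ in range(max_retries):
            idx = rng.integers(len(s), size=len(s))
            try:
                values.append(float(statistic(s[idx], y[idx])))
                ok = True
                break
            except (ConfigError, ValueError, ZeroDivisionError):
                continue
        if not ok:
            failures += 1
    if failures > n_boot / 2:
        raise ConfigError(
            f"statistic undefined on {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal rounding with ties away from zero, for table comparisons."""
    q = 10 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Bundled published confusion matrices + report writer
# ---------------------------------------------------------------------------

def load_screening_confusion() -> dict[str, ConfusionMatrix]:
    """The five published test-cohort confusion matrices, by cohort name."""
    ref = resources.files("lbcscreen.data") / "screening_confusion.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return {r.cohort: ConfusionMatrix(tp=int(r.tp), fp=int(r.fp),
                                      tn=int(r.tn), fn=int(r.fn))
            for r in df.itertuples()}


def evaluation_report(scores: Sequence[float], labels: Sequence[int],
                      threshold: float = 0.5, n_boot: int = 1000,
                      seed: int = 0, with_ci: bool = True) -> dict:
    """Full metric panel for one cohort of slide scores."""
    cm = confusion_at_threshold(scores, labels, threshold)
    out: dict = {"threshold": threshold,
                 "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn,
                               "fn": cm.fn}}
    out.update(binary_metrics(cm))
    roc = roc_curve_and_auc(scores, labels)
    out["roc_auc"] = roc.auc
    out["log_loss"] = log_loss(scores, labels)
    if with_ci:
        out["roc_auc_ci95"] = bootstrap_ci(
            lambda s, y: roc_curve_and_auc(s, y).auc, scores, labels,
            n_boot=n_boot, seed=seed)
        out["accuracy_ci95"] = bootstrap_ci(
            lambda s, y: binary_metrics(
                confusion_at_threshold(s, y, threshold))["accuracy"],
            scores, labels, n_boot=n_boot, seed=seed)
    return out


def write_report(report: dict, path_prefix: str | Path) -> None:
    """JSON report plus a flat CSV of scalar metrics."""
    prefix = Path(path_prefix)
    prefix.with_suffix(".json").write_text(json.dumps(report, indent=1))
    flat = {k: v for k, v in report.items()
            if isinstance(v, (int, float)) or v is None}
    pd.DataFrame([flat]).to_csv(prefix.with_suffix(".csv"), index=False)
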