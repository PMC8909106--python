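from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray,
                    targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient.

    Uses the stable form ``max(z,0) - z*y + log(1+exp(-|z|))``; the gradient
    w.r.t. the logits is ``(sigmoid(z) - y)/N``.
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z.astype(np.float32)).astype(np.float64) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)
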