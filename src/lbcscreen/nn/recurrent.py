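from __future__ import annotations

import numpy as np

from .core import Layer, Parameter
from .losses import sigmoid


class GRU(Layer):
    """Gated recurrent unit over (N, T, D) sequences; returns final hidden.

    Update convention: ``h_t = z_t * h_{t-1} + (1 - z_t) * n_t`` with the
    candidate ``n_t = tanh(W_n x_t + U_n (r_t * h_{t-1}) + b_n)``, i.e. the
    reset gate multiplies the previous hidden state before the recurrent
    matrix (the original formulation).  Backward is full BPTT.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None,
                 name: str = "gru", tag: str = "rnn") -> None:
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(hidden_size)

        def u(shape, nm):
            return Parameter(rng.uniform(-s, s, shape), f"{name}.{nm}", tag)

        d, h = input_size, hidden_size
        self.Wz, self.Wr, self.Wn = u((h, d), "Wz"), u((h, d), "Wr"), u((h, d), "Wn")
        self.Uz, self.Ur, self.Un = u((h, h), "Uz"), u((h, h), "Ur"), u((h, h), "Un")
        self.bz, self.br, self.bn = (u((h,), "bz"), u((h,), "br"),
                                     u((h,), "bn"))
        self.hidden_size = h
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.Wz, self.Wr, self.Wn, self.Uz, self.Ur, self.Un,
                self.bz, self.br, self.bn]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, t, d = x.shape
        h = np.zeros((n, self.hidden_size), dtype=np.float32)
        steps = []
        for ti in range(t):
            xt = x[:, ti, :]
            z = sigmoid(xt @ self.Wz.value.T + h @ self.Uz.value.T
                        + self.bz.value)
            r = sigmoid(xt @ self.Wr.value.T + h @ self.Ur.value.T
                        + self.br.value)
            cand = np.tanh(xt @ self.Wn.value.T
                           + (r * h) @ self.Un.value.T + self.bn.value)
            h_new = z * h + (1 - z) * cand
            steps.append((xt, h, z, r, cand))
            h = h_new
        self._cache = (steps, x.shape)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        steps, xshape = self._cache
        dx = np.zeros(xshape, dtype=np.float32)
        dh = dh.astype(np.float32)
        for ti in range(len(steps) - 1, -1, -1):
            xt, h_prev, z, r, cand = steps[ti]
            dz_gate = dh * (h_prev - cand)
            dcand = dh * (1 - z)
            dh_prev = dh * z

            da_n = dcand * (1 - cand * cand)
            self.Wn.grad += da_n.T @ xt
            self.Un.grad += da_n.T @ (r * h_prev)
            self.bn.grad += da_n.sum(axis=0)
            drh = da_n @ self.Un.value
            dh_prev += drh * r
            dr = drh * h_prev

            da_r = dr * r * (1 - r)
            self.Wr.grad += da_r.T @ xt
            self.Ur.grad += da_r.T @ h_prev
            self.br.grad += da_r.sum(axis=0)
            dh_prev += da_r @ self.Ur.value

            da_z = dz_gate * z * (1 - z)
            self.Wz.grad += da_z.T @ xt
            self.Uz.grad += da_z.T @ h_prev
            self.bz.grad += da_z.sum(axis=0)
            dh_prev += da_z @ self.Uz.value

            dx[:, ti, :] = (da_n @ self.Wn.value + da_r @ self.Wr.value
                            + da_z @ self.Wz.value)
            dh = dh_prev
        return dx
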