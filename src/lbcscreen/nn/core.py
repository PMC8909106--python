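from __future__ import annotations

import numpy as np


class Parameter:
    """A named tensor with an accumulated gradient and a role tag.

    ``tag`` partitions parameters for partial fine-tuning: convolution
    kernels carry ``"conv"``, batch-norm scale/shift ``"norm_affine"``,
    recurrent weights ``"rnn"`` and the classifier head ``"head"``.
    """

    def __init__(self, value: np.ndarray, name: str, tag: str,
                 trainable: bool = True) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.tag = tag
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, {self.value.shape}, tag={self.tag})"


class Layer:
    """Forward/backward unit; subclasses cache what backward needs."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
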