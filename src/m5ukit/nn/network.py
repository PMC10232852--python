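"""Sequential network container: forward/backward, loss, prediction, (de)serialization."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import Dense, Layer

__all__ = ["Network", "binary_cross_entropy"]

_EPS = 1e-7


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities ``p`` against labels ``y``."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Network:
    """An ordered stack of layers mapping (B, 41, 4) one-hot input to (B,) probabilities.

    The final layer must be ``Dense(1, activation='sigmoid')``; training fuses
    that sigmoid with binary cross-entropy so the gradient entering the output
    pre-activation is simply ``(p - y) / B``.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple = (41, 4),
                 dtype=np.float32, seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        shape = self.input_shape
        names: dict[str, int] = {}
        for layer in layers:
            try:
                shape = layer.build(shape, rng, dtype)
            except ValueError as exc:
                raise ValueError(f"cannot build layer {layer.name!r}: {exc}") from exc
            names[layer.name] = names.get(layer.name, 0) + 1
            if names[layer.name] > 1:
                layer.name = f"{layer.name}_{names[layer.name]}"
        self.output_shape = shape
        last = layers[-1]
        if not (isinstance(last, Dense) and last.units == 1 and last.activation == "sigmoid"):
            raise ValueError("last layer must be Dense(1, activation='sigmoid')")

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Full forward pass; returns probabilities of shape (B,)."""
        a = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            a = layer.forward(a, training=training, rng=self._dropout_rng)
        return a[:, 0]

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Chunked inference returning float64 probabilities."""
        x = np.asarray(x)
        out = np.empty(x.shape[0], dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            out[start:start + batch_size] = self.forward(x[start:start + batch_size])
        return out

    # -- training ----------------------------------------------------------
    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer) -> float:
        """One minibatch update; returns the batch BCE loss."""
        p = self.forward(x, training=True)
        loss = binary_cross_entropy(p, y)
        self.zero_grads()
        dz = ((p - np.asarray(y, dtype=self.dtype)) / x.shape[0]).astype(self.dtype)[:, None]
        da = self.layers[-1].backward_preact(dz)
        for layer in reversed(self.layers[:-1]):
            da = layer.backward(da)
        optimizer.step(self.parameters(), self.gradients())
        return loss

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output probability)/d(input), per sample, at the current weights."""
        x = np.asarray(x, dtype=self.dtype)
        p = self.forward(x, training=False)
        dz = (p * (1.0 - p)).astype(self.dtype)[:, None]  # through the output sigmoid
        da = self.layers[-1].backward_preact(dz)
        for layer in reversed(self.layers[:-1]):
            da = layer.backward(da)
        self.zero_grads()  # parameter grads from this pass are not meaningful updates
        return da

    # -- introspection -----------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def forward_to(self, layer_selector: str | int, x: np.ndarray) -> np.ndarray:
        """Forward pass truncated at (and including) the selected layer.

        ``'input'`` (or ``'reshape'``) returns the raw input.  Unknown names
        raise with the list of available layers.
        """
        a = np.asarray(x, dtype=self.dtype)
        if layer_selector in ("input", "reshape"):
            return a
        if isinstance(layer_selector, int):
            try:
                stop = self.layers[layer_selector]
            except IndexError:
                raise KeyError(
                    f"layer index {layer_selector} out of range; available: "
                    f"{self.layer_names()}") from None
        else:
            matches = [l for l in self.layers if l.name == layer_selector]
            if not matches:
                raise KeyError(
                    f"unknown layer {layer_selector!r}; available: "
                    f"['input'] + {self.layer_names()}")
            stop = matches[0]
        for layer in self.layers:
            a = layer.forward(a, training=False, rng=self._dropout_rng)
            if layer is stop:
                return a
        raise AssertionError("unreachable")

    # -- serialization -----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w.astype(p.dtype)

    def save_weights(self, path: str | Path) -> None:
        np.savez(path, **{f"arr_{i}": p for i, p in enumerate(self.parameters())})

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()
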