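"""Neural-network layers with explicit forward/backward passes.

A deliberately small layer library in numpy, sufficient for the five
convolutional/recurrent architectures used for m5U window classification:
1-D valid convolution, non-overlapping max pooling, bidirectional LSTM/GRU
(classic gate equations, reset-before-matmul GRU), dense, dropout and
elementwise activations.  All heavy operations are phrased as BLAS matmuls,
so single-core float32 training of the full stacks is fast.

Conventions
-----------
* Sequence tensors are ``(batch, time, channels)``; flat tensors ``(batch, dim)``.
* ``forward`` always caches what ``backward`` needs; ``backward`` consumes the
  most recent forward pass, accumulates parameter gradients into ``grads`` and
  returns the gradient with respect to its input.
* Convolutions are "valid" (no padding): output length ``(L - K)//stride + 1``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "MaxPool1D", "Flatten", "Dense", "Dropout",
    "Activation", "BiLSTM", "BiGRU", "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, dtype) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q.astype(dtype)


class Layer:
    """Base layer: parameters, gradients, shape inference."""

    name: str = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def build(self, input_shape: tuple, rng: np.random.Generator, dtype) -> tuple:
        """Allocate parameters for the given input shape; return output shape."""
        return input_shape

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """Valid 1-D convolution with optional fused ReLU.

    The kernel is a ``(K, C, F)`` tensor; output position ``i`` of filter
    ``k`` is ``sum_m sum_n w[m, n, k] * x[i*stride + m, n] + b[k]`` — a sum of
    ``K`` matmuls over shifted input slices.
    """

    def __init__(self, filters: int, kernel_size: int, stride: int = 1,
                 activation: str | None = "relu", name: str = "conv1d"):
        super().__init__()
        if filters < 1 or kernel_size < 1 or stride < 1:
            raise ValueError("filters, kernel_size and stride must be positive")
        self.filters, self.kernel_size, self.stride = filters, kernel_size, stride
        self.activation = activation
        self.name = name

    def build(self, input_shape, rng, dtype):
        L, C = input_shape
        if self.kernel_size > L:
            raise ValueError(
                f"{self.name}: kernel size {self.kernel_size} exceeds input length {L}")
        self.W = _glorot_uniform(rng, (self.kernel_size, C, self.filters),
                                 fan_in=self.kernel_size * C,
                                 fan_out=self.kernel_size * self.filters, dtype=dtype)
        self.b = np.zeros(self.filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._L_out = (L - self.kernel_size) // self.stride + 1
        return (self._L_out, self.filters)

    def _slices(self, x):
        span = self.stride * (self._L_out - 1) + 1
        for m in range(self.kernel_size):
            yield m, x[:, m:m + span:self.stride, :]

    def forward(self, x, training=False, rng=None):
        z = np.broadcast_to(self.b, (x.shape[0], self._L_out, self.filters)).copy()
        for m, xs in self._slices(x):
            z += xs @ self.W[m]
        self._x = x
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        self._mask = None
        return z

    def backward(self, dy):
        dz = dy * self._mask if self._mask is not None else dy
        dW, db = self.grads
        db += dz.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        span = self.stride * (self._L_out - 1) + 1
        dz2 = dz.reshape(-1, self.filters)
        for m, xs in self._slices(self._x):
            dW[m] += xs.reshape(-1, xs.shape[2]).T @ dz2
            dx[:, m:m + span:self.stride, :] += dz @ self.W[m].T
        return dx


class MaxPool1D(Layer):
    """Max pooling over the time axis; remainder positions are dropped."""

    def __init__(self, pool_size: int, stride: int | None = None, name: str = "maxpool1d"):
        super().__init__()
        self.pool_size = pool_size
        self.stride = stride if stride is not None else pool_size
        self.name = name

    def build(self, input_shape, rng, dtype):
        L, C = input_shape
        if self.pool_size > L:
            raise ValueError(f"{self.name}: pool size {self.pool_size} exceeds length {L}")
        self._L_out = (L - self.pool_size) // self.stride + 1
        self._in_shape = input_shape
        return (self._L_out, C)

    def forward(self, x, training=False, rng=None):
        starts = np.arange(self._L_out) * self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, self.pool_size, axis=1)
        win = win[:, starts]                      # (B, L_out, C, pool)
        self._argmax = win.argmax(axis=3)
        self._x_shape = x.shape
        return win.max(axis=3)

    def backward(self, dy):
        B, L_out, C = dy.shape
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        b_idx, t_idx, c_idx = np.ogrid[:B, :L_out, :C]
        pos = t_idx * self.stride + self._argmax
        np.add.at(dx, (b_idx, pos, c_idx), dy)
        return dx


class Flatten(Layer):
    """(B, T, C) -> (B, T*C), time-major (position varies slowest)."""

    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def build(self, input_shape, rng, dtype):
        self._in_shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False, rng=None):
        self._batch_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._batch_shape)


class Dense(Layer):
    """Fully connected layer with optional fused activation."""

    def __init__(self, units: int, activation: str | None = None, name: str = "dense"):
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.units = units
        self.activation = activation
        self.name = name

    def build(self, input_shape, rng, dtype):
        if len(input_shape) != 1:
            raise ValueError(
                f"{self.name}: expects flat input, got shape {input_shape} "
                "(insert Flatten or a non-sequence recurrent layer)")
        D = input_shape[0]
        self.W = _glorot_uniform(rng, (D, self.units), D, self.units, dtype)
        self.b = np.zeros(self.units, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._cache = z > 0
            return z * self._cache
        if self.activation == "sigmoid":
            self._cache = sigmoid(z)
            return self._cache
        self._cache = None
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dz = dy * self._cache
        elif self.activation == "sigmoid":
            dz = dy * self._cache * (1.0 - self._cache)
        else:
            dz = dy
        return self.backward_preact(dz)

    def backward_preact(self, dz):
        """Backward from the pre-activation gradient (used to fuse the output
        sigmoid with binary cross-entropy: d(loss)/dz = (p - y)/B)."""
        dW, db = self.grads
        dW += self._x.T @ dz
        db += dz.sum(axis=0)
        return dz @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Activation(Layer):
    """Standalone elementwise activation (relu or sigmoid)."""

    def __init__(self, kind: str = "relu", name: str = "activation"):
        super().__init__()
        if kind not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported activation {kind!r}")
        self.kind = kind
        self.name = name

    def forward(self, x, training=False, rng=None):
        if self.kind == "relu":
            self._cache = x > 0
            return x * self._cache
        self._cache = sigmoid(x)
        return self._cache

    def backward(self, dy):
        if self.kind == "relu":
            return dy * self._cache
        return dy * self._cache * (1.0 - self._cache)


class _LSTMDirection:
    """One direction of an LSTM: gate order (i, f, g, o), forget bias 1."""

    def __init__(self, units: int):
        self.units = units

    def build(self, C, rng, dtype):
        U = self.units
        self.Wx = _glorot_uniform(rng, (C, 4 * U), C, 4 * U, dtype)
        self.Wh = np.concatenate([_orthogonal(rng, U, dtype) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * U, dtype=dtype)
        self.b[U:2 * U] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U), dtype=x.dtype)
        c = np.zeros((B, U), dtype=x.dtype)
        xW = x @ self.Wx + self.b          # (B, T, 4U): input contribution, all steps
        cache = []
        h_seq = np.empty((B, T, U), dtype=x.dtype)
        for t in range(T):
            z = xW[:, t] + h @ self.Wh
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = sigmoid(z[:, 3 * U:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            h_seq[:, t] = h
        self._cache = cache
        self._x = x
        return h_seq

    def backward(self, dh_seq):
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        U = self.units
        dWx, dWh, db = self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U), dtype=x.dtype)
        dc_next = np.zeros((B, U), dtype=x.dtype)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx


class _GRUDirection:
    """One direction of a GRU, classic formulation: the reset gate multiplies
    the previous hidden state *before* the candidate matmul, and the update
    gate interpolates ``h = (1 - z) * h_tilde + z * h_prev``."""

    def __init__(self, units: int):
        self.units = units

    def build(self, C, rng, dtype):
        U = self.units
        # input kernels for (r, z, h~); hidden kernels split: (r, z) and h~
        self.Wx = _glorot_uniform(rng, (C, 3 * U), C, 3 * U, dtype)
        self.Wh_rz = np.concatenate([_orthogonal(rng, U, dtype) for _ in range(2)], axis=1)
        self.Wh_h = _orthogonal(rng, U, dtype)
        self.b = np.zeros(3 * U, dtype=dtype)
        self.params = [self.Wx, self.Wh_rz, self.Wh_h, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U), dtype=x.dtype)
        xW = x @ self.Wx + self.b
        cache = []
        h_seq = np.empty((B, T, U), dtype=x.dtype)
        for t in range(T):
            rz = xW[:, t, :2 * U] + h @ self.Wh_rz
            r = sigmoid(rz[:, :U])
            z = sigmoid(rz[:, U:])
            rh = r * h
            ht = np.tanh(xW[:, t, 2 * U:] + rh @ self.Wh_h)
            h_new = (1.0 - z) * ht + z * h
            cache.append((h, r, z, ht, rh))
            h = h_new
            h_seq[:, t] = h
        self._cache = cache
        self._x = x
        return h_seq

    def backward(self, dh_seq):
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        U = self.units
        dWx, dWh_rz, dWh_h, db = self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U), dtype=x.dtype)
        for t in reversed(range(T)):
            h_prev, r, z, ht, rh = cache[t]
            dh = dh_seq[:, t] + dh_next
            dz_gate = dh * (h_prev - ht)
            dht = dh * (1.0 - z)
            dh_prev = dh * z
            dpre_h = dht * (1.0 - ht * ht)
            drh = dpre_h @ self.Wh_h.T
            dr = drh * h_prev
            dh_prev += drh * r
            dpre_r = dr * r * (1.0 - r)
            dpre_z = dz_gate * z * (1.0 - z)
            dpre_rz = np.concatenate([dpre_r, dpre_z], axis=1)
            dWh_rz += h_prev.T @ dpre_rz
            dWh_h += rh.T @ dpre_h
            dpre_all = np.concatenate([dpre_rz, dpre_h], axis=1)
            dWx += x[:, t].T @ dpre_all
            db += dpre_all.sum(axis=0)
            dx[:, t] = dpre_all @ self.Wx.T
            dh_next = dh_prev + dpre_rz @ self.Wh_rz.T
        return dx


class _Bidirectional(Layer):
    """Shared machinery for BiLSTM/BiGRU: run one direction on the sequence
    and one on its reversal; concatenate along channels.  Output is the full
    sequence (``return_sequences``) or the concatenated final states."""

    direction_cls: type

    def __init__(self, units: int, return_sequences: bool = False, name: str = "birnn"):
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.units = units
        self.return_sequences = return_sequences
        self.name = name
        self.fwd = self.direction_cls(units)
        self.bwd = self.direction_cls(units)

    def build(self, input_shape, rng, dtype):
        if len(input_shape) != 2:
            raise ValueError(f"{self.name}: expects (time, channels) input, got {input_shape}")
        T, C = input_shape
        self.fwd.build(C, rng, dtype)
        self.bwd.build(C, rng, dtype)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads
        return (T, 2 * self.units) if self.return_sequences else (2 * self.units,)

    def forward(self, x, training=False, rng=None):
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1])
        self._T = x.shape[1]
        if self.return_sequences:
            return np.concatenate([h_f, h_b[:, ::-1]], axis=2)
        return np.concatenate([h_f[:, -1], h_b[:, -1]], axis=1)

    def backward(self, dy):
        U, T = self.units, self._T
        if self.return_sequences:
            dh_f = dy[:, :, :U]
            dh_b = dy[:, ::-1, U:]
        else:
            dh_f = np.zeros((dy.shape[0], T, U), dtype=dy.dtype)
            dh_b = np.zeros((dy.shape[0], T, U), dtype=dy.dtype)
            dh_f[:, -1] = dy[:, :U]
            dh_b[:, -1] = dy[:, U:]
        dx = self.fwd.backward(np.ascontiguousarray(dh_f))
        dx += self.bwd.backward(np.ascontiguousarray(dh_b))[:, ::-1]
        return dx


class BiLSTM(_Bidirectional):
    """Bidirectional LSTM; ``units`` is per direction (output width 2*units)."""

    direction_cls = _LSTMDirection

    def __init__(self, units, return_sequences=False, name="bilstm"):
        super().__init__(units, return_sequences, name)


class BiGRU(_Bidirectional):
    """Bidirectional GRU; ``units`` is per direction (output width 2*units)."""

    direction_cls = _GRUDirection

    def __init__(self, units, return_sequences=False, name="bigru"):
        super().__init__(units, return_sequences, name)
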