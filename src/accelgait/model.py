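"""One-dimensional CNN mapping a 60x4 acceleration window to three joint angles.

The network is the fixed architecture
``(60,4) -> [dropout 0.1] -> conv(50,k3) -> conv(50,k3) -> maxpool(2)
-> conv(100,k3) -> conv(100,k3) -> flatten(2400) -> dense(100) -> dense(3)``
with valid (unpadded) convolutions, ReLU activations on all hidden layers,
a linear output, Xavier-normal initialisation, and a loss that weights the
per-joint batch RMSEs as ``(A*RMSE_hip + B*RMSE_knee + C*RMSE_ankle)/3``
with default weights (3, 1, 3) to push the optimiser towards the harder
hip and ankle targets.  The input dropout layer is used only when training
inter-participant (leave-one-subject-out) models, where it aids
generalisation to unseen runners.

Forward pass, backpropagation and the Adam optimiser are implemented
directly in NumPy (convolutions via im2col + matrix products), which keeps
training deterministic for a fixed seed and single-threaded BLAS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

#: Per-sample layer output shapes of the fixed architecture, input first.
EXPECTED_LAYER_SHAPES = [
    (60, 4), (58, 50), (56, 50), (28, 50), (26, 100), (24, 100),
    (2400,), (100,), (3,),
]


@dataclass
class CnnSpec:
    """Architecture and training hyperparameters.

    ``loss_weights`` are the (hip, knee, ankle) RMSE weights (A, B, C);
    ``use_dropout`` enables the input dropout layer (inter-participant
    training only).  ``dtype`` is float32 for speed; tests use float64 for
    finite-difference gradient checks.
    """

    input_shape: tuple[int, int] = (60, 4)
    conv_filters: tuple[int, ...] = (50, 50, 100, 100)
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    dense_units: int = 100
    n_outputs: int = 3
    dropout_rate: float = 0.1
    use_dropout: bool = False
    loss_weights: tuple[float, float, float] = (3.0, 1.0, 3.0)
    learning_rate: float = 0.001
    batch_size: int = 512
    epochs: int = 50
    seed: int = 0
    dtype: str = "float32"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CnnSpec":
        d = dict(d)
        for key in ("input_shape", "conv_filters", "loss_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng, self._mask = rate, rng, None

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Conv1D(_Layer):
    """Valid (unpadded) 1-D convolution, stride 1, optional ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype, relu: bool = True):
        super().__init__()
        fan_in, fan_out = kernel * c_in, kernel * c_out
        std = np.sqrt(2.0 / (fan_in + fan_out))      # Xavier normal
        self.W = rng.normal(0.0, std, size=(kernel * c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.kernel, self.c_in, self.c_out, self.relu = kernel, c_in, c_out, relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        B, L, C = x.shape
        k = self.kernel
        L_out = L - k + 1
        # (B, L, C) -> (B, L_out, C, k) -> (B*L_out, k*C) with memory layout
        # matching W's (k*C, c_out): rows are [tap0 ch0..C, tap1 ch0..C, ...].
        patches = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)
                                    ).reshape(B * L_out, k * C)
        z = cols @ self.W + self.b
        out = z.reshape(B, L_out, self.c_out)
        self._cols, self._in_shape = cols, (B, L, C)
        if self.relu:
            out = np.maximum(out, 0.0)
            self._active = out > 0
        return out

    def backward(self, g):
        B, L, C = self._in_shape
        k = self.kernel
        L_out = L - k + 1
        if self.relu:
            g = g * self._active
        g_mat = g.reshape(B * L_out, self.c_out)
        self.grads[0][...] = self._cols.T @ g_mat
        self.grads[1][...] = g_mat.sum(axis=0)
        W3 = self.W.reshape(k, C, self.c_out)
        dx = np.zeros((B, L, C), dtype=g.dtype)
        for j in range(k):
            dx[:, j:j + L_out, :] += g @ W3[j].T
        return dx


class MaxPool1D(_Layer):
    def __init__(self, size: int = 2, stride: int = 2):
        super().__init__()
        if size != stride:
            raise ValueError("only size == stride pooling is supported")
        self.size = size

    def forward(self, x, train=False):
        B, L, C = x.shape
        if L % self.size:
            raise ValueError(f"pooling a length-{L} sequence by {self.size}")
        blocks = x.reshape(B, L // self.size, self.size, C)
        self._arg = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, g):
        B, L, C = self._in_shape
        blocks = np.zeros((B, L // self.size, self.size, C), dtype=g.dtype)
        np.put_along_axis(blocks, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        return blocks.reshape(B, L, C)


class Flatten(_Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype, relu: bool):
        super().__init__()
        std = np.sqrt(2.0 / (n_in + n_out))          # Xavier normal
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.W + self.b
        if self.relu:
            out = np.maximum(out, 0.0)
            self._active = out > 0
        return out

    def backward(self, g):
        if self.relu:
            g = g * self._active
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Network:
    """The assembled CNN: ordered layers plus an Adam state."""

    def __init__(self, spec: CnnSpec):
        self.spec = spec
        dtype = np.dtype(spec.dtype)
        ss = np.random.SeedSequence(spec.seed).spawn(2)
        init_rng = np.random.default_rng(ss[0])
        self._dropout_rng = np.random.default_rng(ss[1])

        L, C = spec.input_shape
        k = spec.kernel_size
        layers: list[_Layer] = []
        if spec.use_dropout:
            layers.append(Dropout(spec.dropout_rate, self._dropout_rng))
        f1, f2, f3, f4 = spec.conv_filters
        layers.append(Conv1D(C, f1, k, init_rng, dtype))
        layers.append(Conv1D(f1, f2, k, init_rng, dtype))
        layers.append(MaxPool1D(spec.pool_size, spec.pool_stride))
        layers.append(Conv1D(f2, f3, k, init_rng, dtype))
        layers.append(Conv1D(f3, f4, k, init_rng, dtype))
        layers.append(Flatten())
        flat = self._flat_size()
        layers.append(Dense(flat, spec.dense_units, init_rng, dtype, relu=True))
        layers.append(Dense(spec.dense_units, spec.n_outputs, init_rng, dtype,
                            relu=False))
        self.layers = layers
        self._adam_m = [np.zeros_like(p) for lay in layers for p in lay.params]
        self._adam_v = [np.zeros_like(p) for lay in layers for p in lay.params]
        self._adam_t = 0

    def _flat_size(self) -> int:
        L, _ = self.spec.input_shape
        k = self.spec.kernel_size
        L = L - (k - 1)          # conv 1
        L = L - (k - 1)          # conv 2
        if L % self.spec.pool_size:
            raise ValueError("input shape incompatible with pooling")
        L //= self.spec.pool_size
        L = L - (k - 1)          # conv 3
        L = L - (k - 1)          # conv 4
        if L < 1:
            raise ValueError("input shape too short for this architecture")
        return L * self.spec.conv_filters[-1]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def layer_shapes(self) -> list[tuple[int, ...]]:
        """Per-sample output shape of every shape-bearing layer, input first."""
        x = np.zeros((1, *self.spec.input_shape), dtype=self.spec.dtype)
        shapes = [tuple(x.shape[1:])]
        for layer in self.layers:
            x = layer.forward(x, train=False)
            if not isinstance(layer, Dropout):
                shapes.append(tuple(x.shape[1:]))
        return shapes

    # -- parameters ---------------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters, weights, strict=True):
            p[...] = w

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self.parameters, self.gradients,
                              self._adam_m, self._adam_v):
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            p -= (lr * m_hat / (np.sqrt(v_hat) + eps)).astype(p.dtype)


def build_model(spec: CnnSpec | None = None) -> Network:
    """Construct the (untrained) network; weights are seeded by ``spec.seed``."""
    spec = spec or CnnSpec()
    if len(spec.input_shape) != 2:
        raise ValueError("input_shape must be (window_len, n_channels)")
    return Network(spec)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def weighted_loss(y_true: np.ndarray, y_pred: np.ndarray,
                  weights: tuple[float, float, float] = (3.0, 1.0, 3.0)) -> float:
    """Joint-weighted loss ``(A*RMSE_hip + B*RMSE_knee + C*RMSE_ankle) / 3``.

    Each RMSE is the root-mean-square error of one output column over the
    batch.  Non-negative, zero iff the prediction is exact.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim != 2 or y_true.shape[1] != len(weights):
        raise ValueError("expected (batch, 3) arrays")
    if y_true.shape[0] == 0:
        raise ValueError("empty batch")
    per_joint = np.sqrt(np.mean((y_true - y_pred) ** 2, axis=0))
    return float(np.dot(weights, per_joint) / len(weights))


def weighted_loss_grad(y_true: np.ndarray, y_pred: np.ndarray,
                       weights=(3.0, 1.0, 3.0)) -> np.ndarray:
    """Analytic d(loss)/d(y_pred); zero where a joint's RMSE is exactly 0."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    err = y_pred - y_true
    per_joint = np.sqrt(np.mean(err ** 2, axis=0))
    scale = np.zeros_like(per_joint)
    nonzero = per_joint > 0
    w = np.asarray(weights, dtype=float)
    scale[nonzero] = w[nonzero] / (len(w) * n * per_joint[nonzero])
    return err * scale


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedEstimator:
    """A fitted network plus the preprocessing fingerprint it expects."""

    network: Network
    spec: CnnSpec
    fingerprint: dict = field(default_factory=dict)
    history: list[float] = field(default_factory=list)

    @staticmethod
    def _paths(path) -> tuple[str, str]:
        base = str(path)
        if base.endswith(".npz"):
            base = base[:-4]
        return base + ".npz", base + ".json"

    def save(self, path) -> None:
        """Serialise weights (npz) with a JSON sidecar for spec/fingerprint."""
        npz_path, json_path = self._paths(path)
        np.savez(npz_path, *self.network.get_weights())
        with open(json_path, "w") as fh:
            json.dump({"spec": self.spec.to_dict(),
                       "fingerprint": self.fingerprint,
                       "history": self.history}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        npz_path, json_path = cls._paths(path)
        with open(json_path) as fh:
            meta = json.load(fh)
        spec = CnnSpec.from_dict(meta["spec"])
        net = build_model(spec)
        with np.load(npz_path) as data:
            net.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
        return cls(network=net, spec=spec, fingerprint=meta["fingerprint"],
                   history=meta["history"])


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "X") and hasattr(data, "y"):
        return data.X, data.y
    X, y = data
    return np.asarray(X), np.asarray(y)


def train(data, spec: CnnSpec | None = None, network: Network | None = None,
          fingerprint: dict | None = None, sample_stride: int = 1,
          verbose: bool = False) -> TrainedEstimator:
    """Train the CNN for exactly ``spec.epochs`` epochs.

    ``data`` is a WindowedDataset or an ``(X, y)`` pair.  ``sample_stride``
    optionally thins the training windows (every k-th window); since
    neighbouring single-sample-stride windows are nearly identical this
    trades a little data redundancy for proportionate speed.  Shuffling and
    initialisation are seeded from ``spec.seed``; per-epoch mean batch loss
    is recorded in the returned estimator's history.
    """
    spec = spec or CnnSpec()
    X, y = _as_xy(data)
    if sample_stride > 1:
        X, y = X[::sample_stride], y[::sample_stride]
    if len(X) == 0:
        raise ValueError("empty training set")
    if X.shape[1:] != tuple(spec.input_shape):
        raise ValueError(f"window shape {X.shape[1:]} does not match "
                         f"spec input {spec.input_shape}")
    if fingerprint is None and hasattr(data, "fingerprint"):
        fingerprint = dict(data.fingerprint)
    dtype = np.dtype(spec.dtype)
    X = np.ascontiguousarray(X, dtype=dtype)
    y = np.ascontiguousarray(y, dtype=dtype)

    net = network or build_model(spec)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))
    history = []
    n = len(X)
    for epoch in range(spec.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            out = net.forward(X[idx], train=True)
            loss = weighted_loss(y[idx], out, spec.loss_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {start} (lr={spec.learning_rate})")
            g = weighted_loss_grad(y[idx], out, spec.loss_weights).astype(dtype)
            net.backward(g)
            net.adam_step(spec.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1:3d}/{spec.epochs}  loss {history[-1]:.4f}")
    return TrainedEstimator(network=net, spec=spec,
                            fingerprint=fingerprint or {}, history=history)


def predict(estimator: TrainedEstimator, X: np.ndarray,
            batch_size: int = 4096) -> np.ndarray:
    """Apply a trained estimator to windows (N, 60, 4) -> angles (N, 3) deg."""
    X = np.asarray(X)
    if X.ndim != 3 or X.shape[1:] != tuple(estimator.spec.input_shape):
        raise ValueError(f"input shape {X.shape[1:]} does not match the "
                         f"estimator's {estimator.spec.input_shape}")
    if len(X) == 0:
        return np.zeros((0, estimator.spec.n_outputs))
    dtype = np.dtype(estimator.spec.dtype)
    outs = [estimator.network.forward(
        np.ascontiguousarray(X[i:i + batch_size], dtype=dtype), train=False)
        for i in range(0, len(X), batch_size)]
    out = np.concatenate(outs).astype(float)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite predictions")
    return out
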