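"""Classical network head and training loop.

Implements the dense layers, activations and losses that sit on top of
the quanvolutional feature extractor, a small im2col-based Conv2D /
MaxPool stack for the classical reference CNN, exact parameter counting
over architecture specs, and a batch training loop that plugs into the
adaptive optimizer.  Gradients are analytic (backpropagation); the
quanvolution kernel's angles receive exact parameter-shift gradients.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
import pandas as pd

from . import quanvolution as qv
from .adaptive_optimizer import AdaptiveSGD

ACTIVATIONS = ("relu", "tanh", "sigmoid", "softmax", "none")


# ---------------------------------------------------------------------------
# losses and activations
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-stable softmax along the last axis; rows sum to 1."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax input is empty")
    shifted = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


def squared_error(targets: np.ndarray, outputs: np.ndarray) -> float:
    """E = 1/2 * sum((t - o)**2)."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValueError(
            f"targets shape {targets.shape} != outputs shape {outputs.shape}"
        )
    return 0.5 * float(np.sum((targets - outputs) ** 2))


def cross_entropy(targets, probs: np.ndarray) -> float:
    """Categorical cross-entropy, -log p(true class), clipped at 1e-12.

    ``targets`` is a class index or a one-hot vector; ``probs`` a
    probability vector.
    """
    probs = np.asarray(probs, dtype=float)
    if np.ndim(targets) == 0:
        index = int(targets)
        if not 0 <= index < probs.size:
            raise IndexError(f"class index {index} out of range for {probs.size}")
        p = probs[index]
    else:
        targets = np.asarray(targets, dtype=float)
        if targets.shape != probs.shape:
            raise ValueError("one-hot targets must match probs shape")
        p = float(np.dot(targets, probs))
    return -math.log(max(float(p), 1e-12))


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, num_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "softmax":
        return softmax(z)
    if kind == "none":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _activation_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    """Elementwise da/dz (softmax handled jointly with the loss)."""
    if kind == "relu":
        return (z > 0.0).astype(float)
    if kind == "tanh":
        return 1.0 - a ** 2
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "none":
        return np.ones_like(z)
    raise ValueError(f"activation {kind!r} has no elementwise gradient")


# ---------------------------------------------------------------------------
# architecture specs and parameter counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuanvSpec:
    """One quanvolution layer (optionally with quantum pooling)."""

    window: int = 2
    stride: int = 1
    entangler: str = "ring"
    trainable: bool = True
    pooled: bool = True  # quantum pooling -> one channel per window

    @property
    def num_parameters(self) -> int:
        return self.window ** 2 if self.trainable else 0


@dataclass(frozen=True)
class Conv2DSpec:
    in_channels: int
    filters: int
    kernel_size: int
    stride: int = 1
    activation: str = "tanh"

    @property
    def num_parameters(self) -> int:
        # standard counting: (k*k*in_channels + 1) * filters
        return (self.kernel_size ** 2 * self.in_channels + 1) * self.filters


@dataclass(frozen=True)
class MaxPoolSpec:
    pool: int = 2

    num_parameters: int = 0


@dataclass(frozen=True)
class FlattenSpec:
    num_parameters: int = 0


@dataclass(frozen=True)
class DenseSpec:
    in_dim: int
    out_dim: int
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.out_dim < 1:
            raise ValueError("dense dimensions must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def num_parameters(self) -> int:
        return self.in_dim * self.out_dim + self.out_dim


LayerSpec = QuanvSpec | Conv2DSpec | MaxPoolSpec | FlattenSpec | DenseSpec


@dataclass
class ArchitectureSpec:
    """Ordered layer descriptors; adjacent dense dimensions must chain."""

    layers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_out = None
        for layer in self.layers:
            if isinstance(layer, DenseSpec):
                if prev_out is not None and layer.in_dim != prev_out:
                    raise ValueError(
                        f"dense layer expects {layer.in_dim} inputs but the "
                        f"previous dense layer emits {prev_out}"
                    )
                prev_out = layer.out_dim
            else:
                prev_out = None  # non-dense layers reshape the signal


def count_trainable_parameters(arch: ArchitectureSpec) -> int:
    """Sum of per-layer trainable parameter counts.

    Dense: in*out + out.  Conv2D: (k*k*in_channels + 1)*filters.
    Quanvolution: window**2 kernel angles when trainable.  Pooling and
    flatten layers carry none.
    """
    return sum(layer.num_parameters for layer in arch.layers)


def ga_selected_hqcnn(trainable_kernel: bool = True) -> ArchitectureSpec:
    """The GA-selected hybrid architecture: one quanvolution layer with
    quantum pooling (4 kernel angles), flatten, then dense 4 -> 128 -> 64
    -> 4 with a softmax head.  Total 9160 trainable parameters."""
    return ArchitectureSpec(
        [
            QuanvSpec(trainable=trainable_kernel, pooled=True),
            FlattenSpec(),
            DenseSpec(4, 128, "relu"),
            DenseSpec(128, 64, "relu"),
            DenseSpec(64, 4, "softmax"),
        ]
    )


def dense_head(num_features: int) -> ArchitectureSpec:
    """The classical head alone (dense 128 -> 64 -> 4 over precomputed
    quanvolution features), for training with a frozen kernel."""
    return ArchitectureSpec(
        [
            DenseSpec(num_features, 128, "relu"),
            DenseSpec(128, 64, "relu"),
            DenseSpec(64, 4, "softmax"),
        ]
    )


def reference_cnn(input_side: int = 32, in_channels: int = 1) -> ArchitectureSpec:
    """The GA-selected classical reference CNN: three 2x2 conv blocks
    (32, 64, 64 filters) each followed by 2x2 max pooling, then a
    512-unit dense layer and a 4-way softmax head.  Parameters follow
    standard counting."""
    side = input_side
    for _ in range(3):
        side //= 2
    flat = side * side * 64
    return ArchitectureSpec(
        [
            Conv2DSpec(in_channels, 32, 2),
            MaxPoolSpec(2),
            Conv2DSpec(32, 64, 2),
            MaxPoolSpec(2),
            Conv2DSpec(64, 64, 2),
            MaxPoolSpec(2),
            FlattenSpec(),
            DenseSpec(flat, 512, "relu"),
            DenseSpec(512, 4, "softmax"),
        ]
    )


# ---------------------------------------------------------------------------
# layer objects (forward / backward)
# ---------------------------------------------------------------------------

class DenseLayer:
    def __init__(self, spec: DenseSpec, rng: np.random.Generator):
        self.spec = spec
        limit = math.sqrt(6.0 / (spec.in_dim + spec.out_dim))
        self.weights = rng.uniform(-limit, limit, size=(spec.in_dim, spec.out_dim))
        self.bias = np.zeros(spec.out_dim)
        self.grad_weights = np.zeros_like(self.weights)
        self.grad_bias = np.zeros_like(self.bias)
        self._x = self._z = self._a = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.spec.in_dim:
            raise ValueError(
                f"dense layer expects (batch, {self.spec.in_dim}), got {x.shape}"
            )
        self._x = x
        self._z = x @ self.weights + self.bias
        self._a = _activate(self._z, self.spec.activation)
        return self._a

    def backward(self, grad_out: np.ndarray, skip_activation: bool = False):
        """grad_out is dLoss/da (or dLoss/dz when ``skip_activation``,
        used for the fused softmax + cross-entropy head)."""
        if skip_activation:
            dz = grad_out
        else:
            dz = grad_out * _activation_grad(self._z, self._a, self.spec.activation)
        self.grad_weights = self._x.T @ dz
        self.grad_bias = dz.sum(axis=0)
        return dz @ self.weights.T

    def parameters(self):
        return [self.weights, self.bias]

    def gradients(self):
        return [self.grad_weights, self.grad_bias]


class FlattenLayer:
    spec = FlattenSpec()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out, skip_activation: bool = False):
        return grad_out.reshape(self._shape)

    def parameters(self):
        return []

    def gradients(self):
        return []


class QuanvLayer:
    """Quanvolution front end: images (batch, m, m) in, features out.

    Pooled mode emits (batch, (m-1)^2); unpooled mode emits the full
    channel stack (batch, (m-1)^2 * window^2).  When trainable, the four
    kernel angles get exact parameter-shift gradients (shift pi/2):
    d<Z>/d theta_i = [<Z>(theta_i + pi/2) - <Z>(theta_i - pi/2)] / 2.
    No gradient flows into the pixels (the layer is the network input).
    """

    def __init__(self, spec: QuanvSpec, rng: np.random.Generator):
        self.spec = spec
        if spec.trainable:
            kernel_theta = rng.uniform(0.0, 2.0 * math.pi, size=spec.window ** 2)
            self.kernel = qv.QuanvKernel(
                theta=kernel_theta, entangler=spec.entangler, trainable=True,
                num_qubits=spec.window ** 2,
            )
        else:
            self.kernel = qv.QuanvKernel.random(
                rng, entangler=spec.entangler, num_qubits=spec.window ** 2
            )
        self.pooling = qv.default_pooling(num_qubits=spec.window ** 2)
        self.grad_theta = np.zeros_like(self.kernel.theta)
        self._images = None

    def _features(self, images: np.ndarray, kernel: qv.QuanvKernel) -> np.ndarray:
        rows = []
        for img in images:
            pre = qv.PreprocessedImage(img)
            if self.spec.pooled:
                rows.append(
                    qv.quantum_pool(pre, kernel, self.pooling,
                                    self.spec.window, self.spec.stride)
                )
            else:
                rows.append(
                    qv.flatten_features(
                        qv.quanv_convolve(pre, kernel,
                                          self.spec.window, self.spec.stride)
                    )
                )
        return np.asarray(rows)

    def forward(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 3:
            raise ValueError(
                f"quanvolution expects (batch, m, m) images, got {images.shape}"
            )
        self._images = images
        return self._features(images, self.kernel)

    def backward(self, grad_out: np.ndarray, skip_activation: bool = False):
        if self.kernel.trainable:
            grads = np.zeros_like(self.kernel.theta)
            for i in range(self.kernel.theta.size):
                plus = self.kernel.theta.copy()
                plus[i] += math.pi / 2.0
                minus = self.kernel.theta.copy()
                minus[i] -= math.pi / 2.0
                f_plus = self._features(self._images, self.kernel.with_theta(plus))
                f_minus = self._features(self._images, self.kernel.with_theta(minus))
                grads[i] = float(np.sum(grad_out * (f_plus - f_minus) / 2.0))
            self.grad_theta = grads
        return None

    def parameters(self):
        return [self.kernel.theta] if self.kernel.trainable else []

    def gradients(self):
        return [self.grad_theta] if self.kernel.trainable else []


class Conv2DLayer:
    """'same'-padded stride-1 convolution via im2col (small inputs only)."""

    def __init__(self, spec: Conv2DSpec, rng: np.random.Generator):
        if spec.stride != 1:
            raise ValueError("only stride-1 convolution is implemented")
        self.spec = spec
        k, cin, cout = spec.kernel_size, spec.in_channels, spec.filters
        limit = math.sqrt(6.0 / (k * k * cin + cout))
        self.weights = rng.uniform(-limit, limit, size=(k * k * cin, cout))
        self.bias = np.zeros(cout)
        self.grad_weights = np.zeros_like(self.weights)
        self.grad_bias = np.zeros_like(self.bias)

    def _pad_sizes(self):
        k = self.spec.kernel_size
        before = (k - 1) // 2
        return before, k - 1 - before

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        k = self.spec.kernel_size
        p0, p1 = self._pad_sizes()
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
        cols = np.empty((b, h, w, k, k, self.spec.in_channels))
        for di in range(k):
            for dj in range(k):
                cols[:, :, :, di, dj, :] = xp[:, di : di + h, dj : dj + w, :]
        return cols.reshape(b * h * w, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.spec.in_channels:
            raise ValueError(
                f"conv layer expects (batch, h, w, {self.spec.in_channels}), "
                f"got {x.shape}"
            )
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        b, h, w, _ = x.shape
        self._z = (self._cols @ self.weights + self.bias).reshape(
            b, h, w, self.spec.filters
        )
        self._a = _activate(self._z, self.spec.activation)
        return self._a

    def backward(self, grad_out, skip_activation: bool = False):
        dz = grad_out * _activation_grad(self._z, self._a, self.spec.activation)
        b, h, w, cout = dz.shape
        dz_flat = dz.reshape(b * h * w, cout)
        self.grad_weights = self._cols.T @ dz_flat
        self.grad_bias = dz_flat.sum(axis=0)
        dcols = (dz_flat @ self.weights.T).reshape(
            b, h, w, self.spec.kernel_size, self.spec.kernel_size,
            self.spec.in_channels,
        )
        p0, p1 = self._pad_sizes()
        k = self.spec.kernel_size
        dxp = np.zeros((b, h + k - 1, w + k - 1, self.spec.in_channels))
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, p0 : p0 + h, p1 : p1 + w, :]

    def parameters(self):
        return [self.weights, self.bias]

    def gradients(self):
        return [self.grad_weights, self.grad_bias]


class MaxPoolLayer:
    def __init__(self, spec: MaxPoolSpec):
        self.spec = spec

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.spec.pool
        b, h, w, c = x.shape
        hp, wp = h // p, w // p
        x = x[:, : hp * p, : wp * p, :]
        self._in_shape = x.shape
        blocks = x.reshape(b, hp, p, wp, p, c)
        self._blocks = blocks
        out = blocks.max(axis=(2, 4))
        self._mask = blocks == out[:, :, None, :, None, :]
        return out

    def backward(self, grad_out, skip_activation: bool = False):
        # ties share the gradient equally
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        grad_blocks = (
            self._mask * grad_out[:, :, None, :, None, :] / counts
        )
        return grad_blocks.reshape(self._in_shape)

    def parameters(self):
        return []

    def gradients(self):
        return []


def _build_layer(spec: LayerSpec, rng: np.random.Generator):
    if isinstance(spec, DenseSpec):
        return DenseLayer(spec, rng)
    if isinstance(spec, QuanvSpec):
        return QuanvLayer(spec, rng)
    if isinstance(spec, Conv2DSpec):
        return Conv2DLayer(spec, rng)
    if isinstance(spec, MaxPoolSpec):
        return MaxPoolLayer(spec)
    if isinstance(spec, FlattenSpec):
        return FlattenLayer()
    raise ValueError(f"unknown layer spec {spec!r}")


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class Model:
    """A sequential network built from an :class:`ArchitectureSpec`."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0,
                 loss: str = "cross_entropy"):
        if loss not in ("cross_entropy", "squared_error"):
            raise ValueError(f"unknown loss {loss!r}")
        self.arch = arch
        self.loss_kind = loss
        rng = np.random.default_rng(seed)
        self.layers = [_build_layer(spec, rng) for spec in arch.layers]

    # -- forward / loss / backward ------------------------------------

    def forward(self, batch: np.ndarray) -> np.ndarray:
        out = np.asarray(batch, dtype=float)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def loss(self, probs: np.ndarray, labels: np.ndarray) -> float:
        targets = one_hot(labels, probs.shape[1])
        if self.loss_kind == "cross_entropy":
            p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
            return float(np.mean(-np.log(p)))
        return squared_error(targets, probs) / len(labels)

    def backward(self, probs: np.ndarray, labels: np.ndarray) -> None:
        """Backpropagate the mean loss over the batch into layer grads."""
        n = len(labels)
        targets = one_hot(labels, probs.shape[1])
        head = self.layers[-1]
        head_is_softmax = (
            isinstance(head, DenseLayer) and head.spec.activation == "softmax"
        )
        if self.loss_kind == "cross_entropy":
            if not head_is_softmax:
                raise ValueError("cross-entropy training requires a softmax head")
            grad = (probs - targets) / n  # fused softmax + CE gradient wrt z
            grad = head.backward(grad, skip_activation=True)
            rest = self.layers[:-1]
        elif head_is_softmax:
            # squared error through the softmax Jacobian, per sample
            d_probs = (probs - targets) / n
            dot = np.sum(d_probs * probs, axis=1, keepdims=True)
            grad = probs * (d_probs - dot)
            grad = head.backward(grad, skip_activation=True)
            rest = self.layers[:-1]
        else:
            grad = (probs - targets) / n
            rest = self.layers
        for layer in reversed(rest):
            grad = layer.backward(grad)
            if grad is None:
                break

    def loss_and_gradients(self, batch: np.ndarray, labels: np.ndarray) -> float:
        probs = self.forward(batch)
        self.backward(probs, labels)
        return self.loss(probs, labels)

    # -- parameter access ---------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def num_parameters(self) -> int:
        return count_trainable_parameters(self.arch)

    # -- evaluation ----------------------------------------------------

    def evaluate(self, batch: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
        """(mean loss, accuracy) without touching gradients."""
        probs = self.forward(batch)
        loss = self.loss(probs, labels)
        accuracy = float(np.mean(np.argmax(probs, axis=1) == labels))
        return loss, accuracy

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(batch), axis=1)

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Single-archive save: JSON manifest + one array per parameter."""
        manifest = {
            "loss": self.loss_kind,
            "layers": [type(spec).__name__ for spec in self.arch.layers],
            "num_parameters": self.num_parameters(),
        }
        with zipfile.ZipFile(path, "w") as archive:
            archive.writestr("manifest.json", json.dumps(manifest, indent=2))
            for i, p in enumerate(self.parameters()):
                buf = BytesIO()
                np.save(buf, p)
                archive.writestr(f"param_{i}.npy", buf.getvalue())

    def load(self, path) -> None:
        with zipfile.ZipFile(path) as archive:
            for i, p in enumerate(self.parameters()):
                with archive.open(f"param_{i}.npy") as handle:
                    p[...] = np.load(BytesIO(handle.read()))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> np.ndarray:
        return np.array([rec[name] for rec in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def train(
    model: Model,
    train_set: tuple[np.ndarray, np.ndarray],
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
    optimizer=None,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
) -> TrainingHistory:
    """Mini-batch training: forward/backward/step per batch, then an
    end-of-epoch evaluation that feeds the adaptive schedule.

    Reproducible: batch shuffling uses its own generator seeded by
    ``seed``.  The evaluation loss driving the adaptive momentum comes
    from ``eval_set`` when given, else from the training set.
    """
    x_train, y_train = train_set
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    optimizer = optimizer or AdaptiveSGD()
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    for epoch in range(epochs):
        lr, momentum = optimizer.current_lr, optimizer.current_momentum
        order = rng.permutation(len(x_train))
        batch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            loss = model.loss_and_gradients(x_train[idx], y_train[idx])
            optimizer.step(model.parameters(), model.gradients())
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        if eval_set is not None:
            eval_loss, eval_accuracy = model.evaluate(*eval_set)
        else:
            eval_loss, eval_accuracy = model.evaluate(x_train, y_train)
        if not math.isfinite(train_loss) or not math.isfinite(eval_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        optimizer.end_epoch(eval_loss)
        history.append(
            epoch=epoch,
            train_loss=train_loss,
            eval_loss=eval_loss,
            eval_accuracy=eval_accuracy,
            lr=lr,
            momentum=momentum,
        )
    return history
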