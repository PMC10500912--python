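"""Quanvolutional feature extraction with quantum pooling.

An image window (by default 2x2) is encoded into one qubit per pixel via
Ry(pi * x) rotations from the ground state, a shared four-parameter
kernel circuit u(theta) is applied, and Pauli-Z expectations are read
out.  Scanning the window across the image (stride 1, overlapping)
yields (m-1)^2 positions for an m x m image; each position carries one
output channel per window qubit.  Quantum pooling instead appends a
parameter-free unitary V after the kernel and measures a single
designated qubit per window, producing a length-(m-1)^2 feature vector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize_local_mean

from .qsim import (
    CircuitSpec,
    GateSpec,
    StateVector,
    ground_state,
    run_circuit,
    z_expectation,
    z_expectations,
)

ENTANGLERS = ("none", "ring")


# ---------------------------------------------------------------------------
# image preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedImage:
    """An m x m pixel grid scaled to [0, 1], with its row-major flattening."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"expected a square grid, got shape {self.pixels.shape}")
        if np.min(self.pixels) < -1e-12 or np.max(self.pixels) > 1.0 + 1e-12:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.pixels.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.pixels.ravel()


def preprocess_image(raw: np.ndarray, m: int) -> PreprocessedImage:
    """Downsample to m x m by local-mean (area-average) resizing, then
    min-max scale to [0, 1].

    A constant-valued image maps to all zeros (the min-max denominator is
    degenerate; zero is the documented convention).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("raw image is empty")
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={raw.ndim}")
    if m < 2:
        raise ValueError(f"target side m must be >= 2, got {m}")
    if raw.shape == (m, m):
        small = raw
    else:
        small = resize_local_mean(raw, (m, m))
    from .evaluation import minmax_normalize

    return PreprocessedImage(minmax_normalize(small))


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedPatch:
    """Angle encoding of a pixel patch: alpha_i = pi * x_i on qubit i."""

    angles: np.ndarray
    state: StateVector


def encode_patch(patch_pixels: np.ndarray) -> EncodedPatch:
    """Encode k pixels in [0, 1] as Ry(pi * x_i)|0> on a k-qubit register."""
    pixels = np.asarray(patch_pixels, dtype=float).ravel()
    if pixels.size == 0:
        raise ValueError("patch is empty")
    if np.min(pixels) < -1e-12 or np.max(pixels) > 1.0 + 1e-12:
        raise ValueError("patch pixel values must lie in [0, 1]")
    angles = math.pi * pixels
    state = run_circuit(encoding_circuit(angles))
    return EncodedPatch(angles=angles, state=state)


def encoding_circuit(angles: np.ndarray) -> CircuitSpec:
    circuit = CircuitSpec(num_qubits=len(angles))
    circuit.extend(GateSpec("RY", (float(a),), target=i) for i, a in enumerate(angles))
    return circuit


# ---------------------------------------------------------------------------
# kernel and pooling circuits
# ---------------------------------------------------------------------------

@dataclass
class QuanvKernel:
    """The shared convolution kernel u(theta): four trainable Ry angles on
    a four-qubit window, optionally followed by a CNOT entangler ring."""

    theta: np.ndarray = field(default_factory=lambda: np.zeros(4))
    entangler: str = "ring"
    trainable: bool = True
    num_qubits: int = 4

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if self.theta.size != self.num_qubits:
            raise ValueError(
                f"kernel takes {self.num_qubits} parameters, got {self.theta.size}"
            )
        if self.entangler not in ENTANGLERS:
            raise ValueError(
                f"unknown entangler {self.entangler!r}; expected one of {ENTANGLERS}"
            )

    @classmethod
    def random(
        cls, rng: np.random.Generator, entangler: str = "ring", num_qubits: int = 4
    ) -> "QuanvKernel":
        """Random (frozen) kernel: angles uniform on [0, 2*pi)."""
        theta = rng.uniform(0.0, 2.0 * math.pi, size=num_qubits)
        return cls(theta=theta, entangler=entangler, trainable=False,
                   num_qubits=num_qubits)

    def with_theta(self, theta: np.ndarray) -> "QuanvKernel":
        return QuanvKernel(theta=theta, entangler=self.entangler,
                           trainable=self.trainable, num_qubits=self.num_qubits)


def kernel_circuit(kernel: QuanvKernel) -> CircuitSpec:
    """Ry(theta_i) on each qubit, then the entangler layout.

    "ring": CNOT(0->1), CNOT(1->2), ..., CNOT(n-1 -> 0).
    Deterministic: identical kernels give identical circuits.
    """
    n = kernel.num_qubits
    circuit = CircuitSpec(num_qubits=n)
    circuit.extend(
        GateSpec("RY", (float(t),), target=i) for i, t in enumerate(kernel.theta)
    )
    if kernel.entangler == "ring":
        circuit.extend(
            GateSpec("CNOT", (), target=(i + 1) % n, control=i) for i in range(n)
        )
    return circuit


@dataclass
class PoolingSpec:
    """Quantum pooling: a parameter-free unitary V, then measure one qubit."""

    pooled_qubit: int = 0
    v_circuit: CircuitSpec | None = None

    def __post_init__(self) -> None:
        if self.v_circuit is not None and self.v_circuit.num_parameters != 0:
            raise ValueError("pooling circuit V must be parameter-free")

    def to_json(self) -> str:
        return json.dumps(
            {
                "pooled_qubit": self.pooled_qubit,
                "v_circuit": None
                if self.v_circuit is None
                else json.loads(self.v_circuit.to_json()),
            }
        )

    @classmethod
    def from_json(cls, document: str) -> "PoolingSpec":
        d = json.loads(document)
        v = d.get("v_circuit")
        return cls(
            pooled_qubit=int(d["pooled_qubit"]),
            v_circuit=None if v is None else CircuitSpec.from_json(json.dumps(v)),
        )


def default_pooling(num_qubits: int = 4, pooled_qubit: int = 0) -> PoolingSpec:
    """CNOT ladder funneling every other qubit into the pooled qubit:
    CNOT(q -> pooled) for each q != pooled."""
    v = CircuitSpec(num_qubits=num_qubits)
    v.extend(
        GateSpec("CNOT", (), target=pooled_qubit, control=q)
        for q in range(num_qubits)
        if q != pooled_qubit
    )
    return PoolingSpec(pooled_qubit=pooled_qubit, v_circuit=v)


def identity_pooling(pooled_qubit: int = 0) -> PoolingSpec:
    return PoolingSpec(pooled_qubit=pooled_qubit, v_circuit=None)


# ---------------------------------------------------------------------------
# the quanvolution scan
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Per-window Z-expectation channels, shaped (height, width, channels)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("feature map must be (height, width, channels)")
        if np.min(self.values) < -1.0 - 1e-12 or np.max(self.values) > 1.0 + 1e-12:
            raise ValueError("feature-map values must lie in [-1, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    def to_json(self) -> str:
        return json.dumps({"shape": list(self.values.shape),
                           "values": self.values.ravel().tolist()})

    @classmethod
    def from_json(cls, document: str) -> "FeatureMap":
        d = json.loads(document)
        return cls(np.asarray(d["values"]).reshape(d["shape"]))

    def to_csv(self, path) -> None:
        """One row per window position: row, col, then every channel."""
        import pandas as pd

        h, w, c = self.values.shape
        rows, cols = np.divmod(np.arange(h * w), w)
        frame = pd.DataFrame(self.values.reshape(h * w, c),
                             columns=[f"channel_{k}" for k in range(c)])
        frame.insert(0, "col", cols)
        frame.insert(0, "row", rows)
        frame.to_csv(path, index=False)


def _window_grid(m: int, window: int, stride: int) -> list[tuple[int, int]]:
    if window > m:
        raise ValueError(f"window {window} exceeds image side {m}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    positions = range(0, m - window + 1, stride)
    return [(r, c) for r in positions for c in positions]


def quanv_convolve(
    image: PreprocessedImage,
    kernel: QuanvKernel,
    window: int = 2,
    stride: int = 1,
) -> FeatureMap:
    """Scan the kernel across the image and read all per-qubit Z channels.

    Every window position yields window**2 channels (one per qubit).  With
    window=2, stride=1 the output grid is (m-1) x (m-1).
    """
    m = image.m
    if window ** 2 != kernel.num_qubits:
        raise ValueError(
            f"{window}x{window} window needs a {window ** 2}-qubit kernel, "
            f"kernel has {kernel.num_qubits}"
        )
    side = (m - window) // stride + 1
    circuit = kernel_circuit(kernel)
    values = np.empty((side, side, kernel.num_qubits))
    for r, c in _window_grid(m, window, stride):
        patch = image.pixels[r : r + window, c : c + window].ravel()
        state = run_circuit(circuit, encode_patch(patch).state)
        values[r // stride, c // stride] = z_expectations(state)
    return FeatureMap(values)


def quantum_pool(
    image: PreprocessedImage,
    kernel: QuanvKernel,
    pooling: PoolingSpec,
    window: int = 2,
    stride: int = 1,
) -> np.ndarray:
    """Per window: encode, apply u(theta) then V, measure only the pooled
    qubit.  Returns a vector of length (m-1)^2 for window=2, stride=1."""
    m = image.m
    if not 0 <= pooling.pooled_qubit < window ** 2:
        raise IndexError(
            f"pooled qubit {pooling.pooled_qubit} out of range for a "
            f"{window}x{window} window"
        )
    circuit = kernel_circuit(kernel)
    grid = _window_grid(m, window, stride)
    out = np.empty(len(grid))
    for k, (r, c) in enumerate(grid):
        patch = image.pixels[r : r + window, c : c + window].ravel()
        state = run_circuit(circuit, encode_patch(patch).state)
        if pooling.v_circuit is not None:
            state = run_circuit(pooling.v_circuit, state)
        out[k] = z_expectation(state, pooling.pooled_qubit)
    return out


def extract_features(
    images: np.ndarray,
    kernel: QuanvKernel,
    pooling: PoolingSpec | None = None,
    window: int = 2,
    stride: int = 1,
) -> np.ndarray:
    """Batch front end: images (batch, m, m) -> feature matrix.

    With a pooling spec each image yields the pooled vector (one value
    per window); without one, the flattened full channel stack.
    """
    rows = []
    for img in np.asarray(images, dtype=float):
        pre = PreprocessedImage(img)
        if pooling is not None:
            rows.append(quantum_pool(pre, kernel, pooling, window, stride))
        else:
            rows.append(flatten_features(quanv_convolve(pre, kernel, window, stride)))
    return np.asarray(rows)


def flatten_features(fm: FeatureMap) -> np.ndarray:
    """Row-major, channel-last flattening (length = positions * channels)."""
    return fm.values.ravel()


def unflatten_features(
    vec: np.ndarray, height: int, width: int, channels: int
) -> FeatureMap:
    """Inverse of :func:`flatten_features` for a known grid shape."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != height * width * channels:
        raise ValueError(
            f"vector of length {vec.size} cannot fill "
            f"{height}x{width}x{channels}"
        )
    return FeatureMap(vec.reshape(height, width, channels))
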