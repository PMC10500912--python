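"""Exact statevector simulation of small parameterized quantum circuits.

The simulator targets the circuits used by quanvolutional feature
extraction: a handful of qubits (typically four, one per pixel of a 2x2
image window), single-qubit rotations whose angles carry the data or the
trainable parameters, and CNOT entanglers.  States are dense complex
vectors of length ``2**n``; expectations are exact (no shot sampling).

Qubit-ordering convention
-------------------------
Qubit 0 is the *leftmost* tensor factor, i.e. its bit occupies the most
significant position of the computational-basis index.  For two qubits
the basis is ordered ``|00>, |01>, |10>, |11>`` and ``|10>`` means qubit
0 in state ``|1>``, qubit 1 in state ``|0>``.  Every routine in this
module (and the dense Kronecker oracle used to cross-check it) follows
this convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ATOL = 1e-10  # unitarity / normalization tolerance, double precision

SINGLE_QUBIT_KINDS = frozenset({"RX", "RY", "RZ", "X", "Y", "Z", "U3"})
GATE_PARAM_COUNT = {
    "RX": 1, "RY": 1, "RZ": 1, "U3": 3,
    "X": 0, "Y": 0, "Z": 0, "CNOT": 0,
}


# ---------------------------------------------------------------------------
# gate matrices
# ---------------------------------------------------------------------------

def rotation_gate(axis: str, theta: float) -> np.ndarray:
    """Single-qubit rotation R_axis(theta) about a Bloch-sphere axis.

    R_x(t) = [[cos t/2, -i sin t/2], [-i sin t/2, cos t/2]]
    R_y(t) = [[cos t/2, -sin t/2], [sin t/2, cos t/2]]
    R_z(t) = diag(e^{-i t/2}, e^{+i t/2})
    """
    if not math.isfinite(theta):
        raise ValueError(f"rotation angle must be finite, got {theta!r}")
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    if axis == "x":
        return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)
    if axis == "y":
        return np.array([[c, -s], [s, c]], dtype=complex)
    if axis == "z":
        return np.array(
            [[np.exp(-0.5j * theta), 0.0], [0.0, np.exp(0.5j * theta)]],
            dtype=complex,
        )
    raise ValueError(f"unknown rotation axis {axis!r}; expected 'x', 'y' or 'z'")


def pauli_gate(kind: str) -> np.ndarray:
    """Pauli X, Y or Z matrix (each an involution: M @ M = I)."""
    if kind == "X":
        return np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
    if kind == "Y":
        return np.array([[0.0, -1j], [1j, 0.0]], dtype=complex)
    if kind == "Z":
        return np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
    raise ValueError(f"unknown Pauli kind {kind!r}; expected 'X', 'Y' or 'Z'")


def u3_gate(theta: float, phi: float, lam: float) -> np.ndarray:
    """Universal single-qubit rotation with Euler angles (theta, phi, lambda).

    U = [[cos t/2,            -e^{i lam} sin t/2       ],
         [e^{i phi} sin t/2,   e^{i (phi+lam)} cos t/2 ]]

    Any single-qubit gate equals this matrix for some angle triple, up to
    a global phase (e.g. X at (pi, 0, pi)).
    """
    for name, a in (("theta", theta), ("phi", phi), ("lambda", lam)):
        if not math.isfinite(a):
            raise ValueError(f"u3 angle {name} must be finite, got {a!r}")
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    return np.array(
        [
            [c, -np.exp(1j * lam) * s],
            [np.exp(1j * phi) * s, np.exp(1j * (phi + lam)) * c],
        ],
        dtype=complex,
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StateVector:
    """Dense amplitude vector of an n-qubit register (unit norm)."""

    num_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if self.num_qubits < 1:
            raise ValueError("num_qubits must be positive")
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).ravel()
        if self.amplitudes.size != 2 ** self.num_qubits:
            raise ValueError(
                f"amplitude vector has length {self.amplitudes.size}, "
                f"expected 2**{self.num_qubits}"
            )
        norm = float(np.sum(np.abs(self.amplitudes) ** 2))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"state norm**2 = {norm}, expected 1")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def copy(self) -> "StateVector":
        return StateVector(self.num_qubits, self.amplitudes.copy())


def ground_state(num_qubits: int) -> StateVector:
    """|0...0> on ``num_qubits`` qubits."""
    amps = np.zeros(2 ** num_qubits, dtype=complex)
    amps[0] = 1.0
    return StateVector(num_qubits, amps)


def basis_state(num_qubits: int, bits: str | int) -> StateVector:
    """Computational basis state, e.g. ``basis_state(2, "10")``.

    With qubit 0 leftmost, the bit string reads qubit by qubit and equals
    the binary expansion of the basis index.
    """
    index = int(bits, 2) if isinstance(bits, str) else int(bits)
    amps = np.zeros(2 ** num_qubits, dtype=complex)
    amps[index] = 1.0
    return StateVector(num_qubits, amps)


@dataclass(frozen=True)
class GateSpec:
    """One gate application: kind, real parameters, target (and control)."""

    kind: str
    params: tuple = ()
    target: int = 0
    control: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in GATE_PARAM_COUNT:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        expected = GATE_PARAM_COUNT[self.kind]
        if len(self.params) != expected:
            raise ValueError(
                f"{self.kind} takes {expected} parameter(s), got {len(self.params)}"
            )
        if any(not math.isfinite(p) for p in self.params):
            raise ValueError(f"{self.kind} parameters must be finite")
        if self.kind == "CNOT":
            if self.control is None:
                raise ValueError("CNOT requires a control qubit")
            if self.control == self.target:
                raise ValueError("CNOT control and target must differ")
        elif self.control is not None:
            raise ValueError(f"{self.kind} takes no control qubit")

    def matrix(self) -> np.ndarray:
        """The 2x2 matrix of a single-qubit gate (CNOT has no 2x2 form)."""
        if self.kind in ("RX", "RY", "RZ"):
            return rotation_gate(self.kind[-1].lower(), self.params[0])
        if self.kind in ("X", "Y", "Z"):
            return pauli_gate(self.kind)
        if self.kind == "U3":
            return u3_gate(*self.params)
        raise ValueError("CNOT is a two-qubit gate; no 2x2 matrix")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "params": list(self.params), "target": self.target}
        if self.control is not None:
            d["control"] = self.control
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateSpec":
        return cls(
            kind=d["kind"],
            params=tuple(d.get("params", ())),
            target=int(d["target"]),
            control=d.get("control"),
        )


@dataclass
class CircuitSpec:
    """An ordered gate program on a fixed-width register, U(w)."""

    num_qubits: int
    gates: list[GateSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.num_qubits < 1:
            raise ValueError("num_qubits must be positive")
        self.gates = list(self.gates)
        for g in self.gates:
            self._check_indices(g)

    def _check_indices(self, g: GateSpec) -> None:
        indices = [g.target] + ([g.control] if g.control is not None else [])
        for q in indices:
            if not 0 <= q < self.num_qubits:
                raise ValueError(
                    f"gate {g.kind} touches qubit {q}, outside register of "
                    f"{self.num_qubits} qubits"
                )

    def append(self, gate: GateSpec) -> None:
        self._check_indices(gate)
        self.gates.append(gate)

    def extend(self, gates: Iterable[GateSpec]) -> None:
        for g in gates:
            self.append(g)

    @property
    def num_parameters(self) -> int:
        return sum(len(g.params) for g in self.gates)

    def to_json(self) -> str:
        return json.dumps(
            {"num_qubits": self.num_qubits, "gates": [g.to_dict() for g in self.gates]}
        )

    @classmethod
    def from_json(cls, document: str) -> "CircuitSpec":
        d = json.loads(document)
        return cls(
            num_qubits=int(d["num_qubits"]),
            gates=[GateSpec.from_dict(g) for g in d["gates"]],
        )


# ---------------------------------------------------------------------------
# state evolution
# ---------------------------------------------------------------------------

def apply_single_qubit_gate(
    state: StateVector, gate: np.ndarray, qubit: int
) -> StateVector:
    """Apply a 2x2 unitary to one qubit by axis-wise tensor contraction.

    Equivalent to multiplying by I (x) ... (x) gate (x) ... (x) I without
    materializing the 2^n x 2^n matrix.
    """
    n = state.num_qubits
    if not 0 <= qubit < n:
        raise IndexError(f"qubit {qubit} out of range for {n}-qubit state")
    gate = np.asarray(gate, dtype=complex)
    if gate.shape != (2, 2):
        raise ValueError(f"expected a 2x2 gate matrix, got shape {gate.shape}")
    tensor = state.amplitudes.reshape((2,) * n)
    # contract the gate into axis `qubit`, then restore the axis order
    tensor = np.moveaxis(np.tensordot(gate, tensor, axes=([1], [qubit])), 0, qubit)
    return StateVector(n, tensor.ravel())


def apply_cnot(state: StateVector, control: int, target: int) -> StateVector:
    """Flip the target bit of every basis state whose control bit is 1."""
    n = state.num_qubits
    if control == target:
        raise ValueError("CNOT control and target must differ")
    for q in (control, target):
        if not 0 <= q < n:
            raise IndexError(f"qubit {q} out of range for {n}-qubit state")
    tensor = state.amplitudes.reshape((2,) * n).copy()
    # slice with control bit = 1 and swap the target axis's two slices
    sel0 = [slice(None)] * n
    sel0[control] = 1
    sub = tensor[tuple(sel0)]
    tensor[tuple(sel0)] = np.flip(sub, axis=target if target < control else target - 1)
    return StateVector(n, tensor.ravel())


def apply_gate(state: StateVector, gate: GateSpec) -> StateVector:
    if gate.kind == "CNOT":
        return apply_cnot(state, gate.control, gate.target)
    return apply_single_qubit_gate(state, gate.matrix(), gate.target)


def run_circuit(
    circuit: CircuitSpec, initial: StateVector | None = None
) -> StateVector:
    """Sequentially apply every gate; default initial state is |0...0>."""
    if initial is None:
        state = ground_state(circuit.num_qubits)
    else:
        if initial.num_qubits != circuit.num_qubits:
            raise ValueError(
                f"circuit is on {circuit.num_qubits} qubits but the state has "
                f"{initial.num_qubits}"
            )
        state = initial.copy()
    for gate in circuit.gates:
        state = apply_gate(state, gate)
    return state


def z_expectation(state: StateVector, qubit: int) -> float:
    """<Z_qubit> = sum over basis states of |amp|^2 * (+1 if bit 0 else -1)."""
    n = state.num_qubits
    if not 0 <= qubit < n:
        raise IndexError(f"qubit {qubit} out of range for {n}-qubit state")
    probs = np.abs(state.amplitudes) ** 2
    index = np.arange(2 ** n)
    bit = (index >> (n - 1 - qubit)) & 1  # qubit 0 is the most significant bit
    # clip roundoff: the expectation of a +/-1 observable cannot leave [-1, 1]
    return float(np.clip(np.sum(probs * (1.0 - 2.0 * bit)), -1.0, 1.0))


def z_expectations(state: StateVector) -> np.ndarray:
    """<Z_k> for every qubit k, as a length-n vector in [-1, 1]."""
    return np.array([z_expectation(state, q) for q in range(state.num_qubits)])


def is_unitary(matrix: np.ndarray, atol: float = ATOL) -> bool:
    matrix = np.asarray(matrix, dtype=complex)
    eye = np.eye(matrix.shape[0])
    return bool(np.max(np.abs(matrix.conj().T @ matrix - eye)) < atol)
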