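"""Independent oracles used by the tests.

These deliberately avoid the package's own fast paths: the circuit
oracle materializes the full 2^n x 2^n unitary by Kronecker products
(qubit 0 leftmost, matching the documented convention) and multiplies
dense matrices; the statistics oracles are direct textbook formulas.
"""

from __future__ import annotations

import numpy as np

I2 = np.eye(2, dtype=complex)
P0 = np.array([[1.0, 0.0], [0.0, 0.0]], dtype=complex)
P1 = np.array([[0.0, 0.0], [0.0, 1.0]], dtype=complex)
X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)


def kron_chain(factors) -> np.ndarray:
    out = np.array([[1.0]], dtype=complex)
    for f in factors:
        out = np.kron(out, f)
    return out


def dense_single(num_qubits: int, gate: np.ndarray, qubit: int) -> np.ndarray:
    """I (x) ... (x) gate (x) ... (x) I with qubit 0 leftmost."""
    factors = [I2] * num_qubits
    factors[qubit] = gate
    return kron_chain(factors)


def dense_cnot(num_qubits: int, control: int, target: int) -> np.ndarray:
    """P0_c (x) I + P1_c (x) X_t as a full Kronecker sum."""
    id_factors = [I2] * num_qubits
    id_factors[control] = P0
    flip_factors = [I2] * num_qubits
    flip_factors[control] = P1
    flip_factors[target] = X
    return kron_chain(id_factors) + kron_chain(flip_factors)


def dense_circuit_unitary(circuit) -> np.ndarray:
    """Full-matrix product of every gate in order (later gates on the left)."""
    n = circuit.num_qubits
    unitary = np.eye(2 ** n, dtype=complex)
    for gate in circuit.gates:
        if gate.kind == "CNOT":
            full = dense_cnot(n, gate.control, gate.target)
        else:
            full = dense_single(n, gate.matrix(), gate.target)
        unitary = full @ unitary
    return unitary


def random_circuit(rng: np.random.Generator, num_qubits: int, num_gates: int):
    """A random circuit drawing from the full supported gate set."""
    from quanvnet.qsim import CircuitSpec, GateSpec

    kinds = ["RX", "RY", "RZ", "X", "Y", "Z", "U3", "CNOT"]
    circuit = CircuitSpec(num_qubits=num_qubits)
    for _ in range(num_gates):
        kind = kinds[rng.integers(len(kinds))]
        if kind == "CNOT" and num_qubits < 2:
            kind = "X"
        target = int(rng.integers(num_qubits))
        if kind == "CNOT":
            control = int(rng.integers(num_qubits - 1))
            if control >= target:
                control += 1
            circuit.append(GateSpec("CNOT", (), target=target, control=control))
        else:
            n_params = {"RX": 1, "RY": 1, "RZ": 1, "U3": 3}.get(kind, 0)
            params = tuple(rng.uniform(-2 * np.pi, 2 * np.pi, size=n_params))
            circuit.append(GateSpec(kind, params, target=target))
    return circuit


def textbook_paired_t(a: np.ndarray, b: np.ndarray) -> float:
    """Paired t computed from scratch with explicit sums."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / (var ** 0.5 / n ** 0.5)


def textbook_cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sa2 = sum((x - a.mean()) ** 2 for x in a) / (na - 1)
    sb2 = sum((x - b.mean()) ** 2 for x in b) / (nb - 1)
    pooled = (((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)) ** 0.5
    return (a.mean() - b.mean()) / pooled
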