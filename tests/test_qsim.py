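"""Gate algebra, state evolution, and agreement with the dense oracle."""

import math

import numpy as np
import pytest

from _oracles import dense_circuit_unitary, random_circuit
from quanvnet.qsim import (
    CircuitSpec,
    GateSpec,
    StateVector,
    apply_cnot,
    apply_gate,
    apply_single_qubit_gate,
    basis_state,
    ground_state,
    is_unitary,
    pauli_gate,
    rotation_gate,
    run_circuit,
    u3_gate,
    z_expectation,
)

ATOL = 1e-10


class TestGateMatrices:
    def test_zero_rotation_is_identity(self):
        for axis in "xyz":
            np.testing.assert_allclose(rotation_gate(axis, 0.0), np.eye(2),
                                       atol=ATOL)

    def test_rx_pi(self):
        expected = np.array([[0.0, -1j], [-1j, 0.0]])
        np.testing.assert_allclose(rotation_gate("x", math.pi), expected,
                                   atol=ATOL)

    def test_rz_pi_over_3_diagonal_phases(self):
        gate = rotation_gate("z", math.pi / 3)
        np.testing.assert_allclose(
            np.diag(gate),
            [np.exp(-1j * math.pi / 6), np.exp(1j * math.pi / 6)],
            atol=ATOL,
        )
        np.testing.assert_allclose(np.abs(np.diag(gate)), [1.0, 1.0], atol=ATOL)

    @pytest.mark.parametrize(
        "kind,state_in,expected",
        [
            ("X", [1, 0], [0, 1]),        # X|0> = |1>
            ("Y", [1, 0], [0, 1j]),       # Y|0> = i|1>
            ("Z", [0, 1], [0, -1]),       # Z flips the phase of |1>
        ],
    )
    def test_pauli_action_on_basis_states(self, kind, state_in, expected):
        out = pauli_gate(kind) @ np.array(state_in, dtype=complex)
        np.testing.assert_allclose(out, expected, atol=ATOL)

    @pytest.mark.parametrize("kind", ["X", "Y", "Z"])
    def test_pauli_involution(self, kind):
        m = pauli_gate(kind)
        np.testing.assert_allclose(m @ m, np.eye(2), atol=ATOL)

    def test_u3_zero_angles_is_identity(self):
        np.testing.assert_allclose(u3_gate(0.0, 0.0, 0.0), np.eye(2), atol=ATOL)

    def test_u3_pi_0_pi_equals_pauli_x(self):
        np.testing.assert_allclose(u3_gate(math.pi, 0.0, math.pi),
                                   pauli_gate("X"), atol=ATOL)

    def test_all_gates_unitary_at_random_angles(self, rng):
        for _ in range(50):
            theta, phi, lam = rng.uniform(-7, 7, size=3)
            for gate in (
                rotation_gate("x", theta),
                rotation_gate("y", theta),
                rotation_gate("z", theta),
                u3_gate(theta, phi, lam),
            ):
                assert is_unitary(gate)

    @pytest.mark.parametrize("bad", [math.nan, math.inf])
    def test_nonfinite_angles_rejected(self, bad):
        with pytest.raises(ValueError):
            rotation_gate("y", bad)
        with pytest.raises(ValueError):
            u3_gate(0.0, bad, 0.0)

    def test_unknown_kinds_rejected(self):
        with pytest.raises(ValueError):
            pauli_gate("H")
        with pytest.raises(ValueError):
            rotation_gate("w", 0.1)


class TestStateEvolution:
    def test_x_on_qubit0_of_00(self):
        out = apply_single_qubit_gate(ground_state(2), pauli_gate("X"), 0)
        np.testing.assert_allclose(out.amplitudes,
                                   basis_state(2, "10").amplitudes, atol=ATOL)

    def test_identity_leaves_state(self, rng):
        state = run_circuit(random_circuit(rng, 3, 6))
        out = apply_single_qubit_gate(state, np.eye(2), 1)
        np.testing.assert_allclose(out.amplitudes, state.amplitudes, atol=ATOL)

    def test_norm_preserved_by_random_gates(self, rng):
        state = ground_state(3)
        for _ in range(20):
            gate = u3_gate(*rng.uniform(-7, 7, size=3))
            state = apply_single_qubit_gate(state, gate,
                                            int(rng.integers(3)))
            assert abs(state.norm - 1.0) < ATOL

    def test_qubit_out_of_range(self):
        with pytest.raises(IndexError):
            apply_single_qubit_gate(ground_state(2), np.eye(2), 2)

    def test_cnot_flips_target_when_control_set(self):
        out = apply_cnot(basis_state(2, "10"), control=0, target=1)
        np.testing.assert_allclose(out.amplitudes,
                                   basis_state(2, "11").amplitudes, atol=ATOL)

    def test_cnot_identity_when_control_clear(self):
        out = apply_cnot(ground_state(2), control=0, target=1)
        np.testing.assert_allclose(out.amplitudes,
                                   ground_state(2).amplitudes, atol=ATOL)

    def test_cnot_entangles_superposition(self):
        plus0 = StateVector(2, np.array([1, 0, 1, 0]) / math.sqrt(2))
        out = apply_cnot(plus0, control=0, target=1)
        bell = np.array([1, 0, 0, 1]) / math.sqrt(2)
        np.testing.assert_allclose(out.amplitudes, bell, atol=ATOL)

    def test_cnot_control_equals_target(self):
        with pytest.raises(ValueError):
            apply_cnot(ground_state(2), 1, 1)

    @pytest.mark.parametrize("kind", ["X", "Y", "Z"])
    def test_involution_gates_twice_restore_state(self, kind, rng):
        state = run_circuit(random_circuit(rng, 3, 5))
        spec = GateSpec(kind, (), target=1)
        out = apply_gate(apply_gate(state, spec), spec)
        np.testing.assert_allclose(out.amplitudes, state.amplitudes, atol=ATOL)

    def test_cnot_twice_restores_state(self, rng):
        state = run_circuit(random_circuit(rng, 3, 5))
        out = apply_cnot(apply_cnot(state, 2, 0), 2, 0)
        np.testing.assert_allclose(out.amplitudes, state.amplitudes, atol=ATOL)


class TestZExpectation:
    def test_basis_states_give_plus_minus_one(self):
        assert z_expectation(ground_state(1), 0) == 1.0
        assert z_expectation(basis_state(1, "1"), 0) == -1.0
        assert z_expectation(basis_state(3, "010"), 1) == -1.0

    def test_ry_half_pi_gives_zero(self):
        state = run_circuit(
            CircuitSpec(1, [GateSpec("RY", (math.pi / 2,), target=0)])
        )
        assert abs(z_expectation(state, 0)) < ATOL

    def test_closed_form_cos_theta(self, rng):
        for theta in rng.uniform(0, 2 * math.pi, size=10):
            state = run_circuit(CircuitSpec(1, [GateSpec("RY", (theta,), 0)]))
            assert abs(z_expectation(state, 0) - math.cos(theta)) < ATOL

    def test_bounded_on_random_states(self, rng):
        for _ in range(20):
            state = run_circuit(random_circuit(rng, 3, 8))
            for q in range(3):
                assert -1.0 <= z_expectation(state, q) <= 1.0

    def test_index_error(self):
        with pytest.raises(IndexError):
            z_expectation(ground_state(2), 5)


class TestRunCircuit:
    def test_empty_circuit_is_identity(self, rng):
        init = run_circuit(random_circuit(rng, 2, 4))
        out = run_circuit(CircuitSpec(2), init)
        np.testing.assert_allclose(out.amplitudes, init.amplitudes, atol=ATOL)

    def test_default_initial_state_is_ground(self):
        out = run_circuit(CircuitSpec(3))
        np.testing.assert_allclose(out.amplitudes,
                                   ground_state(3).amplitudes, atol=ATOL)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            run_circuit(CircuitSpec(2), ground_state(3))

    def test_matches_dense_oracle_on_random_circuits(self):
        """Tensor-contraction engine vs full Kronecker-product matrices."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(1, 4))
            circuit = random_circuit(rng, n, int(rng.integers(1, 12)))
            engine = run_circuit(circuit).amplitudes
            oracle = dense_circuit_unitary(circuit) @ ground_state(n).amplitudes
            np.testing.assert_allclose(engine, oracle, atol=ATOL)

    def test_four_qubit_kernel_output_normalized(self, rng):
        circuit = random_circuit(rng, 4, 16)
        assert abs(run_circuit(circuit).norm - 1.0) < ATOL


class TestSerialization:
    def test_circuit_json_round_trip(self, rng):
        circuit = random_circuit(rng, 3, 10)
        restored = CircuitSpec.from_json(circuit.to_json())
        assert restored.num_qubits == circuit.num_qubits
        assert restored.gates == circuit.gates

    def test_gate_validation(self):
        with pytest.raises(ValueError):
            GateSpec("RY", (), target=0)  # missing angle
        with pytest.raises(ValueError):
            GateSpec("X", (0.3,), target=0)  # spurious parameter
        with pytest.raises(ValueError):
            GateSpec("CNOT", (), target=0)  # missing control
        with pytest.raises(ValueError):
            CircuitSpec(2, [GateSpec("X", (), target=5)])  # bad index
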