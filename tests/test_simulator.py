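"""Density-matrix evolution, depolarizing noise and shot sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtanimoto import (
    DomainError,
    Gate,
    NoiseSpec,
    PauliObservable,
    angle_from_similarity,
    apply_gate,
    build_circuit,
    depolarize,
    exact_expectation,
    ideal_state,
    run_circuit,
    sample_counts,
)
from qtanimoto.simulator import initial_state, validate_density_matrix

from conftest import oracle_noisy_ghz, oracle_pauli


def physical(rho):
    assert np.allclose(rho, rho.conj().T, atol=1e-10)
    assert np.trace(rho).real == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.eigvalsh(rho).min() >= -1e-10


class TestApplyGate:
    def test_identity_rotation_leaves_state(self):
        rho = initial_state()
        assert np.allclose(apply_gate(rho, Gate("ry", (0.0,), (0,))), rho)

    def test_cnot_is_an_involution(self):
        rho = initial_state()
        rho = apply_gate(rho, Gate("ry", (1.1,), (0,)))
        g = Gate("cx", (), (0, 1))
        assert np.allclose(apply_gate(apply_gate(rho, g), g), rho, atol=1e-12)

    def test_circuit_prepares_ghz_state(self):
        """RY(π/2) + two CNOTs on |000⟩ gives the balanced GHZ density matrix."""
        rho = initial_state()
        for g in (Gate("ry", (np.pi / 2,), (0,)), Gate("cx", (), (0, 1)),
                  Gate("cx", (), (0, 2))):
            rho = apply_gate(rho, g)
        amps = np.array(ideal_state(angle_from_similarity(0.5)).amplitudes)
        assert np.allclose(rho, np.outer(amps, amps), atol=1e-12)
        physical(rho)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError, match="unknown gate"):
            apply_gate(initial_state(), Gate("toffoli", (), (0, 1, 2)))


class TestDepolarize:
    def test_p_zero_is_identity(self):
        rho = oracle_noisy_ghz(0.3, 0.0)
        assert np.allclose(depolarize(rho, (0, 1), 0.0), rho)

    def test_full_depolarization_gives_maximally_mixed(self):
        rho = oracle_noisy_ghz(0.7, 0.0)
        out = depolarize(rho, (0, 1, 2), 1.0)
        assert np.allclose(out, np.eye(8) / 8, atol=1e-12)

    def test_single_qubit_z_decay(self):
        """⟨Z⟩ on a depolarized |0⟩ qubit shrinks to 1−p (closed form)."""
        for p in (0.0, 0.2, 0.77):
            rho = depolarize(initial_state(), (1,), p)
            z = exact_expectation(rho, PauliObservable("IZI")).value
            assert z == pytest.approx(1 - p, abs=1e-12)

    def test_agrees_with_pauli_twirl_oracle(self):
        """Partial-trace form matches the 16-Pauli Kraus twirl exactly."""
        rng = np.random.default_rng(5)
        m = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        rho = m @ m.conj().T
        rho /= np.trace(rho)
        from conftest import oracle_depolarize

        for qubits in ((0,), (1, 2), (0, 2), (0, 1, 2)):
            for p in (0.1, 0.5, 0.95):
                assert np.allclose(
                    depolarize(rho, qubits, p),
                    oracle_depolarize(rho, qubits, p),
                    atol=1e-12,
                )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DomainError):
            depolarize(initial_state(), (0,), 1.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_preserves_physicality(self, t, p):
        rho = oracle_noisy_ghz(t, 0.0)
        physical(depolarize(rho, (0, 1), p))


class TestRunCircuit:
    def test_noiseless_t_one_concentrates_on_000(self):
        circ = build_circuit(angle_from_similarity(1.0))
        _, counts = run_circuit(circ, mode="shots", shots=1000, seed=1)
        assert counts.counts == {"000": 1000}

    def test_noiseless_support_is_000_and_111(self):
        circ = build_circuit(angle_from_similarity(0.5))
        rho, _ = run_circuit(circ)
        diag = np.diag(rho).real
        assert diag[0] == pytest.approx(0.5, abs=1e-12)
        assert diag[7] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(diag[1:7], 0.0, atol=1e-12)

    @pytest.mark.parametrize("arity", ["two_qubit_on_cnot", "three_qubit_global"])
    def test_matches_brute_force_matrix_oracle(self, arity):
        for t in (0.0, 0.035, 0.3, 0.5, 1.0):
            for p in (0.0, 0.01, 0.1, 0.4):
                circ = build_circuit(angle_from_similarity(t))
                noise = NoiseSpec(p=p, arity=arity)
                rho, _ = run_circuit(circ, noise=noise)
                assert np.allclose(rho, oracle_noisy_ghz(t, p, arity), atol=1e-10)

    def test_zzz_decay_closed_form(self):
        """Default channel: exact ⟨ZZZ⟩ = (1−p)²(2t−1) over a (t, p) grid."""
        for t in np.linspace(0, 1, 9):
            for p in (0.0, 0.001, 0.01, 0.05, 0.1, 0.2):
                circ = build_circuit(angle_from_similarity(float(t)))
                rho, _ = run_circuit(circ, noise=NoiseSpec(p=p))
                zzz = exact_expectation(rho, PauliObservable("ZZZ")).value
                assert zzz == pytest.approx((1 - p) ** 2 * (2 * t - 1), abs=1e-10)

    def test_x_basis_rotation_applied_before_sampling(self):
        # after H on every qubit the GHZ state has uniform single-qubit stats
        circ = build_circuit(angle_from_similarity(0.5), measure_basis="XXX")
        rho, counts = run_circuit(circ, mode="shots", shots=4000, seed=9)
        assert counts.basis == "XXX"
        # ⟨XXX⟩ of the balanced GHZ state: (√T·√(1−T))·2 = 1 at T=0.5... measured
        # via the rotated register's ZZZ parity
        parity = sum(
            ((-1) ** label.count("1")) * c for label, c in counts.counts.items()
        ) / counts.shots
        assert parity == pytest.approx(1.0, abs=1e-9)


class TestSampleCounts:
    def test_pure_state_all_mass_on_000(self):
        assert sample_counts(initial_state(), 500, seed=3).counts == {"000": 500}

    def test_seed_reproducibility(self):
        rho = oracle_noisy_ghz(0.3, 0.05)
        c1 = sample_counts(rho, 1000, seed=42)
        c2 = sample_counts(rho, 1000, seed=42)
        assert c1.counts == c2.counts

    def test_maximally_mixed_is_uniform_within_4_sigma(self):
        shots = 80_000
        counts = sample_counts(np.eye(8, dtype=complex) / 8, shots, seed=11)
        sigma = np.sqrt(shots * (1 / 8) * (7 / 8))
        for label in [format(i, "03b") for i in range(8)]:
            assert abs(counts.counts.get(label, 0) - shots / 8) < 4 * sigma

    def test_counts_sum_to_shots(self):
        rho = oracle_noisy_ghz(0.5, 0.2)
        counts = sample_counts(rho, 1234, seed=0)
        assert sum(counts.counts.values()) == 1234

    def test_noiseless_distribution_chi_square(self):
        """10⁴-shot noiseless sampling is consistent with P(000)=t, P(111)=1−t."""
        from scipy import stats

        t, shots = 0.35, 10_000
        circ = build_circuit(angle_from_similarity(t))
        pvals = []
        for seed in range(10):
            _, counts = run_circuit(circ, mode="shots", shots=shots, seed=seed)
            observed = [counts.counts.get("000", 0), counts.counts.get("111", 0)]
            assert sum(observed) == shots  # no off-support outcomes
            _, pv = stats.chisquare(observed, [t * shots, (1 - t) * shots])
            pvals.append(pv)
        assert max(pvals) > 0.01  # not every seed rejected at the 1% level
        assert np.mean([p > 0.01 for p in pvals]) >= 0.8


class TestValidateDensityMatrix:
    def test_clips_eigenvalue_dust(self):
        rho = initial_state()
        rho[1, 1] = -5e-11  # numerically negative but within tolerance
        rho[0, 0] = 1 - rho[1, 1].real
        out = validate_density_matrix(rho)
        assert np.linalg.eigvalsh(out).min() >= 0

    def test_rejects_real_negativity(self):
        from qtanimoto import NumericalStateError

        rho = initial_state()
        rho[1, 1] = -0.1
        rho[0, 0] = 1.1
        with pytest.raises(NumericalStateError):
            validate_density_matrix(rho)
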