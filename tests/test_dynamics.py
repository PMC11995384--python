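"""Vectorization, commutator superoperators, relaxation and rate models."""

import warnings

import numpy as np
import pytest
import scipy.linalg

from treprsim.dynamics import (
    RateSpec,
    devectorize,
    hamiltonian_superoperator,
    liouville_index,
    rate_superoperator,
    t1t2_superoperator,
    validate_rates,
    vectorize,
)

RNG = np.random.default_rng(21)


def test_vectorize_column_stacking_convention():
    M = np.array([[1.0, 2.0], [3.0, 4.0]])
    np.testing.assert_array_equal(vectorize(M), [1.0, 3.0, 2.0, 4.0])


def test_vectorize_round_trip_and_frobenius():
    A = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
    B = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
    np.testing.assert_array_equal(devectorize(vectorize(A)), A)
    assert np.vdot(vectorize(A), vectorize(B)) == pytest.approx(
        np.trace(A.conj().T @ B)
    )


def test_hamiltonian_superoperator_diagonal_case():
    H = np.diag([3.0, 1.0, -2.0])
    L = np.asarray(hamiltonian_superoperator(H))
    n = 3
    for i in range(n):
        for j in range(n):
            idx = liouville_index(i, j, n)
            assert L[idx, idx] == pytest.approx(H[i, i] - H[j, j])
    assert np.abs(L - np.diag(np.diag(L))).max() == 0.0


def test_hamiltonian_superoperator_commutator_identity():
    A = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
    H = A + A.conj().T
    rho = RNG.normal(size=(4, 4)) + 1j * RNG.normal(size=(4, 4))
    L = np.asarray(hamiltonian_superoperator(H))
    np.testing.assert_allclose(
        devectorize(L @ vectorize(rho)), H @ rho - rho @ H, atol=1e-10
    )


def test_hamiltonian_superoperator_eigenvalues_are_gaps():
    A = RNG.normal(size=(3, 3)) + 1j * RNG.normal(size=(3, 3))
    H = A + A.conj().T
    ev_h = np.linalg.eigvalsh(H)
    gaps = sorted((ev_h[i] - ev_h[j]) for i in range(3) for j in range(3))
    ev_l = sorted(np.linalg.eigvals(np.asarray(hamiltonian_superoperator(H))).real)
    np.testing.assert_allclose(ev_l, gaps, atol=1e-8)


def test_t1_population_relaxation_closed_form():
    T1, n = 2.0, 2
    R = np.asarray(t1t2_superoperator(T1, 1.0, n))
    v = vectorize(np.diag([1.0, 0.0]).astype(complex))
    for t in (0.5, 2.0, 10.0):
        rho_t = devectorize(scipy.linalg.expm(R * t) @ v)
        expected = 0.5 + 0.5 * np.exp(-t / T1)
        assert rho_t[0, 0].real == pytest.approx(expected, abs=1e-10)
        assert np.trace(rho_t).real == pytest.approx(1.0, abs=1e-10)


def test_t2_coherence_decay_e_inverse():
    T2 = 0.7
    R = np.asarray(t1t2_superoperator(5.0, T2, 2))
    rho0 = np.array([[0.5, 0.3], [0.3, 0.5]], dtype=complex)
    rho_t = devectorize(scipy.linalg.expm(R * T2) @ vectorize(rho0))
    assert abs(rho_t[0, 1]) == pytest.approx(0.3 * np.exp(-1.0), abs=1e-10)


def test_t1t2_trace_conserved_under_full_superoperator():
    R = np.asarray(t1t2_superoperator(1.3, 0.4, 3))
    A = RNG.normal(size=(3, 3)) + 1j * RNG.normal(size=(3, 3))
    rho0 = A @ A.conj().T
    for t in (0.1, 1.0, 7.0):
        rho_t = devectorize(scipy.linalg.expm(R * t) @ vectorize(rho0))
        assert np.trace(rho_t).real == pytest.approx(np.trace(rho0).real, abs=1e-10)


def test_t1t2_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        t1t2_superoperator(-1.0, 1.0, 2)
    with pytest.raises(ValueError):
        t1t2_superoperator(1.0, 0.0, 2)


def test_rate_superoperator_two_state_transfer():
    r = 0.8
    spec = RateSpec(entries=[(0, 0, 1, 1, r), (0, 0, 0, 0, -r)])
    R = np.asarray(rate_superoperator(spec, 2))
    v = vectorize(np.diag([1.0, 0.0]).astype(complex))
    for t in (0.3, 1.0, 4.0):
        rho_t = devectorize(scipy.linalg.expm(R * t) @ v)
        assert rho_t[0, 0].real == pytest.approx(np.exp(-r * t), abs=1e-10)
        assert np.trace(rho_t).real == pytest.approx(1.0, abs=1e-12)


def test_empty_rate_spec_zero_superoperator():
    assert np.abs(np.asarray(rate_superoperator(RateSpec(), 3))).max() == 0.0


def test_cascade_matches_sequential_kinetics():
    # A -> B -> ground, closed form for a two-step cascade
    ka, kb = 2.0, 0.5
    spec = RateSpec(
        entries=[
            (0, 0, 1, 1, ka),
            (0, 0, 0, 0, -ka),
            (1, 1, 1, 1, -kb),
        ]
    )
    R = np.asarray(rate_superoperator(spec, 2))
    v = vectorize(np.diag([1.0, 0.0]).astype(complex))
    for t in (0.2, 1.0, 3.0):
        rho_t = devectorize(scipy.linalg.expm(R * t) @ v)
        pa = np.exp(-ka * t)
        pb = ka / (kb - ka) * (np.exp(-ka * t) - np.exp(-kb * t))
        assert rho_t[0, 0].real == pytest.approx(pa, abs=1e-8)
        assert rho_t[1, 1].real == pytest.approx(pb, abs=1e-8)


def test_pop_rate_matrix_matches_classical_kinetics():
    # population shorthand vs matrix exponential of the n×n rate matrix
    K = np.array([[0.0, 0.3, 0.0], [1.2, 0.0, 0.4], [0.0, 0.7, 0.0]])
    n = 3
    R = np.asarray(rate_superoperator(RateSpec(pop_rates=K), n))
    K_full = K - np.diag(K.sum(axis=0))  # auto-filled conserving diagonal
    p0 = np.array([1.0, 0.0, 0.0])
    for t in (0.1, 1.0, 5.0):
        rho_t = devectorize(
            scipy.linalg.expm(R * t) @ vectorize(np.diag(p0).astype(complex))
        )
        p_direct = scipy.linalg.expm(K_full * t) @ p0
        np.testing.assert_allclose(np.diag(rho_t).real, p_direct, atol=1e-10)
        assert np.trace(rho_t).real == pytest.approx(1.0, abs=1e-10)


def test_validate_rates_classifications():
    conserving = RateSpec(entries=[(0, 0, 1, 1, 0.5), (0, 0, 0, 0, -0.5)])
    assert validate_rates(conserving, 2) == "conserving"
    decaying = RateSpec(entries=[(0, 0, 0, 0, -0.5)])
    assert validate_rates(decaying, 2) == "decaying"
    assert validate_rates(RateSpec(), 2) == "conserving"
    gaining = RateSpec(entries=[(0, 0, 1, 1, 0.5)])
    with pytest.warns(UserWarning, match="gains population"):
        assert validate_rates(gaining, 2) == "gaining"


def test_coherence_pumping_warns():
    with pytest.warns(UserWarning, match="coherence"):
        rate_superoperator(RateSpec(entries=[(0, 0, 0, 1, 0.5)]), 2)


def test_coherence_damping_does_not_warn():
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        rate_superoperator(RateSpec(entries=[(0, 1, 0, 1, -0.5)]), 2)


def test_rate_spec_validation():
    with pytest.raises(ValueError, match="T1"):
        RateSpec(T1=-1.0, T2=1.0)
    with pytest.raises(ValueError, match="together"):
        RateSpec(T1=1.0)
    with pytest.raises(ValueError, match="basis"):
        RateSpec(basis="diabatic")
    with pytest.raises(ValueError, match="out of bounds"):
        rate_superoperator(RateSpec(entries=[(0, 0, 5, 5, 1.0)]), 2)


def test_unitary_channel_preserves_invariants_over_many_steps():
    A = RNG.normal(size=(3, 3)) + 1j * RNG.normal(size=(3, 3))
    H = A + A.conj().T
    L = np.asarray(hamiltonian_superoperator(H))
    B = RNG.normal(size=(3, 3)) + 1j * RNG.normal(size=(3, 3))
    rho0 = B @ B.conj().T
    rho0 /= np.trace(rho0).real
    step = scipy.linalg.expm(-1j * L * 1e-3)
    v = vectorize(rho0)
    for _ in range(1000):
        v = step @ v
    rho = devectorize(v)
    assert np.trace(rho).real == pytest.approx(1.0, abs=1e-9)
    assert np.abs(rho - rho.conj().T).max() < 1e-9
    np.testing.assert_allclose(
        np.linalg.eigvalsh(rho), np.linalg.eigvalsh(rho0), atol=1e-9
    )
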