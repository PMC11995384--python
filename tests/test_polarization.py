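"""Initial density matrices for the polarization presets."""

import numpy as np
import pytest

from treprsim.polarization import (
    InitialState,
    build_initial_density,
    density_from_eigenpopulations,
    density_pair,
    density_tdp,
    density_triplet_zerofield,
)
from treprsim.spinsystem import SpinSystemSpec, TensorSpec, build_static_hamiltonian


def doub():
    return SpinSystemSpec(kind="doub", g=[TensorSpec(2.0)])


def rp():
    return SpinSystemSpec(
        kind="rp",
        g=[TensorSpec(2.0030), TensorSpec(2.0047)],
        J=1.0,
        dipolar=TensorSpec((1.0, 1.0, -2.0)),
    )


def trip():
    return SpinSystemSpec(kind="trip", g=[TensorSpec(2.002)], D=45.0, E=9.0)


def tdp():
    return SpinSystemSpec(
        kind="tdp",
        g=[TensorSpec(2.003), TensorSpec(2.005)],
        J=-12.0,
        D=20.0,
        E=0.0,
        dipolar=TensorSpec((1.0, 1.0, -2.0)),
    )


def test_eigen_uniform_is_identity():
    H = build_static_hamiltonian(trip(), 347.0, (0.4, 0.8))
    rho = density_from_eigenpopulations([1.0, 1.0, 1.0], H)
    np.testing.assert_allclose(rho, np.eye(3), atol=1e-12)


def test_eigen_doublet_ground_projector():
    H = np.asarray(build_static_hamiltonian(doub(), 348.3))
    rho = density_from_eigenpopulations([1.0, 0.0], H)
    # lower level is |β⟩ (second basis state) for positive g and field
    np.testing.assert_allclose(rho, np.diag([0.0, 1.0]), atol=1e-12)


def test_eigen_rp_matches_direct_assignment():
    # diagonal rp Hamiltonian: eigen populations land on the ST states
    spec = SpinSystemSpec(
        kind="rp",
        g=[TensorSpec(2.0), TensorSpec(2.0)],
        J=5.0,
        dipolar=TensorSpec((0.0, 0.0, 0.0)),
    )
    H = np.asarray(build_static_hamiltonian(spec, 348.3))
    order = np.argsort(np.diag(H).real)  # working index of each ascending state
    p_asc = [0.1, 0.2, 0.3, 0.4]
    rho = density_from_eigenpopulations(p_asc, H)
    expected = np.zeros(4)
    expected[order] = p_asc
    np.testing.assert_allclose(np.diag(rho).real, expected, atol=1e-12)
    assert np.abs(rho - np.diag(np.diag(rho))).max() < 1e-12


def test_eigen_population_count_mismatch():
    H = build_static_hamiltonian(doub(), 348.3)
    with pytest.raises(ValueError, match="populations"):
        density_from_eigenpopulations([1.0, 0.0, 0.0], H)


def test_zf_equal_populations_isotropic():
    rho = density_triplet_zerofield([1 / 3] * 3, trip(), 347.0, (0.9, 1.3))
    np.testing.assert_allclose(rho, np.eye(3) / 3, atol=1e-10)


def test_zf_z_state_maps_to_t0_at_high_field():
    # D>0, E=0, canonical orientation: |TZ⟩ = |T0⟩; pZ is the lowest-energy ZF state
    spec = SpinSystemSpec(kind="trip", g=[TensorSpec(2.0)], D=1200.0, E=0.0)
    rho = density_triplet_zerofield([1.0, 0.0, 0.0], spec, 348.3, (0.0, 0.0))
    np.testing.assert_allclose(np.diag(rho).real, [0.0, 1.0, 0.0], atol=1e-6)


def test_zf_trace_preserved():
    pops = [0.2, 0.5, 0.3]
    rho = density_triplet_zerofield(pops, trip(), 347.0, (0.7, 0.5))
    assert np.trace(rho).real == pytest.approx(sum(pops), abs=1e-12)
    assert np.abs(rho - np.diag(np.diag(rho))).max() == 0.0  # coherences dropped


def test_pair_singlet_density():
    rho = density_pair("singlet", None, rp(), 347.6)
    np.testing.assert_allclose(rho, np.diag([0.0, 0.0, 0.0, 1.0]), atol=1e-14)


def test_pair_triplet_pnm():
    rho = density_pair("triplet-pnm", [1.0, 1.0, 1.0], rp(), 347.6)
    np.testing.assert_allclose(rho, np.diag([1.0, 1.0, 1.0, 0.0]), atol=1e-14)


def test_pair_initial_sy_expectation_zero():
    from treprsim.spinsystem import total_spin_ops

    rho = density_pair("singlet", None, rp(), 347.6)
    _, sy, _ = total_spin_ops(rp())
    assert abs(np.trace(sy @ rho)) < 1e-14


def test_pair_mode_kind_mismatch():
    with pytest.raises(ValueError, match="rp"):
        density_pair("singlet", None, trip(), 347.6)


def test_tdp_uniform_kron():
    rho = density_tdp("triplet-pnm", [1 / 3] * 3, [0.5, 0.5], tdp(), 347.6)
    assert rho.shape == (6, 6)
    np.testing.assert_allclose(rho, np.eye(6) / 6, atol=1e-14)


def test_tdp_single_product_state():
    rho = density_tdp("triplet-pnm", [1.0, 0.0, 0.0], [1.0, 0.0], tdp(), 347.6)
    np.testing.assert_allclose(rho, np.diag([1.0, 0, 0, 0, 0, 0]), atol=1e-14)


def test_tdp_trace_multiplicative():
    rng = np.random.default_rng(11)
    for _ in range(5):
        pt = rng.uniform(0, 1, 3)
        pd = rng.uniform(0, 1, 2)
        rho = density_tdp("triplet-pnm", pt, pd, tdp(), 347.6)
        direct = np.kron(np.diag(pt), np.diag(pd))  # Kronecker oracle
        np.testing.assert_allclose(rho, direct, atol=1e-14)
        assert np.trace(rho).real == pytest.approx(pt.sum() * pd.sum())


@pytest.mark.parametrize(
    "spec,state",
    [
        (doub(), InitialState("eigen", populations=[1.0, 0.0])),
        (trip(), InitialState("zf", triplet=[0.0, 0.5, 0.5])),
        (rp(), InitialState("singlet")),
        (rp(), InitialState("triplet-zf", triplet=[0.3, 0.3, 0.4])),
        (
            tdp(),
            InitialState(
                "triplet-pnm", triplet=[0.6, 0.3, 0.1], doublet=[0.5, 0.5]
            ),
        ),
    ],
    ids=["doub-eigen", "trip-zf", "rp-singlet", "rp-zf", "tdp-pnm"],
)
def test_preset_densities_physical(spec, state):
    """Presets give Hermitian, PSD, unit-trace, working-basis-diagonal ρ0."""
    rho = np.asarray(build_initial_density(state, spec, 347.3, (0.6, 1.0)))
    np.testing.assert_allclose(rho, rho.conj().T, atol=1e-12)
    assert np.linalg.eigvalsh(rho).min() >= -1e-10
    assert np.trace(rho).real == pytest.approx(1.0, abs=1e-10)
    if state.mode != "eigen":
        assert np.abs(rho - np.diag(np.diag(rho))).max() < 1e-12


def test_raw_normalization_preserves_totals():
    state = InitialState("triplet-pnm", triplet=[2.0, 1.0, 1.0], normalize="raw")
    rho = np.asarray(build_initial_density(state, rp(), 347.6))
    assert np.trace(rho).real == pytest.approx(4.0)


def test_custom_mode_accepts_coherences():
    m = np.array([[0.5, 0.2], [0.2, 0.5]])
    state = InitialState("custom", custom_matrix=m)
    rho = np.asarray(build_initial_density(state, doub(), 348.3))
    assert abs(rho[0, 1] - 0.2) < 1e-12


def test_population_negativity_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        InitialState("zf", triplet=[-0.1, 0.5, 0.6])


def test_custom_non_psd_rejected():
    m = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
    with pytest.raises(ValueError, match="semidefinite"):
        build_initial_density(InitialState("custom", custom_matrix=m), doub(), 348.3)
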