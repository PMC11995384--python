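"""Secular Hamiltonian construction for the four spin systems."""

import numpy as np
import pytest

from treprsim.constants import MHZ_TO_ANGULAR, field_for_frequency, zeeman_angular
from treprsim.spinops import spin_matrices
from treprsim.spinsystem import (
    ExperimentSpec,
    SpinSystemSpec,
    TensorSpec,
    allowed_transitions,
    build_static_hamiltonian,
    energy_levels,
    microwave_hamiltonian,
    rotating_frame,
    total_spin_ops,
    zfs_principal_values,
)


def doub(g=2.0):
    return SpinSystemSpec(kind="doub", g=[TensorSpec(g)])


def rp(g1=2.0030, g2=2.0047, J=1.0, dip=(1.0, 1.0, -2.0)):
    return SpinSystemSpec(
        kind="rp", g=[TensorSpec(g1), TensorSpec(g2)], J=J, dipolar=TensorSpec(dip)
    )


def trip(D=45.0, E=9.0, **kw):
    return SpinSystemSpec(kind="trip", g=[TensorSpec(2.002)], D=D, E=E, **kw)


def tdp(J=-500.0, D=20.0):
    return SpinSystemSpec(
        kind="tdp",
        g=[TensorSpec(2.003), TensorSpec(2.005)],
        J=J,
        D=D,
        E=0.0,
        dipolar=TensorSpec((1.0, 1.0, -2.0)),
    )


ALL_SPECS = [doub(), rp(), trip(), tdp()]


def test_zfs_principal_values_traceless():
    pv = zfs_principal_values(45.0, 9.0)
    np.testing.assert_allclose(pv, [-6.0, -24.0, 30.0])
    assert pv.sum() == pytest.approx(0.0)


def test_spec_kind_interaction_validation():
    with pytest.raises(ValueError, match="does not take"):
        SpinSystemSpec(kind="doub", g=[TensorSpec(2.0)], D=45.0)
    with pytest.raises(ValueError, match="requires"):
        SpinSystemSpec(kind="rp", g=[TensorSpec(2.0), TensorSpec(2.0)], J=1.0)
    with pytest.raises(ValueError, match="g tensor"):
        SpinSystemSpec(kind="trip", g=[TensorSpec(2.0), TensorSpec(2.0)], D=45.0)


def test_doublet_zeeman_matches_mw_frequency():
    # g = 2.0 at 348.3 mT resonates at 9.7498 GHz, the doublet peak position
    H = np.asarray(build_static_hamiltonian(doub(), 348.3))
    freq_GHz = (H[0, 0] - H[1, 1]).real / (2 * np.pi * 1e3)
    assert freq_GHz == pytest.approx(9.7498, abs=5e-4)
    assert freq_GHz == pytest.approx(9.75, rel=1e-4)


def test_zero_interactions_zero_matrix():
    spec = SpinSystemSpec(
        kind="rp",
        g=[TensorSpec(2.0), TensorSpec(2.0)],
        J=0.0,
        dipolar=TensorSpec((0.0, 0.0, 0.0)),
    )
    H = np.asarray(build_static_hamiltonian(spec, 0.0))
    assert np.abs(H).max() == 0.0


def test_triplet_canonical_transitions_match_full_hamiltonian():
    # dense eigensolve of the full (non-secular) S·D·S + Zeeman at high field
    D = 1200.0
    spec = trip(D=D, E=0.0)
    B0 = 348.3
    H_sec = np.asarray(build_static_hamiltonian(spec, B0, (0.0, 0.0)))
    sx, sy, sz = (np.asarray(o) for o in spin_matrices(1.0))
    svec = [sx, sy, sz]
    D_lab = np.diag(zfs_principal_values(D, 0.0)) * MHZ_TO_ANGULAR
    H_full = zeeman_angular(2.002, B0) * sz + sum(
        D_lab[a, a] * svec[a] @ svec[a] for a in range(3)
    )
    ev_sec = np.linalg.eigvalsh(H_sec)
    ev_full = np.linalg.eigvalsh(H_full)
    # first-order agreement: second-order shifts are O(D²/ω0) ≈ 0.15 MHz
    np.testing.assert_allclose(ev_sec, ev_full, atol=2 * np.pi * 0.2)
    trans = sorted(t[3] for t in allowed_transitions(H_sec, spec))
    w0 = zeeman_angular(2.002, B0)
    np.testing.assert_allclose(
        trans, [w0 - D * MHZ_TO_ANGULAR, w0 + D * MHZ_TO_ANGULAR], rtol=1e-10
    )


def test_secular_zfs_is_diagonal_of_rotated_full_tensor():
    # constructive definition of the secular approximation
    spec = trip(D_frame=(0.4, 0.8, 1.3))
    phi, theta = 0.9, 0.6
    sx, sy, sz = (np.asarray(o) for o in spin_matrices(1.0))
    svec = [sx, sy, sz]
    D_lab = spec.zfs_tensor().lab(phi, theta) * MHZ_TO_ANGULAR
    H_full = sum(
        D_lab[a, b] * svec[a] @ svec[b] for a in range(3) for b in range(3)
    )
    H = np.asarray(build_static_hamiltonian(spec, 350.0, (phi, theta)))
    H_zfs = H - zeeman_angular(2.002, 350.0) * sz
    scale = max(np.abs(H_full).max(), 1.0)
    assert np.abs(H_zfs - np.diag(np.diag(H_full))).max() / scale < 1e-12


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.kind)
def test_hamiltonians_hermitian_and_commute_with_sz(spec):
    for ori in [(0.0, 0.0), (0.7, 1.1), (2.1, 0.4)]:
        H = np.asarray(build_static_hamiltonian(spec, 347.0, ori))
        np.testing.assert_allclose(H, H.conj().T, atol=1e-10)
        _, _, sz = total_spin_ops(spec)
        assert np.abs(H @ sz - sz @ H).max() < 1e-9


def test_exchange_splitting_and_triplet_degeneracy():
    spec = SpinSystemSpec(
        kind="rp",
        g=[TensorSpec(2.0), TensorSpec(2.0)],
        J=5.0,
        dipolar=TensorSpec((0.0, 0.0, 0.0)),
    )
    ev = np.linalg.eigvalsh(np.asarray(build_static_hamiltonian(spec, 0.0)))
    ev_MHz = ev / MHZ_TO_ANGULAR
    np.testing.assert_allclose(ev_MHz[:3], ev_MHz[0], atol=1e-10)  # triplet degenerate
    assert ev_MHz[3] - ev_MHz[0] == pytest.approx(2 * 5.0, abs=1e-10)  # S-T split 2J


def test_rp_offdiagonals_only_singlet_t0():
    H = np.asarray(build_static_hamiltonian(rp(), 347.6))
    mask = np.abs(H) > 1e-9
    off = mask & ~np.eye(4, dtype=bool)
    expected = np.zeros((4, 4), dtype=bool)
    expected[1, 3] = expected[3, 1] = True  # T0 <-> S only
    assert np.array_equal(off, expected)


def test_rotating_frame_on_resonance_and_identity():
    spec = doub()
    b_res = field_for_frequency(2.0, 9.75)
    H = build_static_hamiltonian(spec, b_res)
    H_rot = np.asarray(rotating_frame(H, 9.75, spec))
    assert np.abs(np.diag(H_rot)).max() < 1e-9
    np.testing.assert_allclose(
        np.asarray(rotating_frame(H, 0.0, spec)), np.asarray(H), atol=1e-12
    )


def test_rotating_frame_shifts_by_delta_m():
    # eigensolve both frames; single-quantum gaps shift by ω·Δm
    spec = rp()
    omega = 9.75 * 2 * np.pi * 1e3
    H_lab = np.asarray(build_static_hamiltonian(spec, 347.6))
    H_rot = np.asarray(rotating_frame(H_lab, 9.75, spec))
    _, _, sz = total_spin_ops(spec)
    ev_lab, v = np.linalg.eigh(H_lab)
    m = np.diag(v.conj().T @ sz @ v).real
    ev_rot_expected = ev_lab - omega * m
    ev_rot = np.linalg.eigvalsh(H_rot)
    np.testing.assert_allclose(np.sort(ev_rot_expected), ev_rot, atol=1e-6)


def test_microwave_hamiltonian_zero_and_linear():
    spec = rp()
    assert np.abs(np.asarray(microwave_hamiltonian(spec, 0.0))).max() == 0.0
    H1 = np.asarray(microwave_hamiltonian(spec, 0.05))
    H2 = np.asarray(microwave_hamiltonian(spec, 0.10))
    np.testing.assert_allclose(H2, 2 * H1, atol=1e-12)
    np.testing.assert_allclose(H1, H1.conj().T, atol=1e-14)


def test_energy_levels_doublet_slopes():
    fields = np.linspace(300.0, 360.0, 7)
    levels = energy_levels(doub(), fields)
    slopes = np.diff(levels, axis=0) / np.diff(fields)[:, None]
    expected = zeeman_angular(2.0, 1.0) / 2
    np.testing.assert_allclose(slopes[:, 0], -expected, rtol=1e-10)
    np.testing.assert_allclose(slopes[:, 1], expected, rtol=1e-10)


def test_energy_levels_tdp_six_curves():
    levels = energy_levels(tdp(), np.linspace(330.0, 360.0, 5))
    assert levels.shape == (5, 6)
    assert np.all(np.diff(levels, axis=1) >= -1e-9)


def test_energy_levels_triplet_zfs_offsets():
    D = 45.0
    levels = energy_levels(trip(D=D, E=0.0), np.array([348.3]), (0.0, 0.0))[0]
    w0 = zeeman_angular(2.002, 348.3)
    gaps = np.diff(levels)
    np.testing.assert_allclose(
        sorted(gaps), sorted([w0 - D * MHZ_TO_ANGULAR, w0 + D * MHZ_TO_ANGULAR]),
        rtol=1e-10,
    )


def test_energy_levels_empty_axis_rejected():
    with pytest.raises(ValueError, match="empty"):
        energy_levels(doub(), np.array([]))


@pytest.mark.parametrize(
    "spec,expected",
    [(doub(), 1), (rp(), 4), (trip(), 2), (tdp(), 4)],
    ids=["doub", "rp", "trip", "tdp"],
)
def test_allowed_transition_counts(spec, expected):
    H = build_static_hamiltonian(spec, 347.6)
    assert len(allowed_transitions(H, spec)) == expected


def test_experiment_spec_validation():
    with pytest.raises(ValueError, match="increasing"):
        ExperimentSpec(9.75, [348.0, 347.0], 0.1, [0.0, 1.0])
    with pytest.raises(ValueError, match="B1"):
        ExperimentSpec(9.75, [347.0], -0.1, [0.0])
    with pytest.raises(ValueError, match="frequency"):
        ExperimentSpec(-1.0, [347.0], 0.1, [0.0])
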