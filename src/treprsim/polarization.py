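"""Initial density matrices for the implemented polarization modes.

Photoexcitation creates non-Boltzmann populations; which levels are
populated depends on the formation mechanism.  Five preset modes are
provided (plus a custom matrix):

``eigen``
    Populations of the eigenstates of the static Hamiltonian at the
    current field point, given in ascending energy order.
``zf`` / ``triplet-zf``
    Populations of the three zero-field triplet states |TX⟩, |TY⟩, |TZ⟩
    in ascending zero-field energy order, projected onto the high-field
    states per field point; coherences are discarded after the
    transformation, so the result is diagonal in the working basis.
``singlet``
    Radical pair born from a singlet precursor: only |S⟩ populated.
``triplet-pnm``
    High-field triplet populations (p+, p0, p−) placed directly on
    (|T+⟩, |T0⟩, |T−⟩).
``custom``
    A user-supplied Hermitian matrix in the working basis (the only
    mode that may carry initial coherences).

All preset modes produce Hermitian, positive-semidefinite matrices that
are diagonal in the working basis — initially only longitudinal
magnetization exists and coherences are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MHZ_TO_ANGULAR, zeeman_angular
from .spinops import OperatorMatrix, spin_matrices
from .spinsystem import SpinSystemSpec, TensorSpec, build_static_hamiltonian

__all__ = [
    "InitialState",
    "density_from_eigenpopulations",
    "density_triplet_zerofield",
    "density_pair",
    "density_tdp",
    "build_initial_density",
]

MODES = ("eigen", "zf", "singlet", "triplet-pnm", "triplet-zf", "custom")

_PSD_TOL = -1e-10


@dataclass
class InitialState:
    """Initial-state selection: mode plus the populations it needs."""

    mode: str
    populations: np.ndarray | None = None  # eigen mode: one per eigenstate
    triplet: np.ndarray | None = None  # 3 triplet populations
    doublet: np.ndarray | None = None  # 2 doublet populations (tdp)
    custom_matrix: np.ndarray | None = None
    normalize: str = "unit"  # 'unit' -> trace 1; 'raw' -> keep totals

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown initial-state mode '{self.mode}'")
        for name in ("populations", "triplet", "doublet"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v < 0):
                    raise ValueError(f"{name} must be non-negative")
                setattr(self, name, v)
        if self.normalize not in ("unit", "raw"):
            raise ValueError("normalize must be 'unit' or 'raw'")


def _finalize(rho: np.ndarray, normalize: str, label: str) -> OperatorMatrix:
    rho = 0.5 * (rho + rho.conj().T)
    ev = np.linalg.eigvalsh(rho)
    if ev.min() < _PSD_TOL:
        raise ValueError(
            f"initial density matrix not positive semidefinite (min eigenvalue {ev.min():.2e})"
        )
    tr = np.trace(rho).real
    if normalize == "unit":
        if tr <= 0:
            raise ValueError("cannot normalize a traceless initial density matrix")
        rho = rho / tr
    return OperatorMatrix(rho, hermitian=True, basis_label=label)


def density_from_eigenpopulations(
    populations: np.ndarray, H_static: np.ndarray | OperatorMatrix
) -> np.ndarray:
    """ρ = V diag(p) V† with V the ascending-energy eigenvectors of H."""
    H = np.asarray(H_static, dtype=complex)
    p = np.asarray(populations, dtype=float)
    if p.size != H.shape[0]:
        raise ValueError(
            f"expected {H.shape[0]} eigenstate populations, got {p.size}"
        )
    _, vecs = np.linalg.eigh(H)
    return (vecs * p) @ vecs.conj().T


def _triplet_zf_populations(
    populations: np.ndarray,
    zfs: TensorSpec,
    g_iso: float,
    B0: float,
    orientation: tuple[float, float],
) -> np.ndarray:
    """High-field populations (T+, T0, T−) from zero-field populations.

    The zero-field states are the eigenstates of the full (non-secular)
    ZFS Hamiltonian S·D·S at the given orientation, ordered by ascending
    zero-field energy.  They are projected onto the eigenstates of the
    full isolated-triplet Hamiltonian at the actual field, and the
    eigenstates are assigned to the working slots (T+, T0, T−) by
    maximum overlap; coherences are discarded.
    """
    p = np.asarray(populations, dtype=float)
    if p.size != 3:
        raise ValueError("zero-field mode needs exactly 3 triplet populations")
    phi, theta = orientation
    sx, sy, sz = (np.asarray(o) for o in spin_matrices(1.0))
    D_lab = zfs.lab(phi, theta) * MHZ_TO_ANGULAR
    svec = [sx, sy, sz]
    H_zfs = sum(
        D_lab[a, b] * (svec[a] @ svec[b]) for a in range(3) for b in range(3)
    )
    zf_energies, zf_vecs = np.linalg.eigh(H_zfs)  # ascending
    H_full = zeeman_angular(g_iso, B0) * sz + H_zfs
    _, hf_vecs = np.linalg.eigh(H_full)
    # assign each high-field eigenstate to its dominant m-state slot
    overlap = np.abs(hf_vecs) ** 2  # rows: m-basis (T+, T0, T-), cols: eigenstates
    slot_of_eig = np.argmax(overlap, axis=0)
    if len(set(slot_of_eig.tolist())) != 3:
        slot_of_eig = np.argsort(np.argsort(-np.diag(hf_vecs.conj().T @ sz @ hf_vecs).real))
    proj = np.abs(hf_vecs.conj().T @ zf_vecs) ** 2  # (eigenstate, zf-state)
    p_eig = proj @ p
    p_work = np.zeros(3)
    for eig_idx, slot in enumerate(slot_of_eig):
        p_work[slot] = p_eig[eig_idx]
    return p_work


def density_triplet_zerofield(
    populations: np.ndarray,
    spec: SpinSystemSpec,
    B0: float,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Triplet density matrix (3×3, working basis) from zero-field populations."""
    if spec.kind == "rp":
        # precursor-triplet ZFS is not an rp parameter; the pair's dipolar
        # tensor defines the zero-field axes used for the mapping
        zfs = spec.dipolar
    else:
        zfs = spec.zfs_tensor()
    g_iso = spec.g[0].isotropic
    p_work = _triplet_zf_populations(populations, zfs, g_iso, B0, orientation)
    return np.diag(p_work).astype(complex)


def density_pair(
    mode: str,
    populations: np.ndarray | None,
    spec: SpinSystemSpec,
    B0: float,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Radical-pair density matrix in the singlet–triplet basis (T+,T0,T−,S)."""
    if spec.kind != "rp":
        raise ValueError(f"pair modes require kind 'rp', got '{spec.kind}'")
    rho = np.zeros((4, 4), dtype=complex)
    if mode == "singlet":
        rho[3, 3] = 1.0
    elif mode == "triplet-pnm":
        p = np.asarray(populations, dtype=float)
        if p.size != 3:
            raise ValueError("triplet-pnm needs 3 populations (p+, p0, p−)")
        rho[:3, :3] = np.diag(p)
    elif mode == "triplet-zf":
        rho[:3, :3] = density_triplet_zerofield(populations, spec, B0, orientation)
    else:
        raise ValueError(f"mode '{mode}' is not a radical-pair mode")
    return rho


def density_tdp(
    triplet_mode: str,
    triplet_populations: np.ndarray,
    doublet_populations: np.ndarray,
    spec: SpinSystemSpec,
    B0: float,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Triplet–doublet-pair density matrix ρ_T ⊗ ρ_d in the product basis."""
    if spec.kind != "tdp":
        raise ValueError(f"density_tdp requires kind 'tdp', got '{spec.kind}'")
    pd = np.asarray(doublet_populations, dtype=float)
    if pd.size != 2:
        raise ValueError("tdp needs 2 doublet populations")
    if triplet_mode == "triplet-pnm":
        pt = np.asarray(triplet_populations, dtype=float)
        if pt.size != 3:
            raise ValueError("triplet-pnm needs 3 populations (p+, p0, p−)")
        rho_t = np.diag(pt).astype(complex)
    elif triplet_mode in ("triplet-zf", "zf"):
        rho_t = density_triplet_zerofield(triplet_populations, spec, B0, orientation)
    else:
        raise ValueError(f"unknown tdp triplet mode '{triplet_mode}'")
    return np.kron(rho_t, np.diag(pd).astype(complex))


def build_initial_density(
    state: InitialState,
    spec: SpinSystemSpec,
    B0: float,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> OperatorMatrix:
    """Construct ρ(t0) in the working basis for one field point/orientation."""
    label = spec.basis_label
    if state.mode == "custom":
        if state.custom_matrix is None:
            raise ValueError("custom mode requires custom_matrix")
        rho = np.asarray(state.custom_matrix, dtype=complex)
        if rho.shape != (spec.dim, spec.dim):
            raise ValueError(
                f"custom matrix shape {rho.shape} does not match system dimension {spec.dim}"
            )
        return _finalize(rho, state.normalize, label)
    if state.mode == "eigen":
        H = build_static_hamiltonian(spec, B0, orientation)
        rho = density_from_eigenpopulations(state.populations, H)
        return _finalize(rho, state.normalize, label)
    if spec.kind == "trip":
        if state.mode not in ("zf", "triplet-zf"):
            raise ValueError(f"mode '{state.mode}' is not valid for a triplet")
        rho = density_triplet_zerofield(state.triplet, spec, B0, orientation)
        return _finalize(rho, state.normalize, label)
    if spec.kind == "rp":
        rho = density_pair(state.mode, state.triplet, spec, B0, orientation)
        return _finalize(rho, state.normalize, label)
    if spec.kind == "tdp":
        if state.doublet is None:
            raise ValueError("tdp initial state requires doublet populations")
        rho = density_tdp(
            state.mode, state.triplet, state.doublet, spec, B0, orientation
        )
        return _finalize(rho, state.normalize, label)
    raise ValueError(f"mode '{state.mode}' is not valid for kind '{spec.kind}'")
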