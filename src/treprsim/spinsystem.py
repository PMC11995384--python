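"""Rotating-frame secular spin Hamiltonians for the four implemented systems.

Systems and working bases
-------------------------
``doub``
    One electron, s = 1/2; basis {|α⟩, |β⟩}; Zeeman interaction only.
``rp``
    Spin-correlated radical pair, two s = 1/2 electrons with exchange J
    and a dipolar tensor; singlet–triplet basis (|T+⟩, |T0⟩, |T−⟩, |S⟩).
``trip``
    Photoexcited triplet, S = 1, zero-field splitting (D, E);
    high-field basis (|T+⟩, |T0⟩, |T−⟩).
``tdp``
    Triplet–doublet pair: S = 1 coupled to s = 1/2 via exchange and a
    dipolar tensor, plus triplet ZFS; product basis
    (|T+α⟩, |T+β⟩, |T0α⟩, |T0β⟩, |T−α⟩, |T−β⟩).

Conventions
-----------
* Internal energy units: angular frequency, rad·μs⁻¹.
* Zeeman term per electron: ω0 = g_eff·μB·B0/ħ with
  g_eff = ‖g_lab·ẑ‖, the first-order secular value for an anisotropic
  g tensor.
* Secular ZFS: (3/2)·D_zz^lab·(Sz² − S(S+1)/3·𝟙) — identical to the
  diagonal of the full rotated S·D·S in the high-field basis.
* Secular dipolar coupling: D_zz^lab·(S1z·S2z − ¼(S1+S2− + S1−S2+)).
* Exchange: −J·(½ + 2 S1·S2); singlet–triplet splitting 2J with the
  triplet below the singlet for J > 0.
* The microwave amplitude B1 is the rotating-frame (circular) amplitude,
  entering as ω1 = g_iso·μB·B1/ħ without a factor ½.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import GHZ_TO_ANGULAR, MHZ_TO_ANGULAR, zeeman_angular
from .orientation import euler_rotation, rotation_matrix
from .spinops import BasisTransform, OperatorMatrix, embed, spin_matrices, transform_basis

__all__ = [
    "TensorSpec",
    "SpinSystemSpec",
    "ExperimentSpec",
    "zfs_principal_values",
    "singlet_triplet_transform",
    "build_static_hamiltonian",
    "rotating_frame",
    "microwave_hamiltonian",
    "total_spin_ops",
    "energy_levels",
    "allowed_transitions",
]

KINDS = ("doub", "rp", "trip", "tdp")

_SQRT2 = np.sqrt(2.0)


def zfs_principal_values(D: float, E: float) -> np.ndarray:
    """Principal values (Dxx, Dyy, Dzz) = (−D/3+E, −D/3−E, +2D/3); traceless."""
    return np.array([-D / 3.0 + E, -D / 3.0 - E, 2.0 * D / 3.0])


@dataclass
class TensorSpec:
    """Symmetric interaction tensor: principal values plus a ZYZ frame tilt.

    ``principal`` may be a scalar (isotropic) or three principal values;
    ``frame`` holds Euler angles (α, β, γ) in radians tilting the tensor
    frame relative to the molecular frame.
    """

    principal: np.ndarray
    frame: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.principal, dtype=float))
        if p.size == 1:
            p = np.full(3, p.item())
        if p.size != 3:
            raise ValueError("tensor needs a scalar or three principal values")
        self.principal = p
        self.frame = tuple(float(a) for a in self.frame)

    @property
    def isotropic(self) -> float:
        return float(np.mean(self.principal))

    def molecular(self) -> np.ndarray:
        """3×3 tensor in the molecular frame (frame tilt applied)."""
        R = euler_rotation(*self.frame)
        return R @ np.diag(self.principal) @ R.T

    def lab(self, phi: float, theta: float) -> np.ndarray:
        """3×3 tensor in the laboratory frame for orientation (ϕ, ϑ)."""
        R = rotation_matrix(phi, theta)
        return R @ self.molecular() @ R.T


@dataclass
class SpinSystemSpec:
    """Declarative description of a spin system and its interactions.

    Couplings J, D, E and dipolar principal values are in MHz; g values
    are dimensionless.  Which fields are allowed depends on ``kind``:
    doub {g}; rp {g (two tensors), J, dipolar}; trip {g, D, E};
    tdp {g (triplet then doublet), J, D, E, dipolar}.
    """

    kind: str
    g: list[TensorSpec] = field(default_factory=list)
    J: float | None = None
    D: float | None = None
    E: float = 0.0
    D_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dipolar: TensorSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown spin-system kind '{self.kind}'")
        self.g = [g if isinstance(g, TensorSpec) else TensorSpec(g) for g in self.g]
        n_g = {"doub": 1, "rp": 2, "trip": 1, "tdp": 2}[self.kind]
        if len(self.g) != n_g:
            raise ValueError(f"kind '{self.kind}' requires {n_g} g tensor(s)")
        needs_J = self.kind in ("rp", "tdp")
        if needs_J and self.J is None:
            raise ValueError(f"kind '{self.kind}' requires an exchange parameter J")
        if not needs_J and self.J is not None:
            raise ValueError(f"kind '{self.kind}' does not take J")
        needs_D = self.kind in ("trip", "tdp")
        if needs_D and self.D is None:
            raise ValueError(f"kind '{self.kind}' requires ZFS parameters D (and E)")
        if not needs_D and self.D is not None:
            raise ValueError(f"kind '{self.kind}' does not take ZFS parameters")
        needs_dip = self.kind in ("rp", "tdp")
        if needs_dip and self.dipolar is None:
            raise ValueError(f"kind '{self.kind}' requires a dipolar tensor")
        if not needs_dip and self.dipolar is not None:
            raise ValueError(f"kind '{self.kind}' does not take a dipolar tensor")

    @property
    def dims(self) -> tuple[int, ...]:
        """Subsystem dimensions in Kronecker order."""
        return {"doub": (2,), "rp": (2, 2), "trip": (3,), "tdp": (3, 2)}[self.kind]

    @property
    def dim(self) -> int:
        return int(np.prod(self.dims))

    @property
    def basis_label(self) -> str:
        return {
            "doub": "alpha-beta",
            "rp": "singlet-triplet (T+,T0,T-,S)",
            "trip": "high-field (T+,T0,T-)",
            "tdp": "product (T+a,T+b,T0a,T0b,T-a,T-b)",
        }[self.kind]

    def zfs_tensor(self) -> TensorSpec:
        if self.D is None:
            raise ValueError("spin system has no ZFS tensor")
        return TensorSpec(zfs_principal_values(self.D, self.E), self.D_frame)


@dataclass
class ExperimentSpec:
    """Experimental conditions: microwave frequency/field, field and time axes."""

    mw_freq: float  # GHz
    B0_axis: np.ndarray  # mT
    B1: float  # mT, rotating-frame amplitude
    time_axis: np.ndarray  # μs

    def __post_init__(self) -> None:
        self.B0_axis = np.atleast_1d(np.asarray(self.B0_axis, dtype=float))
        self.time_axis = np.atleast_1d(np.asarray(self.time_axis, dtype=float))
        if self.mw_freq <= 0:
            raise ValueError("microwave frequency must be positive")
        if self.B1 < 0:
            raise ValueError("B1 must be non-negative")
        if self.B0_axis.size and np.any(np.diff(self.B0_axis) <= 0):
            raise ValueError("field axis must be strictly increasing")
        if self.time_axis.size and (
            np.any(self.time_axis < 0) or np.any(np.diff(self.time_axis) < 0)
        ):
            raise ValueError("time axis must be non-negative and increasing")


def singlet_triplet_transform() -> BasisTransform:
    """Product basis (αα, αβ, βα, ββ) → singlet–triplet basis (T+, T0, T−, S)."""
    U = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0 / _SQRT2, 1.0 / _SQRT2, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 1.0 / _SQRT2, -1.0 / _SQRT2, 0.0],
        ],
        dtype=complex,
    )
    return BasisTransform(U, from_basis="product", to_basis="singlet-triplet")


def _single_spin_ops(spec: SpinSystemSpec) -> list[tuple[np.ndarray, ...]]:
    """Per-spin (Sx, Sy, Sz) embedded in the working basis."""
    dims = spec.dims
    spins = {"doub": (0.5,), "rp": (0.5, 0.5), "trip": (1.0,), "tdp": (1.0, 0.5)}[
        spec.kind
    ]
    ops = []
    for pos, s in enumerate(spins):
        triple = spin_matrices(s)
        embedded = tuple(np.asarray(embed(t, pos, dims)) for t in triple)
        ops.append(embedded)
    if spec.kind == "rp":
        U = singlet_triplet_transform()
        ops = [tuple(U.apply(o) for o in triple) for triple in ops]
    return ops


def total_spin_ops(spec: SpinSystemSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total (Sx, Sy, Sz) in the working basis."""
    ops = _single_spin_ops(spec)
    return tuple(sum(o[k] for o in ops) for k in range(3))  # type: ignore[return-value]


def _g_eff(g: TensorSpec, phi: float, theta: float) -> float:
    """First-order secular g value ‖g_lab·ẑ‖ for the orientation (ϕ, ϑ)."""
    g_lab = g.lab(phi, theta)
    return float(np.linalg.norm(g_lab.T @ np.array([0.0, 0.0, 1.0])))


def build_static_hamiltonian(
    spec: SpinSystemSpec,
    B0: float,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> OperatorMatrix:
    """Lab-frame secular Hamiltonian (rad·μs⁻¹) in the working basis."""
    phi, theta = orientation
    ops = _single_spin_ops(spec)
    n = spec.dim
    H = np.zeros((n, n), dtype=complex)

    for g, (_, _, sz) in zip(spec.g, ops):
        H += zeeman_angular(_g_eff(g, phi, theta), B0) * sz

    if spec.J is not None:
        j_ang = spec.J * MHZ_TO_ANGULAR
        (s1x, s1y, s1z), (s2x, s2y, s2z) = ops
        s1s2 = s1x @ s2x + s1y @ s2y + s1z @ s2z
        H += -j_ang * (0.5 * np.eye(n) + 2.0 * s1s2)

    if spec.dipolar is not None:
        dzz = spec.dipolar.lab(phi, theta)[2, 2] * MHZ_TO_ANGULAR
        (s1x, s1y, s1z), (s2x, s2y, s2z) = ops
        # flip-flop: S1+S2- + S1-S2+ = 2(S1xS2x + S1yS2y)
        H += dzz * (s1z @ s2z - 0.5 * (s1x @ s2x + s1y @ s2y))

    if spec.D is not None:
        dzz = spec.zfs_tensor().lab(phi, theta)[2, 2] * MHZ_TO_ANGULAR
        sz_t = ops[0][2]  # triplet Sz (first-listed spin for trip/tdp)
        H += 1.5 * dzz * (sz_t @ sz_t - (2.0 / 3.0) * np.eye(n))

    H = 0.5 * (H + H.conj().T)  # clean numerical asymmetry
    return OperatorMatrix(H, hermitian=True, basis_label=spec.basis_label)


def rotating_frame(
    H_static: np.ndarray | OperatorMatrix, mw_freq: float, spec: SpinSystemSpec
) -> OperatorMatrix:
    """Transfer to the frame rotating at the microwave frequency.

    Subtracts ω·Sz_total (ω in rad·μs⁻¹ from ``mw_freq`` in GHz); valid
    because every secular Hamiltonian here commutes with total Sz.
    """
    omega = mw_freq * GHZ_TO_ANGULAR
    _, _, sz_tot = total_spin_ops(spec)
    H = np.asarray(H_static, dtype=complex) - omega * sz_tot
    return OperatorMatrix(H, hermitian=True, basis_label=spec.basis_label)


def microwave_hamiltonian(spec: SpinSystemSpec, B1: float) -> OperatorMatrix:
    """Microwave term Σ_i ω1,i·Sx,i with ω1,i = g_iso,i·μB·B1/ħ."""
    if B1 < 0:
        raise ValueError("B1 must be non-negative")
    ops = _single_spin_ops(spec)
    n = spec.dim
    H1 = np.zeros((n, n), dtype=complex)
    for g, (sx, _, _) in zip(spec.g, ops):
        H1 += zeeman_angular(g.isotropic, B1) * sx
    return OperatorMatrix(H1, hermitian=True, basis_label=spec.basis_label)


def energy_levels(
    spec: SpinSystemSpec,
    B0_axis: np.ndarray,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Eigenenergies (rad·μs⁻¹) of the static Hamiltonian vs field.

    Returns an array of shape (n_fields, dim) with ascending eigenvalues
    per field point; adjacent fields are matched by eigenvalue order,
    which yields continuous curves for the secular Hamiltonians used
    here.
    """
    B0_axis = np.atleast_1d(np.asarray(B0_axis, dtype=float))
    if B0_axis.size == 0:
        raise ValueError("empty field axis")
    out = np.empty((B0_axis.size, spec.dim))
    for k, b in enumerate(B0_axis):
        H = build_static_hamiltonian(spec, b, orientation)
        out[k] = np.linalg.eigvalsh(np.asarray(H))
    return out


def allowed_transitions(
    H_static: np.ndarray | OperatorMatrix,
    spec: SpinSystemSpec,
    threshold: float = 1e-3,
) -> list[tuple[int, int, float, float]]:
    """EPR-allowed transitions between eigenstates of a static Hamiltonian.

    Returns (i, j, moment, frequency) for eigenstate pairs i < j (energy
    ascending) whose squared total-Sx matrix element exceeds
    ``threshold`` times the largest moment.  Frequency in rad·μs⁻¹.
    """
    H = np.asarray(H_static, dtype=complex)
    energies, vecs = np.linalg.eigh(H)
    sx_tot, _, _ = total_spin_ops(spec)
    m = vecs.conj().T @ sx_tot @ vecs
    moments = np.abs(m) ** 2
    n = H.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    max_moment = max(moments[i, j] for i, j in pairs) if pairs else 0.0
    out = []
    for i, j in pairs:
        if max_moment > 0 and moments[i, j] > threshold * max_moment:
            out.append((i, j, float(moments[i, j]), float(energies[j] - energies[i])))
    return out
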