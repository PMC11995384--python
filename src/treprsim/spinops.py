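"""Elementary spin-operator algebra and basis transformations.

Spin matrices are the standard angular-momentum matrices in the |m⟩
basis with m descending (normalized Pauli matrices in units of ħ for
s = 1/2).  Composite systems are built by Kronecker embedding, with the
factor order fixed as listed in the subsystem dimensions.

Basis-transform convention
--------------------------
A :class:`BasisTransform` U maps a matrix M from an old basis to a new
basis as M' = U M U†, where the *rows* of U are the new-basis vectors
expressed in the old basis.  :func:`diagonalize` returns the transform
from the working basis to the eigenbasis, so
``transform_basis(H, diagonalize(H)[1])`` is diagonal.  The inverse map
(eigenbasis back to working basis) is ``U.inverse()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OperatorMatrix",
    "BasisTransform",
    "spin_matrices",
    "embed",
    "transform_basis",
    "diagonalize",
]

_HERM_TOL = 1e-12
_UNITARY_TOL = 1e-8


@dataclass
class OperatorMatrix:
    """Complex square matrix holding a spin operator, Hamiltonian or ρ."""

    values: np.ndarray
    hermitian: bool = False
    basis_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("OperatorMatrix requires a square matrix")
        if self.hermitian:
            dev = np.max(np.abs(self.values - self.values.conj().T))
            if dev > _HERM_TOL:
                raise ValueError(
                    f"matrix flagged hermitian deviates from H=H† by {dev:.2e}"
                )

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)


@dataclass
class BasisTransform:
    """Unitary basis-change matrix; rows are new-basis vectors in the old basis."""

    matrix: np.ndarray
    from_basis: str = ""
    to_basis: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        n = self.matrix.shape[0]
        dev = np.max(np.abs(self.matrix @ self.matrix.conj().T - np.eye(n)))
        if dev > _UNITARY_TOL:
            raise ValueError(f"basis transform not unitary (deviation {dev:.2e})")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def apply(self, M: np.ndarray | OperatorMatrix) -> np.ndarray:
        """Transform a matrix to the new basis: U M U†."""
        M = np.asarray(M, dtype=complex)
        return self.matrix @ M @ self.matrix.conj().T

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(v, dtype=complex)

    def inverse(self) -> "BasisTransform":
        return BasisTransform(
            self.matrix.conj().T, from_basis=self.to_basis, to_basis=self.from_basis
        )


def spin_matrices(s: float) -> tuple[OperatorMatrix, OperatorMatrix, OperatorMatrix]:
    """Angular-momentum matrices (Sx, Sy, Sz) for spin s ∈ {1/2, 1}.

    Basis is |m⟩ with m descending; dimension 2s+1.  The triple obeys
    [Sx, Sy] = i Sz exactly.
    """
    if s not in (0.5, 1.0, 1):
        raise ValueError(f"unsupported spin quantum number s={s}; only 1/2 and 1")
    mult = int(round(2 * s + 1))
    m = s - np.arange(mult)  # descending
    sz = np.diag(m).astype(complex)
    # raising operator: <m+1|S+|m> = sqrt(s(s+1) - m(m+1))
    sp = np.zeros((mult, mult), dtype=complex)
    for k in range(1, mult):
        mm = m[k]
        sp[k - 1, k] = np.sqrt(s * (s + 1) - mm * (mm + 1))
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    lbl = f"m-descending (s={s})"
    return (
        OperatorMatrix(sx, hermitian=True, basis_label=lbl),
        OperatorMatrix(sy, hermitian=True, basis_label=lbl),
        OperatorMatrix(sz, hermitian=True, basis_label=lbl),
    )


def embed(
    op: np.ndarray | OperatorMatrix, position: int, dims: list[int] | tuple[int, ...]
) -> OperatorMatrix:
    """Kronecker-embed a single-subsystem operator into a composite system.

    Returns 𝟙 ⊗ … ⊗ op ⊗ … ⊗ 𝟙 with ``op`` at ``dims[position]``; the
    factor order is exactly the order of ``dims``.
    """
    arr = np.asarray(op, dtype=complex)
    if not 0 <= position < len(dims):
        raise ValueError(f"position {position} out of range for dims {dims}")
    if arr.shape[0] != dims[position]:
        raise ValueError(
            f"operator dimension {arr.shape[0]} does not match dims[{position}]={dims[position]}"
        )
    out = np.ones((1, 1), dtype=complex)
    for k, d in enumerate(dims):
        out = np.kron(out, arr if k == position else np.eye(d, dtype=complex))
    herm = bool(np.max(np.abs(arr - arr.conj().T)) <= _HERM_TOL)
    return OperatorMatrix(out, hermitian=herm)


def transform_basis(
    M: np.ndarray | OperatorMatrix, U: BasisTransform
) -> OperatorMatrix:
    """Express M in the new basis: M' = U M U†."""
    arr = np.asarray(M, dtype=complex)
    if arr.shape[0] != U.dim:
        raise ValueError("dimension mismatch between matrix and basis transform")
    out = U.apply(arr)
    herm = bool(np.max(np.abs(arr - arr.conj().T)) <= _HERM_TOL)
    label = U.to_basis
    return OperatorMatrix(out, hermitian=herm, basis_label=label)


def diagonalize(
    H: np.ndarray | OperatorMatrix, hermitian: bool = True
) -> tuple[np.ndarray, BasisTransform]:
    """Eigendecompose a Hermitian matrix.

    Returns energies in ascending order and the working→eigenbasis
    transform U.  Eigenvector phases are fixed so the largest-magnitude
    component of each eigenvector is real and positive (ties broken by
    the lowest index), making the transform reproducible.
    """
    arr = np.asarray(H, dtype=complex)
    if hermitian and np.max(np.abs(arr - arr.conj().T)) > 1e-10:
        raise ValueError("matrix is not Hermitian")
    energies, vecs = np.linalg.eigh(arr)
    # phase fix per eigenvector column
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        mags = np.abs(col)
        idx = int(np.argmax(mags > mags.max() - 1e-12))
        phase = col[idx] / mags[idx] if mags[idx] > 0 else 1.0
        vecs[:, k] = col / phase
    U = BasisTransform(vecs.conj().T, from_basis="working", to_basis="eigen")
    return energies, U
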