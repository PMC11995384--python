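"""Time evolution of the density matrix and signal detection.

Hilbert-space propagation solves the Liouville–von Neumann equation
ρ(t) = e^{−iHt}·ρ0·e^{+iHt} through a single eigendecomposition of the
(time-independent, rotating-frame) Hamiltonian, reused for all time
points.  Liouville-space propagation solves the stochastic Liouville
equation vec ρ(t) = exp[(−i·L_H + R)·t]·vec ρ0 through an
eigendecomposition of the generator, with a scaling-and-squaring matrix
exponential as fallback when the eigenvector matrix is ill-conditioned.

The detected trEPR signal is the expectation value of the total Sy
operator, ⟨Sy⟩ = Tr(Sy·ρ); with this sign an overpopulated lower level
yields a positive (microwave-absorptive) early-time signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .dynamics import Superoperator, devectorize, hamiltonian_superoperator, vectorize
from .spinops import OperatorMatrix

__all__ = [
    "PropagationResult",
    "propagate_hilbert",
    "propagate_liouville",
    "detect",
    "apply_decay",
]

_COND_LIMIT = 1e8


@dataclass
class PropagationResult:
    """Densities and detected signal on a time axis."""

    times: np.ndarray
    densities: np.ndarray  # (n_times, n, n)
    signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=complex)
        if self.densities.shape[0] != self.times.size:
            raise ValueError("times and densities lengths differ")
        if self.signal is not None and len(self.signal) != self.times.size:
            raise ValueError("times and signal lengths differ")


def detect(rho: np.ndarray | OperatorMatrix, sy_total: np.ndarray) -> float:
    """trEPR signal Tr(Sy·ρ); positive = absorption, negative = emission."""
    return float(np.trace(np.asarray(sy_total) @ np.asarray(rho)).real)


def propagate_hilbert(
    H: np.ndarray | OperatorMatrix,
    rho0: np.ndarray | OperatorMatrix,
    times: np.ndarray,
    detect_op: np.ndarray | None = None,
) -> PropagationResult:
    """Unitary evolution under a time-independent Hamiltonian.

    ``H`` must include the microwave term; one eigendecomposition is
    reused for every time point.
    """
    H = np.asarray(H, dtype=complex)
    if np.max(np.abs(H - H.conj().T)) > 1e-10:
        raise ValueError("Hilbert propagation requires a Hermitian Hamiltonian")
    rho0 = np.asarray(rho0, dtype=complex)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    energies, vecs = np.linalg.eigh(H)
    rho0_eig = vecs.conj().T @ rho0 @ vecs
    omega = energies[:, None] - energies[None, :]  # (n, n) transition frequencies
    out = np.empty((times.size,) + rho0.shape, dtype=complex)
    for k, t in enumerate(times):
        phase = np.exp(-1j * omega * t)
        out[k] = vecs @ (rho0_eig * phase) @ vecs.conj().T
    signal = None
    if detect_op is not None:
        signal = np.array([detect(out[k], detect_op) for k in range(times.size)])
    return PropagationResult(times, out, signal)


def propagate_liouville(
    H: np.ndarray | OperatorMatrix,
    R: Superoperator | np.ndarray | None,
    rho0: np.ndarray | OperatorMatrix,
    times: np.ndarray,
    detect_op: np.ndarray | None = None,
) -> PropagationResult:
    """Stochastic-Liouville evolution vec ρ(t) = e^{(−i·L_H + R)t}·vec ρ0."""
    H = np.asarray(H, dtype=complex)
    rho0 = np.asarray(rho0, dtype=complex)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    n = H.shape[0]
    if rho0.shape != (n, n):
        raise ValueError("dimension mismatch between H and rho0")
    G = -1j * np.asarray(hamiltonian_superoperator(H))
    if R is not None:
        R_arr = np.asarray(R, dtype=complex)
        if R_arr.shape != G.shape:
            raise ValueError("dimension mismatch between H and R superoperator")
        G = G + R_arr
    v0 = vectorize(rho0)
    out = np.empty((times.size, n, n), dtype=complex)
    use_eig = True
    try:
        w, V = np.linalg.eig(G)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            use_eig = False
    except np.linalg.LinAlgError:
        use_eig = False
    if use_eig:
        c0 = np.linalg.solve(V, v0)
        for k, t in enumerate(times):
            out[k] = devectorize(V @ (np.exp(w * t) * c0))
    else:
        dts = np.diff(times)
        uniform = times.size > 1 and np.allclose(dts, dts[0], rtol=1e-10, atol=1e-14)
        if uniform:
            E0 = scipy.linalg.expm(G * times[0])
            Edt = scipy.linalg.expm(G * dts[0])
            v = E0 @ v0
            for k in range(times.size):
                out[k] = devectorize(v)
                if k + 1 < times.size:
                    v = Edt @ v
        else:
            for k, t in enumerate(times):
                out[k] = devectorize(scipy.linalg.expm(G * t) @ v0)
    signal = None
    if detect_op is not None:
        signal = np.array([detect(out[k], detect_op) for k in range(times.size)])
    return PropagationResult(times, out, signal)


def apply_decay(signal: np.ndarray, times: np.ndarray, k: float) -> np.ndarray:
    """Multiply a signal (trace or field×time matrix) by e^{−kt}.

    Phenomenological overall decay for Hilbert-space simulations, where
    no dynamics superoperator is available.  The time axis runs along
    the last dimension.
    """
    if k < 0:
        raise ValueError("decay rate must be non-negative")
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    return signal * np.exp(-k * times)
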