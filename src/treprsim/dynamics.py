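"""Liouville-space machinery: vectorization, commutator and relaxation
superoperators, and user-defined rate superoperators.

A density matrix of dimension n is written as a column-stacked vector of
n² elements (element (i, j) sits at index j·n + i); superoperators are
n² × n² matrices acting on these vectors.  The coherent part enters as
the commutator superoperator L_H with d vec(ρ)/dt = −i·L_H·vec(ρ);
incoherent dynamics are added as rate superoperators whose elements are
set directly rather than derived from a bath model: the entry
r at (kl ← ij) adds r·ρ_ij to dρ_kl/dt.  Loss from the source element
is *not* implied — the user states it explicitly through negative
diagonal entries, so the total population is conserved only if the
population columns sum to zero (see :func:`validate_rates`).

The phenomenological T1/T2 model damps every coherence at 1/T2 and
drives the populations toward the uniform (infinite-temperature)
distribution at 1/T1, conserving the trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spinops import OperatorMatrix

__all__ = [
    "Superoperator",
    "RateSpec",
    "vectorize",
    "devectorize",
    "liouville_index",
    "hamiltonian_superoperator",
    "t1t2_superoperator",
    "rate_superoperator",
    "validate_rates",
]


@dataclass
class Superoperator:
    """n²×n² matrix acting on column-stacked density matrices."""

    values: np.ndarray
    kind: str = "combined"  # hamiltonian | relaxation | combined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        n2 = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n2:
            raise ValueError("superoperator must be square")
        n = int(round(np.sqrt(n2)))
        if n * n != n2:
            raise ValueError("superoperator side length must be a perfect square")

    @property
    def hilbert_dim(self) -> int:
        return int(round(np.sqrt(self.values.shape[0])))

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)


@dataclass
class RateSpec:
    """User-facing description of incoherent dynamics.

    Exactly one style is normally used:

    * ``T1``/``T2`` (μs): the phenomenological relaxation model;
    * ``entries``: raw element rates [(i, j, k, l, r), ...] meaning
      dρ_kl/dt += r·ρ_ij (r in μs⁻¹, negative allowed);
    * ``pop_rates``: n×n first-order kinetics matrix K with
      destination-row × source-column semantics, K[k, j] ≥ 0 the rate
      j → k for k ≠ j.  If the diagonal is all zero it is auto-filled
      to conserve population; a nonzero diagonal is taken as the
      explicit (possibly decaying) self-rate.
    * ``basis``: 'working' applies the rates to working-basis density
      matrix elements; 'eigen' interprets the indices as eigenstates of
      the static rotating-frame Hamiltonian (ascending energy) and the
      superoperator is transformed accordingly at build time.

    Styles combine additively if several are given.
    """

    T1: float | None = None
    T2: float | None = None
    entries: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    pop_rates: np.ndarray | None = None
    basis: str = "working"

    def __post_init__(self) -> None:
        if self.T1 is not None and self.T1 <= 0:
            raise ValueError("T1 must be positive")
        if self.T2 is not None and self.T2 <= 0:
            raise ValueError("T2 must be positive")
        if (self.T1 is None) != (self.T2 is None):
            raise ValueError("T1 and T2 must be given together")
        if self.pop_rates is not None:
            self.pop_rates = np.asarray(self.pop_rates, dtype=float)
        if self.basis not in ("working", "eigen"):
            raise ValueError("rate basis must be 'working' or 'eigen'")
        for e in self.entries:
            if len(e) != 5 or not np.isfinite(e[4]):
                raise ValueError(f"malformed rate entry {e!r}")

    @property
    def is_empty(self) -> bool:
        return self.T1 is None and not self.entries and self.pop_rates is None


def liouville_index(i: int, j: int, n: int) -> int:
    """Vector index of density-matrix element (i, j) under column stacking."""
    return j * n + i


def vectorize(M: np.ndarray | OperatorMatrix) -> np.ndarray:
    """Column-stack a square matrix into a vector of n² elements."""
    arr = np.asarray(M, dtype=complex)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("vectorize expects a square matrix")
    return arr.flatten(order="F")


def devectorize(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    v = np.asarray(v, dtype=complex)
    n = int(round(np.sqrt(v.size)))
    if n * n != v.size:
        raise ValueError("vector length is not a perfect square")
    return v.reshape((n, n), order="F")


def hamiltonian_superoperator(H: np.ndarray | OperatorMatrix) -> Superoperator:
    """Commutator superoperator L_H = 𝟙⊗H − Hᵀ⊗𝟙.

    With column stacking, −i·L_H·vec(ρ) = vec(−i[H, ρ]).
    """
    arr = np.asarray(H, dtype=complex)
    if np.max(np.abs(arr - arr.conj().T)) > 1e-10:
        raise ValueError("Hamiltonian must be Hermitian")
    n = arr.shape[0]
    eye = np.eye(n, dtype=complex)
    L = np.kron(eye, arr) - np.kron(arr.T, eye)
    return Superoperator(L, kind="hamiltonian")


def t1t2_superoperator(T1: float, T2: float, n: int) -> Superoperator:
    """Phenomenological relaxation superoperator.

    Coherences decay at 1/T2; populations relax toward the uniform
    distribution: dρ_ii/dt = −(ρ_ii − Tr(ρ)/n)/T1.  Trace-conserving.
    """
    if T1 <= 0 or T2 <= 0:
        raise ValueError("relaxation times must be positive")
    n2 = n * n
    R = np.zeros((n2, n2), dtype=complex)
    for i in range(n):
        for j in range(n):
            idx = liouville_index(i, j, n)
            if i != j:
                R[idx, idx] = -1.0 / T2
            else:
                for k in range(n):
                    R[idx, liouville_index(k, k, n)] += 1.0 / (n * T1)
                R[idx, idx] += -1.0 / T1
    return Superoperator(R, kind="relaxation")


def _expand_pop_rates(K: np.ndarray, n: int) -> list[tuple[int, int, int, int, float]]:
    if K.shape != (n, n):
        raise ValueError(f"population-rate matrix must be {n}×{n}")
    entries: list[tuple[int, int, int, int, float]] = []
    autofill = bool(np.all(np.diag(K) == 0.0))
    for src in range(n):
        for dst in range(n):
            r = K[dst, src]
            if dst == src or r == 0.0:
                continue
            if r < 0:
                raise ValueError("off-diagonal population rates must be non-negative")
            entries.append((src, src, dst, dst, r))
            if autofill:
                entries.append((src, src, src, src, -r))
    if not autofill:
        for src in range(n):
            if K[src, src] != 0.0:
                entries.append((src, src, src, src, K[src, src]))
    return entries


def rate_superoperator(rates: RateSpec, n: int) -> Superoperator:
    """Assemble the dynamics superoperator from a :class:`RateSpec`.

    Does not include the basis transformation for ``basis='eigen'``
    specs — the propagation layer applies it, since the eigenbasis
    depends on field and orientation.
    """
    n2 = n * n
    R = np.zeros((n2, n2), dtype=complex)
    if rates.T1 is not None:
        R += np.asarray(t1t2_superoperator(rates.T1, rates.T2, n))
    all_entries = list(rates.entries)
    if rates.pop_rates is not None:
        all_entries += _expand_pop_rates(rates.pop_rates, n)
    coherence_pumping = False
    for i, j, k, l, r in all_entries:
        if not (0 <= i < n and 0 <= j < n and 0 <= k < n and 0 <= l < n):
            raise ValueError(f"rate entry index out of bounds: {(i, j, k, l)}")
        if (i != j or k != l) and not (i == k and j == l and r <= 0):
            coherence_pumping = True
        R[liouville_index(k, l, n), liouville_index(i, j, n)] += r
    if coherence_pumping:
        warnings.warn(
            "rate entries couple or pump coherences; positivity of the density "
            "matrix is not guaranteed",
            stacklevel=2,
        )
    return Superoperator(R, kind="relaxation")


def validate_rates(rates: RateSpec, n: int) -> str:
    """Classify the population flow of a rate specification.

    Returns 'conserving' (every population column sums to zero),
    'decaying' (some column sums negative, none positive — population
    leaves the spin system) or 'gaining' (a column sums positive, which
    is unphysical without an external source and triggers a warning).
    The T1/T2 model is conserving by construction and ignored here.
    """
    R = np.asarray(
        rate_superoperator(
            RateSpec(entries=rates.entries, pop_rates=rates.pop_rates, basis=rates.basis),
            n,
        )
    ).real
    tol = 1e-12
    sums = []
    for k in range(n):
        col = liouville_index(k, k, n)
        s = sum(R[liouville_index(i, i, n), col] for i in range(n))
        sums.append(s)
    if any(s > tol for s in sums):
        warnings.warn(
            "rate matrix gains population from outside the spin system", stacklevel=2
        )
        return "gaining"
    if any(s < -tol for s in sums):
        return "decaying"
    return "conserving"
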