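"""Tensor rotations and orientation grids for powder averaging.

A molecular orientation relative to the laboratory frame is described
by two Euler angles: a rotation by ϕ about z followed by a rotation by
ϑ about y (the third Euler angle is redundant for spectra that depend
only on the direction of B0 in the molecular frame and is fixed at
zero).  Interaction-tensor frames within the molecule may carry a full
ZYZ Euler triple.

Powder averages sum single-orientation spectra over a grid of (ϕ, ϑ)
pairs with equal weights.  Two grids are provided: a triangular
SOPHE-style mesh and a golden-angle Fibonacci spiral, both covering the
upper hemisphere (trEPR spectra are invariant under field inversion);
the SOPHE mesh can be restricted to one octant for tensors with
orthorhombic symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationGrid",
    "rotation_matrix",
    "euler_rotation",
    "rotate_tensor",
    "sophe_grid",
    "fibonacci_grid",
    "single_orientation",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class OrientationGrid:
    """Set of (ϕ, ϑ) pairs in radians with equal weights summing to 1."""

    angles: np.ndarray  # shape (N, 2): columns phi, theta
    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.angles.shape[0] != self.weights.shape[0]:
            raise ValueError("angles and weights lengths differ")

    def __len__(self) -> int:
        return self.angles.shape[0]

    def directions(self) -> np.ndarray:
        """Unit vectors (sinϑcosϕ, sinϑsinϕ, cosϑ) for every grid point."""
        phi, theta = self.angles[:, 0], self.angles[:, 1]
        return np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=1,
        )


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(phi: float, theta: float) -> np.ndarray:
    """Orientation rotation R = Ry(ϑ)·Rz(ϕ); proper orthogonal."""
    return _ry(theta) @ _rz(phi)


def euler_rotation(alpha: float, beta: float, gamma: float = 0.0) -> np.ndarray:
    """ZYZ Euler rotation Rz(α)·Ry(β)·Rz(γ) for tensor-frame tilts."""
    return _rz(alpha) @ _ry(beta) @ _rz(gamma)


def rotate_tensor(T: np.ndarray, phi: float, theta: float) -> np.ndarray:
    """Rotate a symmetric 3×3 tensor to the orientation (ϕ, ϑ): R T Rᵀ."""
    R = rotation_matrix(phi, theta)
    return R @ np.asarray(T, dtype=float) @ R.T


def sophe_grid(knots: int, coverage: str = "hemisphere") -> OrientationGrid:
    """Triangular SOPHE-style mesh.

    ``knots`` is the number of ϑ-increments between pole and equator.
    In octant mode ring i (ϑ = iπ/2k) carries i+1 points with
    ϕ ∈ [0, π/2], giving (k+1)(k+2)/2 points; hemisphere mode extends
    every ring to the full circle (4i points, one point at the pole).
    All points enter the powder sum with equal weight.
    """
    if knots < 1:
        raise ValueError("sophe_grid requires knots >= 1")
    if coverage not in ("hemisphere", "octant"):
        raise ValueError(f"unknown coverage '{coverage}'")
    pts = []
    for i in range(knots + 1):
        theta = 0.5 * np.pi * i / knots
        if i == 0:
            pts.append((0.0, 0.0))
            continue
        if coverage == "octant":
            for j in range(i + 1):
                pts.append((0.5 * np.pi * j / i, theta))
        else:
            for j in range(4 * i):
                pts.append((2.0 * np.pi * j / (4 * i), theta))
    angles = np.array(pts)
    n = len(pts)
    return OrientationGrid(angles, np.full(n, 1.0 / n), scheme="sophe")


def fibonacci_grid(N: int) -> OrientationGrid:
    """Golden-angle spiral with exactly N points on the upper hemisphere."""
    if N < 1:
        raise ValueError("fibonacci_grid requires N >= 1")
    i = np.arange(N)
    z = (N - i - 0.5) / N  # cosϑ from near-pole to near-equator
    theta = np.arccos(z)
    phi = np.mod(i * GOLDEN_ANGLE, 2.0 * np.pi)
    angles = np.stack([phi, theta], axis=1)
    return OrientationGrid(angles, np.full(N, 1.0 / N), scheme="fibonacci")


def single_orientation(phi: float = 0.0, theta: float = 0.0) -> OrientationGrid:
    """Grid with one explicit orientation (oriented-sample simulations)."""
    return OrientationGrid(np.array([[phi, theta]]), np.array([1.0]), scheme="single")
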