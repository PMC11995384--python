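"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the code paths they check:
``rk4_propagate`` integrates the stochastic Liouville equation with a
fixed-step classical Runge–Kutta scheme acting directly on the density
matrix, independent of the eigendecomposition/matrix-exponential
propagators in the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from treprsim.config import SimulationConfig
from treprsim.dynamics import rate_superoperator
from treprsim.fixtures import FIXTURE_NAMES, make_fixture
from treprsim.spectrum import _eigen_transform_super
from treprsim.spinsystem import (
    build_static_hamiltonian,
    microwave_hamiltonian,
    rotating_frame,
)


def rk4_propagate(G: np.ndarray, v0: np.ndarray, t_end: float, step: float = 1e-4):
    """Fixed-step RK4 integration of dv/dt = G v from 0 to t_end."""
    n_steps = int(round(t_end / step))
    v = v0.astype(complex).copy()
    h = t_end / n_steps if n_steps else step
    for _ in range(n_steps):
        k1 = G @ v
        k2 = G @ (v + 0.5 * h * k1)
        k3 = G @ (v + 0.5 * h * k2)
        k4 = G @ (v + h * k3)
        v = v + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return v


def fixture_propagation_problem(name: str, orientation=(0.0, 0.0)):
    """Central-field propagation problem (H_rot_total, R or None, rho0) of a fixture."""
    from treprsim.polarization import build_initial_density

    fx = make_fixture(name)
    cfg = SimulationConfig(fx.config)
    spec = cfg.spin_system()
    exp = cfg.experiment()
    dyn = cfg.dynamics()
    b0 = float(exp.B0_axis[exp.B0_axis.size // 2])
    H_lab = np.asarray(build_static_hamiltonian(spec, b0, orientation))
    H = np.asarray(rotating_frame(H_lab, exp.mw_freq, spec)) + np.asarray(
        microwave_hamiltonian(spec, exp.B1)
    )
    rho0 = np.asarray(build_initial_density(cfg.initial_state(), spec, b0, orientation))
    R = None
    if dyn.space == "liouville" and dyn.rates is not None and not dyn.rates.is_empty:
        R = np.asarray(rate_superoperator(dyn.rates, spec.dim))
        if dyn.rates.basis == "eigen":
            S = _eigen_transform_super(H_lab)
            R = S @ R @ S.conj().T
    return spec, H, R, rho0


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_name(request):
    return request.param
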