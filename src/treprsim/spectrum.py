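"""Field sweep, orientation loop and powder summation into 2-D datasets.

:func:`simulate` produces the simulator's central product: a
field × time matrix of the detected ⟨Sy⟩ signal, the computed analogue
of the experimental trEPR surface.  For every orientation of the grid
and every field point the interaction tensors are rotated, the
rotating-frame secular Hamiltonian (plus microwave term) is built, the
initial density matrix is constructed (per field point for the
field-dependent modes), the density matrix is propagated in the chosen
space and the signal detected; orientations are summed with equal
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .dynamics import RateSpec, Superoperator, rate_superoperator
from .orientation import OrientationGrid, single_orientation
from .polarization import InitialState, build_initial_density
from .propagation import apply_decay, propagate_hilbert, propagate_liouville
from .spinsystem import (
    ExperimentSpec,
    SpinSystemSpec,
    build_static_hamiltonian,
    microwave_hamiltonian,
    rotating_frame,
    total_spin_ops,
)

__all__ = [
    "DynamicsModel",
    "TrEPRDataset",
    "simulate",
    "population_evolution",
    "broaden_field",
    "slice_trace",
    "slice_spectrum",
]


@dataclass
class DynamicsModel:
    """Choice of propagation space and incoherent dynamics.

    ``space`` is 'hilbert' (fast; coherent dynamics only, optional
    exponential decay ``decay_k`` in μs⁻¹ applied to the signal) or
    'liouville' (dynamics superoperator from ``rates`` included).
    """

    space: str = "hilbert"
    rates: RateSpec | None = None
    decay_k: float | None = None

    def __post_init__(self) -> None:
        if self.space not in ("hilbert", "liouville"):
            raise ValueError("space must be 'hilbert' or 'liouville'")
        if self.space == "hilbert" and self.rates is not None and not self.rates.is_empty:
            raise ValueError(
                "rate superoperators require Liouville space; use space='liouville'"
            )
        if self.space == "liouville" and self.decay_k is not None:
            raise ValueError("decay_k is a Hilbert-space convenience; use rates instead")
        if self.decay_k is not None and self.decay_k < 0:
            raise ValueError("decay_k must be non-negative")


@dataclass
class TrEPRDataset:
    """Simulated trEPR surface: signal(field, time) plus metadata."""

    field_axis: np.ndarray  # mT
    time_axis: np.ndarray  # μs
    signal: np.ndarray  # (n_fields, n_times), real
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field_axis = np.asarray(self.field_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.field_axis.size, self.time_axis.size):
            raise ValueError("signal shape must be (n_fields, n_times)")


def _field_independent(initial: InitialState) -> bool:
    return initial.mode in ("singlet", "triplet-pnm", "custom")


def _eigen_transform_super(H_lab: np.ndarray) -> np.ndarray:
    """Unitary superoperator mapping eigenbasis vectors to working-basis vectors."""
    _, vecs = np.linalg.eigh(np.asarray(H_lab))
    return np.kron(vecs.conj(), vecs)


def simulate(
    spec: SpinSystemSpec,
    experiment: ExperimentSpec,
    initial: InitialState,
    dynamics: DynamicsModel | None = None,
    grid: OrientationGrid | None = None,
    metadata: dict | None = None,
) -> TrEPRDataset:
    """Run the full trEPR simulation and return the field × time dataset."""
    dynamics = dynamics or DynamicsModel()
    grid = grid if grid is not None else single_orientation()
    fields = experiment.B0_axis
    times = experiment.time_axis
    _, sy_tot, _ = total_spin_ops(spec)
    H1 = np.asarray(microwave_hamiltonian(spec, experiment.B1))
    n = spec.dim

    R_work: np.ndarray | None = None
    rates = dynamics.rates
    if dynamics.space == "liouville" and rates is not None and not rates.is_empty:
        R_work = np.asarray(rate_superoperator(rates, n))
    eigen_rates = rates is not None and rates.basis == "eigen"

    signal = np.zeros((fields.size, times.size))
    rho0_cached = None
    if _field_independent(initial):
        rho0_cached = np.asarray(build_initial_density(initial, spec, fields[0]))

    for (phi, theta), weight in zip(grid.angles, grid.weights):
        ori = (float(phi), float(theta))
        for fi, B0 in enumerate(fields):
            try:
                H_lab = np.asarray(build_static_hamiltonian(spec, B0, ori))
                H_rot = np.asarray(rotating_frame(H_lab, experiment.mw_freq, spec))
                H_tot = H_rot + H1
                if rho0_cached is not None:
                    rho0 = rho0_cached
                else:
                    rho0 = np.asarray(build_initial_density(initial, spec, B0, ori))
                if dynamics.space == "hilbert":
                    res = propagate_hilbert(H_tot, rho0, times, detect_op=sy_tot)
                else:
                    R = R_work
                    if R is not None and eigen_rates:
                        S = _eigen_transform_super(H_lab)
                        R = S @ R @ S.conj().T
                    res = propagate_liouville(H_tot, R, rho0, times, detect_op=sy_tot)
            except Exception as err:
                raise RuntimeError(
                    f"simulation failed at orientation (phi={phi:.4f}, theta={theta:.4f}), "
                    f"B0={B0:.4f} mT: {err}"
                ) from err
            signal[fi] += weight * res.signal

    if dynamics.space == "hilbert" and dynamics.decay_k:
        signal = apply_decay(signal, times, dynamics.decay_k)

    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    meta.update(
        {
            "kind": spec.kind,
            "space": dynamics.space,
            "grid_scheme": grid.scheme,
            "n_orientations": len(grid),
        }
    )
    return TrEPRDataset(fields, times, signal, meta)


def population_evolution(
    spec: SpinSystemSpec,
    experiment: ExperimentSpec,
    initial: InitialState,
    dynamics: DynamicsModel | None = None,
    B0: float | None = None,
    orientation: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstate populations p_i(t) at one field point and orientation.

    Populations are the diagonal of ρ(t) in the eigenbasis of the static
    Hamiltonian (microwave term excluded), labelled by ascending energy.
    Returns (times, populations) with populations of shape
    (n_times, dim).
    """
    dynamics = dynamics or DynamicsModel()
    if B0 is None:
        B0 = float(experiment.B0_axis[experiment.B0_axis.size // 2])
    times = experiment.time_axis
    H_lab = np.asarray(build_static_hamiltonian(spec, B0, orientation))
    H_rot = np.asarray(rotating_frame(H_lab, experiment.mw_freq, spec))
    H_tot = H_rot + np.asarray(microwave_hamiltonian(spec, experiment.B1))
    rho0 = np.asarray(build_initial_density(initial, spec, B0, orientation))
    if dynamics.space == "hilbert":
        res = propagate_hilbert(H_tot, rho0, times)
    else:
        R = None
        rates = dynamics.rates
        if rates is not None and not rates.is_empty:
            R = np.asarray(rate_superoperator(rates, spec.dim))
            if rates.basis == "eigen":
                S = _eigen_transform_super(H_lab)
                R = S @ R @ S.conj().T
        res = propagate_liouville(H_tot, R, rho0, times)
    _, vecs = np.linalg.eigh(H_lab)
    pops = np.einsum("ki,tkl,li->ti", vecs.conj(), res.densities, vecs).real
    return times, pops


def broaden_field(ds: TrEPRDataset, fwhm: float) -> TrEPRDataset:
    """Gaussian inhomogeneous broadening along the field axis.

    Convolves every time slice with an area-preserving Gaussian of the
    given full width at half maximum (mT); ``fwhm=0`` returns the
    dataset unchanged.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return ds
    steps = np.diff(ds.field_axis)
    if not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("field broadening requires a uniform field axis")
    step = steps[0]
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = max(1, int(np.ceil(4.0 * sigma / step)))
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    out = np.empty_like(ds.signal)
    for tj in range(ds.signal.shape[1]):
        out[:, tj] = np.convolve(ds.signal[:, tj], kernel, mode="same")
    meta = dict(ds.metadata)
    meta["field_broadening_fwhm_mT"] = fwhm
    return TrEPRDataset(ds.field_axis.copy(), ds.time_axis.copy(), out, meta)


def _nearest(axis: np.ndarray, value: float, name: str) -> int:
    if value < axis.min() - 1e-12 or value > axis.max() + 1e-12:
        raise ValueError(
            f"{name}={value} outside axis range [{axis.min()}, {axis.max()}]"
        )
    return int(np.argmin(np.abs(axis - value)))


def slice_trace(ds: TrEPRDataset, B0: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Kinetic trace at the nearest field point: (field used, times, signal)."""
    i = _nearest(ds.field_axis, B0, "B0")
    return float(ds.field_axis[i]), ds.time_axis.copy(), ds.signal[i].copy()


def slice_spectrum(ds: TrEPRDataset, t: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Field spectrum at the nearest time point: (time used, fields, signal)."""
    j = _nearest(ds.time_axis, t, "t")
    return float(ds.time_axis[j]), ds.field_axis.copy(), ds.signal[:, j].copy()
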