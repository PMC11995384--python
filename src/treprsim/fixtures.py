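"""Demonstration scenarios as runnable configurations with built-in checks.

Five scenarios cover the four spin systems and the main physical
phenomena the simulator is designed to reproduce:

``doublet_nutation``
    Isotropic doublet (g = 2.0) at 9.75 GHz, Hilbert space.  On-resonance
    kinetic traces show transient nutations (Torrey oscillations) whose
    frequency is proportional to B1.
``rp_zqc``
    Weakly coupled spin-correlated radical pair born in the singlet
    state; the trace at its resonance field shows transient nutations
    plus zero-quantum-coherence quantum beats.
``triplet_t1t2``
    Powder triplet with the phenomenological T1/T2 relaxation model in
    Liouville space: shorter T1 speeds up the signal decay, shorter T2
    broadens the spectrum.
``triplet_custom_rates``
    Same triplet with a custom rate matrix: unequal |T±⟩ ↔ |T0⟩
    spin–lattice rates make the spectrum asymmetric.
``tdp_reverse_quartet``
    Strongly exchange-coupled triplet–doublet pair in which the
    Q±1/2 levels drain into the doublet manifold at different rates,
    inverting the central net polarization over time while the
    multiplet wings keep their sign.

Coupling strengths are deliberately modest model values (the point is
the phenomenology, not any particular compound); they also keep the
fixed-step integrator used as a numerical cross-check well inside its
accuracy range.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, parse_config, serialize_config
from .spectrum import simulate, slice_spectrum, slice_trace
from .spinsystem import build_static_hamiltonian

__all__ = [
    "Fixture",
    "FIXTURE_NAMES",
    "make_fixture",
    "run_fixture",
    "dominant_frequency",
]

FIXTURE_NAMES = (
    "doublet_nutation",
    "rp_zqc",
    "triplet_t1t2",
    "triplet_custom_rates",
    "tdp_reverse_quartet",
)


@dataclass
class Fixture:
    """A named scenario: full configuration plus check descriptions."""

    name: str
    config: dict
    checks: list[str] = field(default_factory=list)

    def parsed(self) -> SimulationConfig:
        return parse_config(serialize_config(SimulationConfig(self.config)))

    def to_yaml(self) -> str:
        return serialize_config(SimulationConfig(self.config))


def dominant_frequency(times: np.ndarray, signal: np.ndarray, n_peaks: int = 1):
    """Dominant oscillation frequencies (MHz) of a kinetic trace.

    Hann-windowed, zero-padded FFT with parabolic peak interpolation;
    returns the ``n_peaks`` largest local maxima sorted by amplitude.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    dt = times[1] - times[0]
    sig = signal - signal.mean()
    sig = sig * np.hanning(sig.size)
    n_fft = 8 * sig.size
    spec = np.abs(np.fft.rfft(sig, n_fft))
    freqs = np.fft.rfftfreq(n_fft, dt)  # MHz (times in μs)
    peaks = []
    for k in range(2, spec.size - 1):
        if spec[k] > spec[k - 1] and spec[k] >= spec[k + 1]:
            a, b, c = spec[k - 1], spec[k], spec[k + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
            peaks.append((b, freqs[k] + shift * (freqs[1] - freqs[0])))
    peaks.sort(reverse=True)
    return [f for _, f in peaks[:n_peaks]]


def _base(kind_cfg: dict, exp: dict, pop: dict, dyn: dict, opt: dict) -> dict:
    return {
        "schema": 1,
        "Sys": kind_cfg,
        "Exp": exp,
        "Pop": pop,
        "Dyn": dyn,
        "Opt": opt,
    }


_TRIPLET_SYS = {"kind": "trip", "g": 2.002, "D": 45.0, "E": 9.0}


def _coupled_state_indices(config: dict, B0: float) -> dict[str, int]:
    """Map quartet/doublet labels to ascending-energy eigenstate indices.

    The coupled |S_tot, m⟩ states of a triplet–doublet pair are built
    from Clebsch–Gordan coefficients in the product basis and matched
    to the eigenstates of the static Hamiltonian by maximum overlap.
    """
    spec = SimulationConfig(config).spin_system()
    s = np.sqrt(np.array([1.0 / 3.0, 2.0 / 3.0]))
    states = {
        "Q+3/2": np.eye(6)[0],
        "Q+1/2": s[0] * np.eye(6)[1] + s[1] * np.eye(6)[2],
        "Q-1/2": s[1] * np.eye(6)[3] + s[0] * np.eye(6)[4],
        "Q-3/2": np.eye(6)[5],
        "D+1/2": s[1] * np.eye(6)[1] - s[0] * np.eye(6)[2],
        "D-1/2": s[0] * np.eye(6)[3] - s[1] * np.eye(6)[4],
    }
    H = np.asarray(build_static_hamiltonian(spec, B0))
    _, vecs = np.linalg.eigh(H)
    out = {}
    taken: set[int] = set()
    for label, v in states.items():
        overlaps = np.abs(vecs.conj().T @ v) ** 2
        for idx in np.argsort(-overlaps):
            if int(idx) not in taken:
                out[label] = int(idx)
                taken.add(int(idx))
                break
    return out


def _coherence_damping(n: int, rate: float) -> list[list]:
    return [[i, j, i, j, -rate] for i in range(n) for j in range(n) if i != j]


def make_fixture(name: str) -> Fixture:
    if name == "doublet_nutation":
        cfg = _base(
            {"kind": "doub", "g": 2.0},
            {
                "mwFreq": 9.75,
                "Range": [346.3, 350.3],
                "nPoints": 81,
                "B1": 0.1,
                "tMax": 2.0,
                "nTimePoints": 501,
            },
            {"Mode": "eigen", "Eigen": [1.0, 0.0]},
            {"space": "hilbert"},
            {"GridType": "single"},
        )
        return Fixture(
            name,
            cfg,
            checks=[
                "resonance: field of max |signal| at 348.3 mT (one field step)",
                "nutation frequency doubles when B1 doubles (ratio 2.00 +/- 0.05)",
                "on-resonance trace obeys |<Sy>| = (1/2)|dp sin(w1 t)|",
            ],
        )
    if name == "rp_zqc":
        cfg = _base(
            {"kind": "rp", "g": [2.0030, 2.0047], "J": 1.0, "dip": [1.0, 1.0, -2.0]},
            {
                "mwFreq": 9.75,
                "Range": [346.6, 348.6],
                "nPoints": 101,
                "B1": 0.1,
                "tMax": 2.0,
                "nTimePoints": 2001,
            },
            {"Mode": "singlet"},
            {"space": "hilbert"},
            {"GridType": "single"},
        )
        return Fixture(
            name,
            cfg,
            checks=[
                "trace at the resonance field contains >= 2 distinct oscillation peaks",
                "peak frequencies match eigenvalue differences of the rotating-frame generator",
            ],
        )
    if name == "triplet_t1t2":
        cfg = _base(
            dict(_TRIPLET_SYS),
            {
                "mwFreq": 9.75,
                "Range": [345.46, 350.46],
                "nPoints": 101,
                "B1": 0.1,
                "tMax": 6.0,
                "nTimePoints": 241,
            },
            {"Mode": "zf", "Triplet": [0.0, 0.5, 0.5]},
            {"space": "liouville", "T1": 5.0, "T2": 5.0},
            {"GridType": "fibonacci", "nOrientations": 40, "Broadening": 0.2},
        )
        return Fixture(
            name,
            cfg,
            checks=[
                "T1 = 1 us decays faster than T1 = 5 us (late-time integrated |signal|)",
                "T2 = 0.1 us spectrum at t = 1 us has larger second moment than T2 = 5 us",
            ],
        )
    if name == "triplet_custom_rates":
        dyn = {
            "space": "liouville",
            "RateBasis": "eigen",
            # ascending energy: 0 = T-, 1 = T0, 2 = T+; fast T+<->T0, slow T-<->T0
            "PopRates": [[0.0, 0.2, 0.0], [0.2, 0.0, 2.0], [0.0, 2.0, 0.0]],
            "Rates": _coherence_damping(3, 2.0),
        }
        cfg = _base(
            dict(_TRIPLET_SYS),
            {
                "mwFreq": 9.75,
                "Range": [345.46, 350.46],
                "nPoints": 101,
                "B1": 0.1,
                "tMax": 0.5,
                "nTimePoints": 51,
            },
            {"Mode": "zf", "Triplet": [0.0, 0.5, 0.5]},
            dyn,
            {"GridType": "fibonacci", "nOrientations": 40, "Broadening": 0.2},
        )
        return Fixture(
            name,
            cfg,
            checks=[
                "unequal |T+->|T0> and |T->|T0> rates give an asymmetric spectrum at t = 0.5 us",
            ],
        )
    if name == "tdp_reverse_quartet":
        sys_cfg = {
            "kind": "tdp",
            "g": [2.003, 2.005],
            "J": -12.0,
            "D": 20.0,
            "E": 0.0,
            "dip": [1.0, 1.0, -2.0],
        }
        from .constants import field_for_frequency

        # centre the sweep on the quartet-manifold resonance g_Q = (2gT + gd)/3
        g_q = (2.0 * sys_cfg["g"][0] + sys_cfg["g"][1]) / 3.0
        center = round(field_for_frequency(g_q, 9.75), 4)
        exp_cfg = {
            "mwFreq": 9.75,
            "Range": [center - 1.0, center + 1.0],
            "nPoints": 81,
            "B1": 0.01,
            "tMax": 3.0,
            "nTimePoints": 301,
        }
        partial = _base(sys_cfg, exp_cfg, {"Mode": "triplet-pnm"}, {}, {})
        idx = _coupled_state_indices(partial, center)
        q_plus, q_minus = idx["Q+1/2"], idx["Q-1/2"]
        d_plus, d_minus = idx["D+1/2"], idx["D-1/2"]
        r_fast, r_slow = 2.0, 0.2
        rates = [
            [q_plus, q_plus, d_plus, d_plus, r_fast],
            [q_plus, q_plus, q_plus, q_plus, -r_fast],
            [q_minus, q_minus, d_minus, d_minus, r_slow],
            [q_minus, q_minus, q_minus, q_minus, -r_slow],
        ] + _coherence_damping(6, 3.0)
        cfg = _base(
            sys_cfg,
            exp_cfg,
            {"Mode": "triplet-pnm", "Triplet": [0.6, 0.3, 0.1], "Doublet": [0.5, 0.5]},
            {"space": "liouville", "RateBasis": "eigen", "Rates": rates},
            {"GridType": "single"},
        )
        return Fixture(
            name,
            cfg,
            checks=[
                "central net-polarization signal changes sign over time",
                "multiplet wing signal keeps its sign",
            ],
        )
    raise ValueError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# check runners


def _simulate_config(config: dict):
    cfg = SimulationConfig(copy.deepcopy(config))
    ds = simulate(
        cfg.spin_system(),
        cfg.experiment(),
        cfg.initial_state(),
        cfg.dynamics(),
        cfg.grid(),
    )
    if cfg.broadening > 0:
        from .spectrum import broaden_field

        ds = broaden_field(ds, cfg.broadening)
    return cfg, ds


def _check_doublet(fx: Fixture) -> dict:
    from .constants import zeeman_angular

    results = {}
    cfg, ds = _simulate_config(fx.config)
    peak_field = ds.field_axis[np.argmax(np.max(np.abs(ds.signal), axis=1))]
    step = ds.field_axis[1] - ds.field_axis[0]
    results["resonance_field"] = {
        "passed": bool(abs(peak_field - 348.3) <= step + 1e-9),
        "value": float(peak_field),
    }
    freqs = []
    for b1 in (fx.config["Exp"]["B1"], 2 * fx.config["Exp"]["B1"]):
        c = copy.deepcopy(fx.config)
        c["Exp"]["B1"] = b1
        _, dsb = _simulate_config(c)
        _, t, trace = slice_trace(dsb, 348.3)
        freqs.append(dominant_frequency(t, trace)[0])
    ratio = freqs[1] / freqs[0]
    results["nutation_b1_ratio"] = {
        "passed": bool(abs(ratio - 2.0) <= 0.05),
        "value": float(ratio),
    }
    # closed-form Rabi check at the exact resonance field
    from .constants import field_for_frequency
    from .polarization import build_initial_density
    from .propagation import propagate_hilbert
    from .spinsystem import (
        microwave_hamiltonian,
        rotating_frame,
        total_spin_ops,
    )

    spec = cfg.spin_system()
    exp = cfg.experiment()
    g = fx.config["Sys"]["g"]
    b_res = field_for_frequency(g, exp.mw_freq)
    H = np.asarray(
        rotating_frame(build_static_hamiltonian(spec, b_res), exp.mw_freq, spec)
    ) + np.asarray(microwave_hamiltonian(spec, exp.B1))
    rho0 = np.asarray(build_initial_density(cfg.initial_state(), spec, b_res))
    _, sy, _ = total_spin_ops(spec)
    res = propagate_hilbert(H, rho0, exp.time_axis, detect_op=sy)
    w1 = zeeman_angular(g, exp.B1)
    err = np.max(np.abs(np.abs(res.signal) - 0.5 * np.abs(np.sin(w1 * exp.time_axis))))
    results["rabi_closed_form"] = {"passed": bool(err < 1e-6), "value": float(err)}
    return results


def _check_rp(fx: Fixture) -> dict:
    from .spinsystem import microwave_hamiltonian, rotating_frame

    cfg, ds = _simulate_config(fx.config)
    peak_field = ds.field_axis[np.argmax(np.max(np.abs(ds.signal), axis=1))]
    _, t, trace = slice_trace(ds, peak_field)
    peaks = dominant_frequency(t, trace, n_peaks=4)
    distinct = [peaks[0]]
    for p in peaks[1:]:
        if all(abs(p - q) > 0.5 for q in distinct):
            distinct.append(p)
    results = {
        "n_oscillation_peaks": {
            "passed": bool(len(distinct) >= 2),
            "value": float(len(distinct)),
        }
    }
    spec = cfg.spin_system()
    exp = cfg.experiment()
    H = np.asarray(
        rotating_frame(build_static_hamiltonian(spec, peak_field), exp.mw_freq, spec)
    ) + np.asarray(microwave_hamiltonian(spec, exp.B1))
    ev = np.linalg.eigvalsh(H)
    gaps = np.abs(np.subtract.outer(ev, ev)) / (2 * np.pi)  # MHz
    df = 2.0 / (t[-1] - t[0]) if t[-1] > t[0] else 1.0
    ok = all(np.min(np.abs(gaps - p)) < 2 * df for p in distinct[:2])
    results["peaks_match_eigengaps"] = {
        "passed": bool(ok),
        "value": float(max(np.min(np.abs(gaps - p)) for p in distinct[:2])),
    }
    return results


def _late_time_signal(ds) -> float:
    mask = ds.time_axis >= 0.5 * ds.time_axis[-1]
    return float(np.sum(np.abs(ds.signal[:, mask])))


def _second_moment(fields: np.ndarray, spec_slice: np.ndarray) -> float:
    w = np.abs(spec_slice)
    w = w / w.sum()
    mu = np.sum(w * fields)
    return float(np.sum(w * (fields - mu) ** 2))


def _check_t1t2(fx: Fixture) -> dict:
    results = {}
    _, ds_base = _simulate_config(fx.config)
    short_t1 = copy.deepcopy(fx.config)
    short_t1["Dyn"]["T1"] = 1.0
    _, ds_t1 = _simulate_config(short_t1)
    results["short_T1_decays_faster"] = {
        "passed": bool(_late_time_signal(ds_t1) < _late_time_signal(ds_base)),
        "value": float(_late_time_signal(ds_t1) / _late_time_signal(ds_base)),
    }
    short_t2 = copy.deepcopy(fx.config)
    short_t2["Dyn"]["T2"] = 0.1
    _, ds_t2 = _simulate_config(short_t2)
    _, f, s_base = slice_spectrum(ds_base, 1.0)
    _, _, s_t2 = slice_spectrum(ds_t2, 1.0)
    m_base, m_t2 = _second_moment(f, s_base), _second_moment(f, s_t2)
    results["short_T2_broader"] = {
        "passed": bool(m_t2 > m_base),
        "value": float(m_t2 / m_base),
    }
    return results


def _asymmetry(fields: np.ndarray, spec_slice: np.ndarray) -> float:
    """Norm of the symmetric part about the spectrum centre (antisymmetric -> 0)."""
    sym = spec_slice + spec_slice[::-1]
    return float(np.linalg.norm(sym) / np.linalg.norm(spec_slice))


def _check_custom_rates(fx: Fixture) -> dict:
    _, ds = _simulate_config(fx.config)
    _, f, s = slice_spectrum(ds, 0.5)
    symmetric = copy.deepcopy(fx.config)
    symmetric["Dyn"]["PopRates"] = [[0.0, 2.0, 0.0], [2.0, 0.0, 2.0], [0.0, 2.0, 0.0]]
    _, ds_sym = _simulate_config(symmetric)
    _, _, s_sym = slice_spectrum(ds_sym, 0.5)
    a, a_sym = _asymmetry(f, s), _asymmetry(f, s_sym)
    return {
        "asymmetric_rates_break_symmetry": {
            "passed": bool(a > 2.0 * a_sym),
            "value": float(a / max(a_sym, 1e-30)),
        }
    }


def _windowed_means(ds, B0: float) -> tuple[float, float]:
    _, t, trace = slice_trace(ds, B0)
    early = trace[(t >= 0.05) & (t <= 0.25)].mean()
    late = trace[t >= 0.5 * t[-1]].mean()
    return float(early), float(late)


def _resonance_field(config: dict, pair: tuple[str, str]) -> float:
    """Field at which a labelled transition crosses the microwave frequency."""
    from .constants import GHZ_TO_ANGULAR

    cfg = SimulationConfig(config)
    spec = cfg.spin_system()
    exp = cfg.experiment()
    omega = exp.mw_freq * GHZ_TO_ANGULAR
    best, best_field = np.inf, exp.B0_axis[0]
    for b in exp.B0_axis:
        idx = _coupled_state_indices(config, float(b))
        ev = np.linalg.eigvalsh(np.asarray(build_static_hamiltonian(spec, float(b))))
        offset = abs(abs(ev[idx[pair[0]]] - ev[idx[pair[1]]]) - omega)
        if offset < best:
            best, best_field = offset, float(b)
    return best_field


def _check_rqm(fx: Fixture) -> dict:
    _, ds = _simulate_config(fx.config)
    central_field = _resonance_field(fx.config, ("Q+1/2", "Q-1/2"))
    wing_field = _resonance_field(fx.config, ("Q+3/2", "Q+1/2"))
    c_early, c_late = _windowed_means(ds, central_field)
    w_early, w_late = _windowed_means(ds, wing_field)
    return {
        "central_polarization_inverts": {
            "passed": bool(c_early * c_late < 0),
            "value": float(c_late / c_early) if c_early else float("nan"),
        },
        "wings_keep_sign": {
            "passed": bool(w_early * w_late > 0),
            "value": float(w_late / w_early) if w_early else float("nan"),
        },
    }


_CHECKERS = {
    "doublet_nutation": _check_doublet,
    "rp_zqc": _check_rp,
    "triplet_t1t2": _check_t1t2,
    "triplet_custom_rates": _check_custom_rates,
    "tdp_reverse_quartet": _check_rqm,
}


def run_fixture(fixture: Fixture | str) -> dict:
    """Execute a fixture's checks; returns {check: {passed, value}}."""
    fx = make_fixture(fixture) if isinstance(fixture, str) else fixture
    return _CHECKERS[fx.name](fx)
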