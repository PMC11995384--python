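"""YAML configuration parsing and validation.

A simulation is described by a YAML document with EasySpin-style key
groups::

    schema: 1
    Sys:                      # spin system
      kind: trip              # doub | rp | trip | tdp
      g: 2.002                # scalar / 3 principal values / list per spin
      gFrame: [0, 0, 0]       # Euler angles in radians (per spin for pairs)
      D: 45.0                 # ZFS D in MHz (trip, tdp)
      E: 9.0                  # ZFS E in MHz
      DFrame: [0, 0, 0]
      J: 1.0                  # exchange in MHz (rp, tdp)
      dip: [1, 1, -2]         # dipolar principal values in MHz (rp, tdp)
      dipFrame: [0, 0, 0]
    Exp:
      mwFreq: 9.75            # GHz
      Range: [344, 352]       # mT
      nPoints: 161
      B1: 0.1                 # mT (rotating-frame amplitude)
      tMax: 2.0               # μs
      nTimePoints: 501
    Pop:
      Mode: eigen             # eigen | zf | singlet | triplet-pnm | triplet-zf | custom
      Eigen: [1, 0]           # eigen mode, ascending energy
      Triplet: [0, 0, 1]      # zf (ascending ZF energy) or pnm (p+, p0, p−)
      Doublet: [0.5, 0.5]     # tdp only
      Custom: [[...], ...]    # custom mode (inline) — may be complex
      Normalize: unit         # unit | raw
    Dyn:
      space: hilbert          # hilbert | liouville
      T1: 5.0                 # μs (liouville)
      T2: 5.0                 # μs
      DecayRate: 0.0          # μs⁻¹ (hilbert, exponential signal decay)
      Rates: [[i, j, k, l, r], ...]   # raw element rates, r in μs⁻¹
      PopRates: [[...], ...]  # n×n kinetics matrix, destination row × source column
      RateBasis: working      # working | eigen
    Opt:
      GridType: single        # single | sophe | fibonacci
      nKnots: 10              # sophe
      nOrientations: 100      # fibonacci
      Orientation: [0, 0]     # (ϕ, ϑ) radians, single mode
      Coverage: hemisphere    # sophe: hemisphere | octant
      Broadening: 0.0         # Gaussian field broadening FWHM in mT

Unknown keys are hard errors; defaults are as shown.  Parsing then
serializing then parsing again is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .dynamics import RateSpec
from .orientation import OrientationGrid, fibonacci_grid, single_orientation, sophe_grid
from .polarization import InitialState
from .spectrum import DynamicsModel
from .spinsystem import ExperimentSpec, SpinSystemSpec, TensorSpec

__all__ = ["SimulationConfig", "parse_config", "serialize_config", "load_config"]

_ALLOWED = {
    "": {"schema", "Sys", "Exp", "Pop", "Dyn", "Opt"},
    "Sys": {"kind", "g", "gFrame", "J", "D", "E", "DFrame", "dip", "dipFrame"},
    "Exp": {"mwFreq", "Range", "nPoints", "B1", "tMax", "nTimePoints"},
    "Pop": {"Mode", "Eigen", "Triplet", "Doublet", "Custom", "CustomFile", "Normalize"},
    "Dyn": {"space", "T1", "T2", "DecayRate", "Rates", "PopRates", "RateBasis", "RateFile"},
    "Opt": {
        "GridType",
        "nKnots",
        "nOrientations",
        "Orientation",
        "Coverage",
        "Broadening",
    },
}

_SYS_KEYS_BY_KIND = {
    "doub": {"kind", "g", "gFrame"},
    "rp": {"kind", "g", "gFrame", "J", "dip", "dipFrame"},
    "trip": {"kind", "g", "gFrame", "D", "E", "DFrame"},
    "tdp": {"kind", "g", "gFrame", "J", "D", "E", "DFrame", "dip", "dipFrame"},
}


class ConfigError(ValueError):
    """Configuration validation failure; the message names the key path."""


def _check_keys(mapping: dict, group: str) -> None:
    allowed = _ALLOWED[group]
    for key in mapping:
        if key not in allowed:
            prefix = f"{group}." if group else ""
            raise ConfigError(f"unknown configuration key '{prefix}{key}'")


def _require(mapping: dict, key: str, group: str):
    if key not in mapping:
        raise ConfigError(f"missing required key '{group}.{key}'")
    return mapping[key]


@dataclass
class SimulationConfig:
    """Validated configuration; ``raw`` is the normalized YAML mapping."""

    raw: dict
    base_dir: Path | None = None

    # -- builders -----------------------------------------------------
    def spin_system(self) -> SpinSystemSpec:
        sys = self.raw["Sys"]
        kind = sys["kind"]
        n_spins = 2 if kind in ("rp", "tdp") else 1
        g_raw = sys["g"]
        frames = sys.get("gFrame")
        if n_spins == 2:
            if not isinstance(g_raw, list) or len(g_raw) != 2:
                raise ConfigError(f"Sys.g must list two entries for kind '{kind}'")
            g_entries = g_raw
            frame_entries = frames if frames is not None else [None, None]
        else:
            g_entries = [g_raw]
            frame_entries = [frames]
        g_tensors = []
        for g, fr in zip(g_entries, frame_entries):
            g_tensors.append(TensorSpec(g, tuple(fr) if fr else (0.0, 0.0, 0.0)))
        kwargs: dict = {"kind": kind, "g": g_tensors}
        if "J" in sys:
            kwargs["J"] = float(sys["J"])
        if "D" in sys:
            kwargs["D"] = float(sys["D"])
            kwargs["E"] = float(sys.get("E", 0.0))
            if "DFrame" in sys:
                kwargs["D_frame"] = tuple(sys["DFrame"])
        if "dip" in sys:
            kwargs["dipolar"] = TensorSpec(
                sys["dip"], tuple(sys.get("dipFrame", (0.0, 0.0, 0.0)))
            )
        try:
            return SpinSystemSpec(**kwargs)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"Sys: {err}") from err

    def experiment(self) -> ExperimentSpec:
        exp = self.raw["Exp"]
        lo, hi = _require(exp, "Range", "Exp")
        n = int(_require(exp, "nPoints", "Exp"))
        t_max = float(_require(exp, "tMax", "Exp"))
        nt = int(_require(exp, "nTimePoints", "Exp"))
        try:
            return ExperimentSpec(
                mw_freq=float(_require(exp, "mwFreq", "Exp")),
                B0_axis=np.linspace(float(lo), float(hi), n),
                B1=float(_require(exp, "B1", "Exp")),
                time_axis=np.linspace(0.0, t_max, nt),
            )
        except ValueError as err:
            raise ConfigError(f"Exp: {err}") from err

    def initial_state(self) -> InitialState:
        pop = self.raw["Pop"]
        custom = pop.get("Custom")
        if custom is None and "CustomFile" in pop:
            path = Path(pop["CustomFile"])
            if self.base_dir is not None and not path.is_absolute():
                path = self.base_dir / path
            custom = np.loadtxt(path, dtype=complex)
        elif custom is not None:
            custom = np.array(
                [[complex(x) for x in row] for row in custom], dtype=complex
            )
        try:
            return InitialState(
                mode=_require(pop, "Mode", "Pop"),
                populations=pop.get("Eigen"),
                triplet=pop.get("Triplet"),
                doublet=pop.get("Doublet"),
                custom_matrix=custom,
                normalize=pop.get("Normalize", "unit"),
            )
        except ValueError as err:
            raise ConfigError(f"Pop: {err}") from err

    def dynamics(self) -> DynamicsModel:
        dyn = self.raw.get("Dyn", {})
        entries = [tuple(e[:4]) + (float(e[4]),) for e in dyn.get("Rates", [])]
        entries = [(int(i), int(j), int(k), int(l), r) for i, j, k, l, r in entries]
        if "RateFile" in dyn:
            path = Path(dyn["RateFile"])
            if self.base_dir is not None and not path.is_absolute():
                path = self.base_dir / path
            table = np.atleast_2d(np.loadtxt(path))
            entries += [
                (int(i), int(j), int(k), int(l), float(r)) for i, j, k, l, r in table
            ]
        rates = None
        if entries or "T1" in dyn or "PopRates" in dyn:
            try:
                rates = RateSpec(
                    T1=dyn.get("T1"),
                    T2=dyn.get("T2"),
                    entries=entries,
                    pop_rates=dyn.get("PopRates"),
                    basis=dyn.get("RateBasis", "working"),
                )
            except ValueError as err:
                raise ConfigError(f"Dyn: {err}") from err
        try:
            return DynamicsModel(
                space=dyn.get("space", "hilbert"),
                rates=rates,
                decay_k=dyn.get("DecayRate"),
            )
        except ValueError as err:
            raise ConfigError(f"Dyn: {err}") from err

    def grid(self) -> OrientationGrid:
        opt = self.raw.get("Opt", {})
        gtype = opt.get("GridType", "single")
        if gtype == "single":
            ori = opt.get("Orientation", (0.0, 0.0))
            return single_orientation(float(ori[0]), float(ori[1]))
        if gtype == "sophe":
            return sophe_grid(
                int(opt.get("nKnots", 10)), opt.get("Coverage", "hemisphere")
            )
        if gtype == "fibonacci":
            return fibonacci_grid(int(opt.get("nOrientations", 100)))
        raise ConfigError(f"Opt.GridType: unknown grid type '{gtype}'")

    @property
    def broadening(self) -> float:
        return float(self.raw.get("Opt", {}).get("Broadening", 0.0))


def parse_config(text: str, base_dir: str | Path | None = None) -> SimulationConfig:
    """Parse and validate a YAML configuration document."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"invalid YAML: {err}") from err
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a YAML mapping")
    _check_keys(data, "")
    schema = data.get("schema", 1)
    if schema != 1:
        raise ConfigError(f"unsupported schema version {schema!r}")
    for group in ("Sys", "Exp", "Pop"):
        if group not in data:
            raise ConfigError(f"missing required group '{group}'")
    for group in ("Sys", "Exp", "Pop", "Dyn", "Opt"):
        if group in data:
            if not isinstance(data[group], dict):
                raise ConfigError(f"group '{group}' must be a mapping")
            _check_keys(data[group], group)
    sys = data["Sys"]
    kind = _require(sys, "kind", "Sys")
    if kind not in _SYS_KEYS_BY_KIND:
        raise ConfigError(f"Sys.kind: unknown spin-system kind '{kind}'")
    for key in sys:
        if key not in _SYS_KEYS_BY_KIND[kind]:
            raise ConfigError(f"key 'Sys.{key}' is not allowed for kind '{kind}'")
    data.setdefault("schema", 1)
    cfg = SimulationConfig(
        raw=data, base_dir=Path(base_dir) if base_dir is not None else None
    )
    # build everything once so key errors surface at parse time
    cfg.spin_system()
    cfg.experiment()
    cfg.initial_state()
    cfg.dynamics()
    cfg.grid()
    return cfg


def serialize_config(cfg: SimulationConfig) -> str:
    """Serialize back to YAML; parse(serialize(x)) == x."""
    return yaml.safe_dump(cfg.raw, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    return parse_config(path.read_text(), base_dir=path.parent)
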