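# treprsim

Simulation of **time-resolved (transient continuous-wave) EPR spectra** of
spin-polarized multi-spin systems.

In a trEPR experiment a nanosecond laser pulse creates a paramagnetic species
with strongly non-Boltzmann level populations; the direct-detected EPR response
is then recorded as a function of time at a series of static magnetic fields,
giving a 2-D field × time surface with absorptive (positive) and emissive
(negative) lines.  `treprsim` computes this surface by modeling the experiment:
it propagates the density matrix under the stochastic Liouville equation

dρ̂/dt = −i [Ĥ, ρ̂] + R̂̂ ρ̂

with a time-independent rotating-frame secular spin Hamiltonian Ĥ (Zeeman,
microwave, exchange −J(½ + 2 Ŝ₁·Ŝ₂), secular dipolar coupling and zero-field
splitting) and a dynamics superoperator R̂̂ whose rate elements are set directly
(phenomenological T₁/T₂, first-order population kinetics, or arbitrary element
rates).  The detected signal is ⟨Ŝy⟩ = Tr(Ŝy ρ̂).

It is aimed at EPR spectroscopists analyzing photoexcited doublets, triplets,
spin-correlated radical pairs (SCRPs) and triplet–doublet (quartet) systems —
phenomena such as transient nutations (Torrey oscillations), zero-quantum
quantum beats, T₁/T₂ relaxation effects and the reverse-quartet mechanism.

## Features

* Four predefined spin systems: doublet (`doub`), spin-correlated radical pair
  (`rp`, singlet–triplet basis), triplet (`trip`, high-field basis with ZFS
  parameters D and E), triplet–doublet pair (`tdp`, product basis).
* Initial polarizations: eigenstate populations, zero-field triplet
  populations, singlet or triplet precursor for pairs, Kronecker-product states
  for the triplet–doublet pair, or a custom density matrix.
* Hilbert-space propagation (fast, coherent dynamics, optional exponential
  signal decay) or Liouville-space propagation with relaxation superoperators.
* Powder averaging on SOPHE-style or Fibonacci orientation grids, or oriented
  samples via explicit Euler angles.
* Field-swept 2-D datasets, kinetic traces, eigenstate-population evolutions,
  Gaussian field broadening; CSV and HDF5 writers; a YAML configuration
  interface with EasySpin-style key groups and a `treprsim` command line.

## Worked example

Kinetic trace of an isotropic doublet (g = 2.0) driven on resonance at
9.75 GHz — the textbook transient-nutation case:

```python
import numpy as np
from treprsim import (SpinSystemSpec, TensorSpec, ExperimentSpec,
                      InitialState, simulate, slice_trace)

spec = SpinSystemSpec(kind="doub", g=[TensorSpec(2.0)])
exp = ExperimentSpec(mw_freq=9.75,                      # GHz
                     B0_axis=np.arange(344.0, 352.05, 0.05),  # mT
                     B1=0.1,                            # mT
                     time_axis=np.linspace(0, 2, 501))  # μs
init = InitialState("eigen", populations=[1.0, 0.0])    # lower level populated

ds = simulate(spec, exp, init)
peak = ds.field_axis[np.argmax(np.max(np.abs(ds.signal), axis=1))]
print(f"resonance field: {peak:.2f} mT")

b_used, t, trace = slice_trace(ds, peak)
print(f"max signal {trace.max():.3f} at t = {t[np.argmax(trace)]:.3f} us")
```

Output:

```
resonance field: 348.30 mT
max signal 0.498 at t = 0.088 us
```

The maximum-|signal| field 348.30 mT is the resonance field of g = 2.0 at
9.75 GHz (hν/gμB = 348.31 mT, found to within one 0.05 mT field step), and the
trace oscillates as ½|sin(ω₁t)| — the transient nutation at
ν₁ = gμB·B1/h = 2.80 MHz for B1 = 0.1 mT, so the first maximum (amplitude ½,
slightly less at the nearest grid field) occurs at 1/(4ν₁) ≈ 0.089 μs.
Positive signal means microwave absorption.

Five demonstration scenarios with built-in physics checks ship with the
package:

```bash
treprsim fixtures emit doublet_nutation --out doub.yaml
treprsim simulate doub.yaml --out doub.csv
treprsim fixtures run rp_zqc        # transient nutations + quantum beats
```

Available scenarios: `doublet_nutation`, `rp_zqc`, `triplet_t1t2`,
`triplet_custom_rates`, `tdp_reverse_quartet`.

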