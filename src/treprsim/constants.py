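"""Physical constants and unit conversions.

Internal Hamiltonians are expressed in angular-frequency units of
rad·μs⁻¹.  User-facing quantities follow the conventions common in EPR
spectroscopy: static and microwave fields in mT, microwave frequency in
GHz, couplings (J, D, E, dipolar) in MHz, times in μs and rates in μs⁻¹.
"""

import numpy as np

#: Bohr magneton, J/T (CODATA 2018)
MU_B = 9.2740100783e-24
#: Planck constant, J·s (exact, SI 2019)
H_PLANCK = 6.62607015e-34
#: Reduced Planck constant, J·s
HBAR = H_PLANCK / (2.0 * np.pi)

#: MHz -> rad·μs⁻¹
MHZ_TO_ANGULAR = 2.0 * np.pi
#: GHz -> rad·μs⁻¹
GHZ_TO_ANGULAR = 2.0 * np.pi * 1.0e3


def zeeman_angular(g: float, B_mT: float) -> float:
    """Electron Zeeman angular frequency g·μB·B/ħ in rad·μs⁻¹ for B in mT."""
    return g * MU_B * (B_mT * 1.0e-3) / HBAR * 1.0e-6


def field_for_frequency(g: float, freq_GHz: float) -> float:
    """Resonance field in mT of an isotropic g value at a given frequency."""
    return H_PLANCK * freq_GHz * 1.0e9 / (g * MU_B) * 1.0e3
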