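"""Physical constants and unit conversions, single-sourced.

Internal unit policy: lengths in Å, times in ns, energies in kcal/mol,
charges in elementary charge e.  Reported quantities use s⁻¹ and M.
"""

import math

#: Boltzmann constant, kcal mol⁻¹ K⁻¹ (kT = 0.59616 kcal/mol at 300 K).
KB_KCAL_PER_MOL_K = 0.0019872

#: Dipole conversion: 1 e·Å = 4.8032 Debye.
EA_TO_DEBYE = 4.8032

#: Number-density conversion: 1 M = 6.0221e-4 molecules/Å³.
MOLAR_TO_PER_A3 = 6.0221e-4

#: Rate conversion ns⁻¹ → s⁻¹.
PER_NS_TO_PER_S = 1.0e9

#: 1 nm²/ns in Å²/ns.
NM2_PER_NS_TO_A2_PER_NS = 100.0

#: Default effective diffusion constant, nm²/ns.
DEFAULT_D_NM2_PER_NS = 1.0

#: Default reference cross-section converting bulk concentration to a 1D
#: boundary density: area of the 17 Å restraint cylinder, Å².
DEFAULT_SIGMA_REF_A2 = math.pi * 17.0**2

#: Default temperature, K.
DEFAULT_TEMPERATURE_K = 300.0


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
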