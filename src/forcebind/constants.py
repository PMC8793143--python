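"""Physical constants and unit conventions.

Working units throughout the package: forces in pN, lengths in nm, time in s,
loading rates in pN/s, energies in kJ/mol, frequencies in Hz.  The thermal
energy at 298 K, ``KBT_298 = 4.114`` pN*nm, is the single source of truth for
k_B*T; every other module imports :func:`thermal_energy` rather than
multiplying Boltzmann's constant itself.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (SI; informational — pN*nm path goes via KBT_298).
BOLTZMANN_SI = 1.380649e-23

#: Molar gas constant, J/(mol*K).
GAS_CONSTANT = 8.314462618

#: Thermal energy at 298 K in pN*nm.
KBT_298 = 4.114

#: Default temperature, K.
T_DEFAULT = 298.0

#: Default Arrhenius prefactor for the dissociation-barrier relation, Hz.
ARRHENIUS_A = 1.0e6

#: Default reference loading rate for force comparison, pN/s (= 10 nN/s).
REFERENCE_LOADING_RATE = 1.0e4

#: Fundamental resonance of the quartz sensors, Hz.
F0_DEFAULT = 5.0e6

#: Acoustic shear impedance of AT-cut quartz, kg/(m^2 s).
ZQ_QUARTZ = 8.8e6

#: Default hydrated peptide-film density for viscoelastic modelling, kg/m^3.
FILM_DENSITY_DEFAULT = 1100.0

#: Aqueous buffer at ~25 C: density kg/m^3, shear viscosity Pa*s.
LIQUID_DENSITY_DEFAULT = 1000.0
LIQUID_VISCOSITY_DEFAULT = 8.9e-4


def thermal_energy(temperature: float = T_DEFAULT) -> float:
    """k_B*T in pN*nm, scaled linearly from the 298 K anchor value."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KBT_298 * (temperature / T_DEFAULT)
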