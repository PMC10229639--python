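"""Physical constants in the pN/nm/s unit system used throughout.

Forces are pN, lengths nm, stiffnesses pN/nm, energies pN*nm, time s.
"""

#: Boltzmann constant in pN*nm per kelvin (1.380649e-23 J/K = 1.380649e-2 pN*nm/K).
BOLTZMANN_PN_NM_PER_K: float = 1.380649e-2

#: Reference assay temperature (25 C).
DEFAULT_TEMPERATURE_K: float = 298.15


def thermal_energy(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kT in pN*nm (4.116 pN*nm at 298.15 K)."""
    if temperature_K <= 0:
        raise ValueError(f"temperature_K must be positive, got {temperature_K}")
    return BOLTZMANN_PN_NM_PER_K * temperature_K
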