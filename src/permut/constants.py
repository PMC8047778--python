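"""Physical constants (SI, CODATA 2018) and unit helpers.

Internal units: lengths in nm, times in ps, masses in unified atomic mass
units (u), molar entropies in J mol^-1 K^-1. Entropy estimators work in
nats per molecule; conversion to molar units happens in exactly one place
(:func:`nats_to_molar`).
"""

from __future__ import annotations

PLANCK_H = 6.62607015e-34  # J s
BOLTZMANN_KB = 1.380649e-23  # J K^-1
AVOGADRO_NA = 6.02214076e23  # mol^-1
GAS_CONSTANT_R = BOLTZMANN_KB * AVOGADRO_NA  # 8.31446... J mol^-1 K^-1
ATOMIC_MASS_U = 1.66053906660e-27  # kg

ARGON_MASS_U = 39.948
WATER_MASS_U = 18.01528


def nats_to_molar(nats: float) -> float:
    """Convert an entropy in nats per molecule to J mol^-1 K^-1."""
    return nats * GAS_CONSTANT_R


def thermal_wavelength_nm(mass_u: float, temperature_K: float) -> float:
    """De Broglie thermal wavelength lambda = h / sqrt(2 pi m k_B T), in nm."""
    import math

    m = mass_u * ATOMIC_MASS_U
    lam_m = PLANCK_H / math.sqrt(2.0 * math.pi * m * BOLTZMANN_KB * temperature_K)
    return lam_m * 1e9
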