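"""Physical constants used throughout the package.

Free energies are in kcal/mol. The thermal energy k_B*T at body temperature
(37 degC = 310.15 K) is the benchmark against which binding-preference
changes are judged physiologically relevant: an allelic difference in
binding free energy below ~0.616 kcal/mol is unlikely to overcome thermal
noise.
"""

from scipy.constants import R as _R_J_PER_MOL_K

#: kcal per Joule conversion (thermochemical calorie).
_KCAL_PER_J = 1.0 / 4184.0

#: Gas constant (molar Boltzmann constant) in kcal/(mol*K).
BOLTZMANN_KCAL_MOL_K: float = _R_J_PER_MOL_K * _KCAL_PER_J

#: Physiological temperature, Kelvin (37 degC).
BODY_TEMPERATURE_K: float = 310.15


def thermal_energy(temperature_k: float = BODY_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature."""
    return BOLTZMANN_KCAL_MOL_K * temperature_k


#: k_B*T at 37 degC, ~0.616 kcal/mol.
KT_KCAL_MOL: float = thermal_energy()
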