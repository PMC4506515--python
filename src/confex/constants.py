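"""Physical constants (CODATA 2018) and unit helpers."""

K_B = 1.380649e-23
"""Boltzmann constant, J K^-1."""

H_PLANCK = 6.62607015e-34
"""Planck constant, J s."""

R_GAS = 8.314462618
"""Molar gas constant, J mol^-1 K^-1."""

GAMMA_1H = 2.6752218744e8
"""Proton gyromagnetic ratio, rad s^-1 T^-1."""

CELSIUS_OFFSET = 273.15

J_PER_CAL = 4.184

DEFAULT_N15_MHZ = 86.2
"""15N Larmor frequency (MHz) on an 850 MHz (1H) spectrometer."""


def celsius_to_kelvin(t_c):
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - CELSIUS_OFFSET
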