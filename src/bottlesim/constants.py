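"""Physical constants shared across the package (SI units)."""

#: Ideal gas constant, J mol^-1 K^-1
R_GAS = 8.31446261815324

#: Molar mass of ethanol, kg mol^-1
M_ETHANOL = 46.069e-3

#: Molar mass of water, kg mol^-1
M_WATER = 18.015e-3

#: Celsius offset
T_ZERO_C = 273.15

#: Default atmospheric pressure, Pa
P_ATM = 101325.0

#: Density of semi-crystalline PET (~32 % crystallinity), kg m^-3
RHO_PET = 1335.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T_ZERO_C


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - T_ZERO_C
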