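"""Physical constants and unit conventions.

All public free energies are in kcal/mol unless explicitly converted at an
I/O boundary; reduced energies (beta*U) are unitless.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: kcal -> kJ conversion (thermochemical calorie).
KCAL_TO_KJ = 4.184


def beta_from_temperature(temperature: float) -> float:
    """Inverse temperature 1/(kB*T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL * temperature)
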