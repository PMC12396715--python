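"""Physical constants used throughout the model (SI, except where noted)."""

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.314462618  # J / (mol K)


def rt_over_f_mv(temperature: float) -> float:
    """R*T/F expressed in millivolts for a given temperature in kelvin."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY
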