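"""Physical constants and default experimental conditions."""

FARADAY = 96485.332
"""Faraday constant, C/mol."""

GAS_CONSTANT = 8.314462
"""Molar gas constant, J/(mol K)."""

DEFAULT_TEMPERATURE = 293.15
"""Default recording temperature (20 degrees C), kelvin."""
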