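"""Unit conversions shared across modules."""

#: grams of glucose per mole, used for mg/dL <-> mM conversion
GLUCOSE_MOLAR_MASS = 18.016  # mg/dL per mM

#: millilitres of tissue per hectogram, assuming unit density
ML_PER_HG = 100.0


def mgdl_to_mm(value: float) -> float:
    """Convert plasma glucose from mg/dL to mM."""
    return value / GLUCOSE_MOLAR_MASS


def mm_to_mgdl(value: float) -> float:
    """Convert plasma glucose from mM to mg/dL."""
    return value * GLUCOSE_MOLAR_MASS
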