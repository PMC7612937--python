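"""Unit conversion helpers.

Traces are carried in clinical units (pressure in mmHg, velocity in m/s,
time in s); formulas that are dimensionally SI (ρcU, sum-of-squares wave
speed, γ approximations) convert to Pa internally through these helpers.
"""

MMHG_TO_PA = 133.322
"""Pa per mmHg."""

ML_TO_M3 = 1e-6
"""m³ per mL."""

CM2_TO_M2 = 1e-4
"""m² per cm²."""


def mmhg_to_pa(p):
    return p * MMHG_TO_PA


def pa_to_mmhg(p):
    return p / MMHG_TO_PA
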