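"""Unit conversions used across the package.

Internal mechanical unit system: mm (length), kPa (stress/modulus),
kPa*mm (line traction).  Luminal pressures are quoted in mmHg at the
user surface and converted on entry.
"""

MMHG_TO_KPA = 0.133322
"""1 mmHg in kPa."""

SOUND_SPEED_MM_PER_S = 1.54e6
"""Speed of sound in soft tissue, mm/s (1540 m/s)."""

ML_PER_MIN_TO_CM3_PER_S = 1.0 / 60.0


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_KPA
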