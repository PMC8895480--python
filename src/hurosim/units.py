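"""Unit conversion helpers.

Interface stiffnesses are quoted in N/mm in the indentation and design
literature; the dynamics core works in SI (N/m).  All conversions between the
two conventions go through this module so the factor lives in exactly one
place.
"""

N_PER_MM_TO_N_PER_M = 1000.0
MPA_TO_PA = 1.0e6


def n_per_mm_to_n_per_m(k: float) -> float:
    """Convert a stiffness in N/mm to N/m."""
    return k * N_PER_MM_TO_N_PER_M


def n_per_m_to_n_per_mm(k: float) -> float:
    """Convert a stiffness in N/m to N/mm."""
    return k / N_PER_MM_TO_N_PER_M
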