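"""Unit conventions and conversions.

Geometry is in mm, displacements in mm internally (µm at the tracking
surface), pressures and moduli in kPa internally with mmHg accepted at the
boundary.
"""

MMHG_TO_KPA = 0.133322
"""Conversion constant, kPa per mmHg."""


def mmhg_to_kpa(p_mmhg):
    """Convert a pressure (scalar or array) from mmHg to kPa."""
    return p_mmhg * MMHG_TO_KPA


def kpa_to_mmhg(p_kpa):
    """Convert a pressure (scalar or array) from kPa to mmHg."""
    return p_kpa / MMHG_TO_KPA
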