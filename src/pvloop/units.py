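"""Unit conventions and conversions.

All pressures crossing a public interface are in mmHg; the virtual-impedance
components are specified in cgs (Barye-based) units, so the conversion factor
1 mmHg = 1333.22 Barye (dyn/cm^2) is applied wherever a flow x resistance or
inertance x flow-derivative product (Barye) is combined with a pressure in
mmHg.  Flows are cm^3/s (= mL/s) throughout; volumes are cm^3 (= mL).
"""

MMHG_TO_BARYE: float = 1333.22
"""Barye per mmHg."""


def mmhg_to_barye(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Barye (dyn/cm^2)."""
    return p_mmhg * MMHG_TO_BARYE


def barye_to_mmhg(p_barye: float) -> float:
    """Convert a pressure from Barye (dyn/cm^2) to mmHg."""
    return p_barye / MMHG_TO_BARYE
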