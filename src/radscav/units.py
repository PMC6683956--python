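"""Unit conversions at the package boundary.

Internally every concentration is µM and every time is minutes: the
second-order scavenging constants are tabulated in µM⁻¹·min⁻¹, so keeping
that basis everywhere avoids silent rescaling of rate laws. User-facing
inputs quoted in mM (radical initiator) or µg/ml (curcumin mass
concentration) are converted here, explicitly, and nowhere else.
"""

from __future__ import annotations

#: Molar mass of curcumin, g/mol.
CURCUMIN_MW = 368.38


def mM_to_uM(value_mM: float) -> float:
    """Convert millimolar to micromolar."""
    return float(value_mM) * 1000.0


def uM_to_mM(value_uM: float) -> float:
    """Convert micromolar to millimolar."""
    return float(value_uM) / 1000.0


def ug_per_ml_to_uM(value_ug_per_ml: float, mw_g_per_mol: float = CURCUMIN_MW) -> float:
    """Convert a mass concentration (µg/ml) to µM given a molar mass.

    1 µg/ml = 1 mg/l, so concentration [µM] = 1000 * (mg/l) / MW.
    The default molar mass is curcumin's (368.38 g/mol), under which the
    common working solution of 50 µg/ml is ≈ 135.7 µM.
    """
    if mw_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    return float(value_ug_per_ml) * 1000.0 / mw_g_per_mol
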