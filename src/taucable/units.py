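"""Centralized unit conversions.

Internal unit system: μm (length), ms (time), mV (voltage), nA (current),
MΩ (resistance), μS (conductance), nF (capacitance).  This set is closed:
MΩ·nA = mV, μS·mV = nA, MΩ·nF = ms, nF·mV/ms = nA.

Specific membrane constants keep their conventional units at the API surface
(Rm in Ω·cm², Cm in μF/cm², Ra in Ω·cm) and are converted here, once.
"""

import math

#: μm² per cm²
UM2_PER_CM2 = 1e8


def membrane_capacitance_nF(Cm_uF_per_cm2: float, area_um2: float) -> float:
    """Capacitance of a membrane patch, nF, from Cm (μF/cm²) and area (μm²)."""
    # μF/cm² · μm² / (μm²/cm²) = μF ; ×1e3 → nF
    return Cm_uF_per_cm2 * area_um2 / UM2_PER_CM2 * 1e3


def membrane_conductance_uS(Rm_ohm_cm2: float, area_um2: float) -> float:
    """Leak conductance of a membrane patch, μS, from Rm (Ω·cm²) and area (μm²)."""
    # (area_cm²/Rm) S ×1e6 → μS
    return area_um2 / UM2_PER_CM2 / Rm_ohm_cm2 * 1e6


def axial_resistance_Mohm(Ra_ohm_cm: float, length_um: float, diam_um: float) -> float:
    """Axial resistance of a cylinder, MΩ, from Ra (Ω·cm), length and diameter (μm).

    R = Ra·l/(π d²/4).
    """
    if diam_um <= 0 or length_um < 0:
        raise ValueError("need diam > 0 and length >= 0")
    # Ra in Ω·cm = Ra·1e4 Ω·μm ; result Ω → ×1e-6 MΩ
    return 4.0 * Ra_ohm_cm * 1e4 * length_um / (math.pi * diam_um**2) * 1e-6


def space_constant_um(diam_um: float, Rm_ohm_cm2: float, Ra_ohm_cm: float) -> float:
    """Passive space constant λ = sqrt(d·Rm/(4·Ra)), μm.

    ``Rm_ohm_cm2`` must already carry any spine correction (Rm/q).
    """
    if diam_um <= 0 or Rm_ohm_cm2 <= 0 or Ra_ohm_cm <= 0:
        raise ValueError("space_constant requires positive d, Rm, Ra")
    d_cm = diam_um * 1e-4
    lam_cm = math.sqrt(d_cm * Rm_ohm_cm2 / (4.0 * Ra_ohm_cm))
    return lam_cm * 1e4
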