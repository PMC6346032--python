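"""Daily shoot structural-carbon gain from whole-rosette gas exchange.

Growing leaves photosynthesise more, so under constant specific leaf area
the day-over-day increment of total net photosynthesis per rosette
reflects rosette growth. Requiring the *specific* rate (per gram fresh
weight) to be equal on two consecutive days,

    ∫ rPS1 dt / gFW1  =  ∫ rPS2 dt / gFW2,

with the rosette fresh weight gFW2 weighed after day 2, yields the unknown
fresh weight gFW1 at the start. The fresh-weight gain ΔgFW = gFW2 − gFW1
is converted to structural carbon through the dry-matter ratio
(0.108 gDW/gFW) and the carbon fraction of dry matter (0.45 gC/gDW), and
expressed as µmol C6 (72 g C per mol C6). One gram of new fresh tissue
thus corresponds to 675 µmol C6. This daily gain is the single constraint
on structural-carbon formation used by the final model variant.
"""

from __future__ import annotations

import dataclasses

#: gDW per gFW of rosette tissue
FW_TO_DW = 0.108
#: g carbon per gDW
DW_CARBON_FRACTION = 0.45
#: g carbon per mol of C6 bodies (6 × 12 g/mol; the conversion passes
#: through grams of carbon, not grams of hexose)
C6_MOLAR_MASS = 72.0


def fw_to_umol_c6(grams_fw: float, fw_to_dw: float = FW_TO_DW,
                  dw_carbon_fraction: float = DW_CARBON_FRACTION) -> float:
    """µmol C6 contained in a mass of fresh tissue (default 675 µmol/gFW)."""
    return grams_fw * fw_to_dw * dw_carbon_fraction / C6_MOLAR_MASS * 1e6


@dataclasses.dataclass
class GrowthInput:
    """Two-day gas-exchange summary for the growth calculation.

    ``integral_rps1``/``integral_rps2`` are the net CO2 exchange integrals
    (µmol CO2 per rosette) over day 1 and day 2; ``gfw2`` is the rosette
    fresh weight (g) weighed after the day-2 measurement.
    """

    integral_rps1: float
    integral_rps2: float
    gfw2: float
    fw_to_dw: float = FW_TO_DW
    dw_carbon_fraction: float = DW_CARBON_FRACTION

    def __post_init__(self) -> None:
        if self.integral_rps2 <= 0:
            raise ValueError("day-2 photosynthesis integral must be positive")
        if self.integral_rps1 <= 0:
            raise ValueError("day-1 photosynthesis integral must be positive")
        if self.gfw2 <= 0:
            raise ValueError("rosette fresh weight must be positive")
        if not (0 < self.fw_to_dw < 1) or not (0 < self.dw_carbon_fraction < 1):
            raise ValueError("conversion fractions must lie in (0, 1)")


def solve_gfw1(inp: GrowthInput) -> float:
    """Day-1 fresh weight from the equal-specific-photosynthesis balance."""
    return inp.gfw2 * inp.integral_rps1 / inp.integral_rps2


def daily_sc_gain(inp: GrowthInput) -> float:
    """Daily structural-carbon gain in µmol C6 per gFW.

    The fresh-weight increment is converted to carbon and normalised by
    gFW2, the weighed rosette (the only measured reference weight; recorded
    in output metadata wherever gains are reported).
    """
    gfw1 = solve_gfw1(inp)
    delta_fw = inp.gfw2 - gfw1
    return fw_to_umol_c6(delta_fw, inp.fw_to_dw, inp.dw_carbon_fraction) / inp.gfw2


def sc_gain_report(inp: GrowthInput) -> dict:
    """gFW1, ΔgFW and the per-gFW daily gain, with the reference weight."""
    gfw1 = solve_gfw1(inp)
    return {
        "gfw1_g": gfw1,
        "gfw2_g": inp.gfw2,
        "delta_gfw_g": inp.gfw2 - gfw1,
        "sc_gain_umol_c6_per_gfw": daily_sc_gain(inp),
        "normalised_by": "gFW2",
    }


def growth_input_from_traces(times1, net1, times2, net2, gfw2: float, **conversions) -> GrowthInput:
    """Build a :class:`GrowthInput` by integrating two net-exchange traces.

    Traces are net CO2 exchange per gFW and hour; both integrals are scaled
    by the same reference weight so the day ratio — the only quantity that
    matters for the growth inference — is unchanged.
    """
    import numpy as np

    i1 = float(np.trapezoid(np.asarray(net1, float), np.asarray(times1, float))) * gfw2
    i2 = float(np.trapezoid(np.asarray(net2, float), np.asarray(times2, float))) * gfw2
    return GrowthInput(integral_rps1=i1, integral_rps2=i2, gfw2=gfw2, **conversions)
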