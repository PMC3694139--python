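"""Unit conversion helpers.

All internal state is SI (m, Pa, s, m^3/s).  Published transport
coefficients for tumor/normal tissue are tabulated in cm / mmHg units and
vessel diameters in micrometres; conversions happen at the boundary of the
system, never inside the solvers.
"""

MMHG_PA = 133.322  # 1 mmHg in Pa


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def lp_cgs_to_si(lp: float) -> float:
    """Hydraulic conductivity of a vessel wall, cm/(mmHg s) -> m/(Pa s)."""
    return lp * 1e-2 / MMHG_PA


def k_cgs_to_si(k: float) -> float:
    """Tissue hydraulic conductivity, cm^2/(mmHg s) -> m^2/(Pa s)."""
    return k * 1e-4 / MMHG_PA


def sv_cgs_to_si(sv: float) -> float:
    """Vessel surface area per tissue volume, 1/cm -> 1/m."""
    return sv * 1e2


def um(x: float) -> float:
    """Micrometres -> metres."""
    return x * 1e-6
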