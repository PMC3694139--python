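"""Structural diameter adaptation of capillary segments.

Vessels remodel their diameter in response to three stimuli balanced
against an intrinsic shrinking tendency:

* wall shear stress  S_wss = log10(tau_w + tau_ref),
* intravascular pressure  S_p = -k_p log10(tau_e(P_b)),  where tau_e is
  the sigmoidal shear-vs-pressure set point fitted to rat mesentery data,
* metabolic supply  S_m = k_m log10(Q_ref / (Q_b H) + 1),  penalizing
  segments whose red-cell flux falls below the reference (parent) flow.

Stresses inside the logarithms are expressed in dyn/cm^2, the unit in
which this stimulus formulation and its constants (tau_ref = 0.103) were
originally calibrated; with SI pascals the equilibrium shear of the
shrinking tendency would sit above anything a capillary bed fed by one
parent vessel can generate, and every vessel would collapse to the lower
diameter bound.

One explicit Euler step changes each capillary diameter by
dD = D dt (S_wss + S_p + S_m - k_s), clamped to the physiologic range;
parent-vessel segments never remodel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import AdaptationParams
from .units import pa_to_mmhg
from .vessel_graph import VesselNetwork

PA_TO_DYN = 10.0  # 1 Pa = 10 dyn/cm^2


@dataclass
class StimulusBreakdown:
    s_wss: float
    s_p: float
    s_m: float
    tau_e: float       # Pa

    @property
    def total(self) -> float:
        # shrinking tendency is applied by the caller via params.k_s
        return self.s_wss + self.s_p + self.s_m


def tau_e(pressure: float) -> float:
    """Shear-stress set point implied by intravascular pressure, in Pa.

    Sigmoidal fit 100 - 86 exp(-5000 (log10 log10 P)^5.4) in dyn/cm^2
    with P in mmHg, scaled to Pa; below 10 mmHg the fit is not applicable
    and the floor value 1.4 Pa is used (the continuous form meets it
    exactly at 10 mmHg).
    """
    p_mmhg = pa_to_mmhg(pressure)
    if p_mmhg <= 10.0:
        return 1.4
    inner = math.log10(math.log10(p_mmhg))
    dyn = 100.0 - 86.0 * math.exp(-5000.0 * inner ** 5.4)
    return 0.1 * dyn  # dyn/cm^2 -> Pa


def stimuli(tau_w: float, pb_mean: float, rbc_flux: float, q_ref: float,
            params: AdaptationParams) -> StimulusBreakdown:
    """Evaluate the three adaptation stimuli for one segment.

    ``rbc_flux`` is Q_b * H (m^3/s); stagnant segments are capped at a
    configured floor so the metabolic log stays bounded.
    """
    s_wss = math.log10(tau_w * PA_TO_DYN + params.tau_ref)
    te = tau_e(pb_mean)
    s_p = -params.k_p * math.log10(te * PA_TO_DYN)
    flux = max(abs(rbc_flux), params.metabolic_floor * q_ref)
    s_m = params.k_m * math.log10(q_ref / flux + 1.0)
    return StimulusBreakdown(s_wss=s_wss, s_p=s_p, s_m=s_m, tau_e=te)


def update_diameters(net: VesselNetwork, params: AdaptationParams,
                     q_ref: float | None = None,
                     relax: float | None = None) -> float:
    """One Euler remodeling step on every capillary segment.

    Returns max |dD / D| over remodeled segments.  Diameters are clamped
    to [d_min, d_max]; parent segments stay untouched.  ``q_ref``
    defaults to the configured parent reference flow, or to the largest
    |Q_b| in the network when ``q_ref_from_network`` is set.
    """
    if q_ref is None:
        if params.q_ref_from_network:
            q_ref = max((abs(s.flow) for s in net.segments.values()
                         if math.isfinite(s.flow)), default=params.q_ref)
        else:
            q_ref = params.q_ref
    relax = params.relax if relax is None else relax
    max_rel = 0.0
    for seg in net.segments.values():
        if seg.is_parent:
            continue
        pb_mean = 0.5 * (net.nodes[seg.node_a].pressure
                         + net.nodes[seg.node_b].pressure)
        s = stimuli(seg.wall_shear, pb_mean, seg.flow * seg.hematocrit,
                    q_ref, params)
        s_tot = s.total - params.k_s
        d_new = seg.diameter * (1.0 + params.dt * s_tot)
        d_new = min(max(d_new, params.d_min), params.d_max)
        d_new = seg.diameter + relax * (d_new - seg.diameter)
        max_rel = max(max_rel, abs(d_new - seg.diameter) / seg.diameter)
        seg.diameter = d_new
    return max_rel
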