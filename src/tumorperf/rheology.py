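"""Blood rheology in the microcirculation.

Two ingredients of the non-continuous behavior of blood in capillaries:

* the apparent (effective) viscosity of blood as a function of tube
  diameter and discharge hematocrit — the empirical in-vitro fit to human
  blood data, capturing the Fåhræus–Lindqvist reduction of viscosity in
  narrow tubes; and

* phase separation (plasma skimming) at diverging junctions: red cells
  partition unequally between daughter branches, biased toward the faster
  branch, with a critical velocity ratio above which the slow branch
  receives no red cells at all.
"""

from __future__ import annotations

import math

import numpy as np

from .config import PhaseSepParams, ViscosityLaw
from .vessel_graph import VesselNetwork


class HematocritError(RuntimeError):
    """Flow-field inconsistency or non-convergence of the junction sweep."""


# ---------------------------------------------------------------------
# apparent viscosity

def mu_45(d_um: float) -> float:
    """Relative apparent viscosity at fixed hematocrit 0.45, D in um."""
    return 3.2 - 2.44 * math.exp(-0.06 * d_um ** 0.645) \
        + 220.0 * math.exp(-1.3 * d_um)


def shape_exponent(d_um: float) -> float:
    """Exponent C(D) shaping the hematocrit dependence of viscosity."""
    dampener = 1.0 / (1.0 + 1e-11 * d_um ** 12)
    return (0.8 + math.exp(-0.075 * d_um)) * (dampener - 1.0) + dampener


def relative_viscosity(diameter: float, hematocrit: float,
                       law: ViscosityLaw | None = None) -> float:
    """Relative apparent viscosity mu_rel(D, H); D in metres.

    Normalized so that mu_rel(D, 0.45) = mu_45(D) and mu_rel(D, 0) = 1.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError("hematocrit must lie in [0, 1)")
    d_um = diameter * 1e6
    c = shape_exponent(d_um)
    num = (1.0 - hematocrit) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    return 1.0 + (mu_45(d_um) - 1.0) * num / den


def apparent_viscosity(diameter: float, hematocrit: float,
                       law: ViscosityLaw | None = None) -> float:
    """Apparent viscosity in Pa s: mu_rel times the plasma viscosity."""
    law = law or ViscosityLaw()
    return relative_viscosity(diameter, hematocrit, law) * law.mu_plasma


def update_network_viscosity(net: VesselNetwork, law: ViscosityLaw) -> None:
    """Assign segment apparent viscosities from the current D and H.

    Parent segments keep the configured bulk value; capillaries use the
    diameter/hematocrit law.
    """
    for seg in net.segments.values():
        if seg.is_parent:
            seg.viscosity = law.mu_parent
        else:
            seg.viscosity = apparent_viscosity(seg.diameter, seg.hematocrit, law)


# ---------------------------------------------------------------------
# phase separation

def split_hematocrit(h_in: float, rbc_flux_in: float,
                     out_flows: np.ndarray, out_velocities: np.ndarray,
                     params: PhaseSepParams) -> np.ndarray:
    """Distribute red cells from a junction into its outgoing branches.

    ``rbc_flux_in`` is the incoming red-cell flux sum(H |Q|); ``h_in`` the
    flux-weighted inflow hematocrit.  For a single outlet this is plain
    mixing.  For several outlets the hematocrit ratio between branches
    follows H_i/H_slowest = 1 + zeta (U_i/U_slowest - 1); any branch whose
    velocity ratio to the fastest exceeds the critical ratio receives no
    red cells.  Red-cell flux is conserved up to the H_max clamp, whose
    excess is redistributed to the sibling outlets.
    """
    q = np.abs(np.asarray(out_flows, dtype=float))
    u = np.abs(np.asarray(out_velocities, dtype=float))
    m = q.size
    if m == 0:
        return np.zeros(0)
    if m == 1:
        h = np.array([rbc_flux_in / q[0] if q[0] > 0 else h_in])
        return np.minimum(h, params.h_max)

    active = np.ones(m, dtype=bool)
    u_max = u.max()
    if u_max > 0:
        # critical velocity-ratio cutoff: starved branches get H = 0
        active &= u * params.u_cr >= u_max
    if not active.any():
        active[:] = True

    h = np.zeros(m)
    u_slow = u[active].min()
    if u_slow > 0:
        ratio = 1.0 + params.zeta * (u / u_slow - 1.0)
    else:
        ratio = np.ones(m)
    ratio = np.where(active, ratio, 0.0)
    denom = float(np.sum(ratio * q))
    if denom <= 0:
        h[active] = h_in
    else:
        h = ratio * rbc_flux_in / denom

    # clamp and push the excess red-cell flux onto unclamped siblings
    for _ in range(m):
        over = h > params.h_max
        if not over.any():
            break
        excess = float(np.sum((h[over] - params.h_max) * q[over]))
        h[over] = params.h_max
        room = active & ~over & (h < params.h_max)
        if not room.any() or excess <= 0:
            break
        h[room] = h[room] + excess / q[room].sum()
    return np.minimum(h, params.h_max)


def update_network_hematocrit(net: VesselNetwork, params: PhaseSepParams
                              ) -> int:
    """Propagate hematocrit from the parent vessel through the network.

    Segment flow goes from the higher-pressure endpoint to the lower, so
    nodes processed in order of decreasing pressure see all their inflow
    hematocrits already assigned; a handful of damped sweeps handles the
    residual coupling introduced by clamping.  Returns the number of
    sweeps used.

    Parent segments and their junction nodes hold the fixed discharge
    hematocrit of the parent vessel.
    """
    if not net.has_flows():
        raise HematocritError("hematocrit update requires solved flows")

    order = sorted(net.nodes, key=lambda nid: -_node_pressure(net, nid))
    # blood enters the system at parent-vessel junctions and at inlet
    # nodes, in both cases at the fixed parent discharge hematocrit
    parent_nodes = {nid for s in net.segments.values() if s.is_parent
                    for nid in (s.node_a, s.node_b)}
    parent_nodes |= {nid for nid, node in net.nodes.items()
                     if node.role == "inlet"}
    q_scale = max((abs(s.flow) for s in net.segments.values()), default=0.0)
    q_eps = 1e-12 * q_scale  # flows below this are numerically stagnant

    for sweep in range(1, params.max_iter + 1):
        # first sweep walks the flow DAG in upstream-to-downstream order and
        # is exact when no clamp couples siblings; later damped sweeps mop up
        relax = 1.0 if sweep == 1 else params.relax
        max_change = 0.0
        for nid in order:
            node = net.nodes[nid]
            segs = net.segments_at(nid)
            outflows = []
            influx = 0.0
            inflow_q = 0.0
            for seg in segs:
                q_away = seg.flow if seg.node_a == nid else -seg.flow
                if q_away > 0:
                    outflows.append((seg, q_away))
                else:
                    influx += seg.hematocrit * abs(q_away)
                    inflow_q += abs(q_away)
            if not outflows:
                continue
            if nid in parent_nodes:
                h_node = params.h_parent
                influx = h_node * sum(q for _, q in outflows)
            elif inflow_q > q_eps:
                h_node = influx / inflow_q
            else:
                # no vascular inflow: the junction is fed by transvascular
                # reabsorption, which carries plasma only
                h_node = 0.0
                influx = 0.0
            cap_out = [(s, q) for s, q in outflows if not s.is_parent]
            if not cap_out:
                continue
            q_arr = np.array([q for _, q in cap_out])
            u_arr = np.array([abs(s.flow) / (math.pi * s.diameter ** 2 / 4)
                              for s, _ in cap_out])
            if nid in parent_nodes:
                influx_cap = h_node * q_arr.sum()
            else:
                q_parent_out = sum(q for s, q in outflows if s.is_parent)
                influx_cap = max(influx - params.h_parent * q_parent_out, 0.0)
            h_new = split_hematocrit(h_node, influx_cap, q_arr, u_arr, params)
            for (seg, _), h in zip(cap_out, h_new):
                if seg.is_parent:
                    continue
                h_relaxed = seg.hematocrit + relax * (h - seg.hematocrit)
                max_change = max(max_change, abs(h_relaxed - seg.hematocrit))
                seg.hematocrit = h_relaxed
        for seg in net.segments.values():
            if seg.is_parent:
                seg.hematocrit = params.h_parent
        if max_change < params.tol:
            return sweep
    raise HematocritError(
        f"hematocrit sweep did not converge in {params.max_iter} iterations "
        f"(last change {max_change:.3e})")


def _node_pressure(net: VesselNetwork, nid: int) -> float:
    p = net.nodes[nid].pressure
    return p if math.isfinite(p) else -math.inf
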