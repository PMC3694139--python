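"""Steady intravascular flow in the capillary network.

Each segment carries Poiseuille flow driven by its endpoint nodal
pressures; fluid also filters across the leaky wall following Starling's
law, evaluated with segment-averaged intravascular and interstitial
pressures.  Mass conservation at every interior node closes the system,
which is linear in the nodal pressures for frozen viscosity and
hematocrit (Picard linearization).  The system is solved either by
successive over-relaxation on the nodal update or by a direct sparse
factorization; both routes converge to the same resistor-network
solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import SolverConfig, TissueConfig
from .vessel_graph import VesselNetwork


class FlowSolverError(RuntimeError):
    pass


@dataclass
class FlowState:
    """Converged intravascular flow field."""

    node_ids: list[int]
    pressures: np.ndarray          # Pa, aligned with node_ids
    segment_ids: list[int]
    flows: np.ndarray              # Q_b, m^3/s, signed a -> b
    transvascular: np.ndarray      # Q_t, m^3/s, positive out of the vessel
    velocities: np.ndarray         # m/s
    wall_shears: np.ndarray        # Pa
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    iterations: int = 0
    inlet_flow: float = math.nan   # flow entering the network at the inlet
    outlet_flow: float = math.nan  # flow leaving at the outlet


def poiseuille_flow(diameter: float, length: float, dp: float,
                    mu_app: float) -> float:
    """Volumetric flow through a cylindrical segment, signed with dp."""
    if diameter <= 0 or length <= 0 or mu_app <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    return math.pi * diameter ** 4 * dp / (128.0 * mu_app * length)


def poiseuille_conductance(diameter: float, length: float,
                           mu_app: float) -> float:
    return math.pi * diameter ** 4 / (128.0 * mu_app * length)


def starling_flow(diameter: float, length: float, pb_mean: float,
                  pi_mean: float, lp: float, sigma: float,
                  oncotic_difference: float) -> float:
    """Transvascular filtration through a segment wall (Starling's law).

    Positive values leave the vessel.  ``oncotic_difference`` is
    pi_B - pi_i in Pa; the effective driving pressure is
    (Pb - Pi) - sigma * (pi_B - pi_i).
    """
    area = math.pi * diameter * length
    return lp * area * ((pb_mean - pi_mean) - sigma * oncotic_difference)


def wall_shear(diameter: float, flow: float, mu_app: float) -> float:
    """Poiseuille wall shear stress tau_w = 32 mu |Q| / (pi D^3)."""
    return 32.0 * mu_app * abs(flow) / (math.pi * diameter ** 3)


def _segment_region(net: VesselNetwork, seg, tumor_mask: np.ndarray | None,
                    n: int, length: float) -> bool:
    """True if the segment midpoint lies in the tumor."""
    if tumor_mask is None:
        return False
    na, nb = net.nodes[seg.node_a], net.nodes[seg.node_b]
    xm, ym = 0.5 * (na.x + nb.x), 0.5 * (na.y + nb.y)
    h = length / n
    i = min(max(int(xm / h), 0), n - 1)
    j = min(max(int(ym / h), 0), n - 1)
    return bool(tumor_mask[i, j])


def solve_nodal_pressures(net: VesselNetwork,
                          tissue: TissueConfig,
                          solver: SolverConfig,
                          pi_field: np.ndarray | None = None,
                          tumor_mask: np.ndarray | None = None,
                          n: int = 100,
                          length: float = 2e-3,
                          inlet_pressure: float = 3325.0,
                          outlet_pressure: float = 1330.0,
                          leakage: bool = True,
                          x0: np.ndarray | None = None) -> FlowState:
    """Solve mass conservation at every interior node for P_b.

    Segment flows are Poiseuille; each segment loses its Starling
    transvascular flux, allocated half to each endpoint node.  Inlet and
    outlet nodes carry Dirichlet pressures.  ``pi_field`` supplies the
    interstitial pressure sampled at segment endpoints (zero if absent).
    """
    node_ids = list(net.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    nn = len(node_ids)
    seg_ids = list(net.segments)

    h = length / n

    def cell_of(node):
        i = min(max(int(node.x / h), 0), n - 1)
        j = min(max(int(node.y / h), 0), n - 1)
        return i, j

    # per-segment constants
    g = np.empty(len(seg_ids))
    kt = np.zeros(len(seg_ids))
    cs = np.zeros(len(seg_ids))   # Starling offset P_i_mean + sigma*d_pi
    ia = np.empty(len(seg_ids), dtype=np.int64)
    ib = np.empty(len(seg_ids), dtype=np.int64)
    for s, sid in enumerate(seg_ids):
        seg = net.segments[sid]
        if not math.isfinite(seg.viscosity) or seg.viscosity <= 0:
            raise FlowSolverError(
                f"segment {sid} has no valid viscosity; update rheology first")
        g[s] = poiseuille_conductance(seg.diameter, seg.length, seg.viscosity)
        ia[s], ib[s] = index[seg.node_a], index[seg.node_b]
        if leakage:
            in_tumor = _segment_region(net, seg, tumor_mask, n, length)
            props = tissue.region(in_tumor)
            kt[s] = props.lp * math.pi * seg.diameter * seg.length
            na, nb = net.nodes[seg.node_a], net.nodes[seg.node_b]
            if pi_field is not None:
                pia = pi_field[cell_of(na)]
                pib = pi_field[cell_of(nb)]
                pi_mean = 0.5 * (pia + pib)
            else:
                pi_mean = 0.0
            cs[s] = pi_mean + props.oncotic_drop

    fixed = np.full(nn, np.nan)
    for i, nid in enumerate(node_ids):
        role = net.nodes[nid].role
        if role == "inlet":
            fixed[i] = inlet_pressure
        elif role == "outlet":
            fixed[i] = outlet_pressure
    free = np.isnan(fixed)
    if not free.any() and nn > 2:
        raise FlowSolverError("no interior nodes to solve for")

    # assemble A P = b over all nodes; Dirichlet rows are identities and
    # Dirichlet neighbors are folded into the right-hand side
    rows, cols, vals = [], [], []
    b = np.zeros(nn)
    diag = np.zeros(nn)
    for s in range(len(seg_ids)):
        a_i, b_i = ia[s], ib[s]
        gs, ks, c = g[s], kt[s], cs[s]
        # balance at node "me": gs*(P_you - P_me)
        #                       - ks/2 * ((P_me + P_you)/2 - c) = 0
        for me, you in ((a_i, b_i), (b_i, a_i)):
            if not free[me]:
                continue
            diag[me] += gs + ks / 4.0
            b[me] += ks * c / 2.0
            coeff = -(gs - ks / 4.0)
            if free[you]:
                rows.append(me); cols.append(you); vals.append(coeff)
            else:
                b[me] -= coeff * fixed[you]
    for i in range(nn):
        if free[i]:
            rows.append(i); cols.append(i); vals.append(diag[i])
        else:
            rows.append(i); cols.append(i); vals.append(1.0)
            b[i] = fixed[i]
    a_sys = sp.csr_matrix((vals, (rows, cols)), shape=(nn, nn))

    if x0 is not None and x0.shape == (nn,):
        x = x0.copy()
    else:
        x = np.full(nn, outlet_pressure, dtype=float)
    x[~free] = fixed[~free]

    iterations = 0
    if solver.network_method == "direct":
        x = spla.spsolve(a_sys.tocsc(), b)
        iterations = 1
    else:
        omega = solver.omega_network
        d = a_sys.diagonal()
        m = (sp.tril(a_sys, k=-1) + sp.diags(d / omega)).tocsr()
        n_mat = (sp.triu(a_sys, k=1) + sp.diags(d * (1.0 - 1.0 / omega))).tocsr()
        scale = max(abs(inlet_pressure), abs(outlet_pressure), 1.0)
        for iterations in range(1, solver.max_iter + 1):
            x_new = spla.spsolve_triangular(m, b - n_mat @ x, lower=True)
            change = np.max(np.abs(x_new - x)) / scale
            x = x_new
            if change < solver.tol:
                break
        else:
            raise FlowSolverError(
                f"nodal SOR did not converge in {solver.max_iter} sweeps")

    if not np.all(np.isfinite(x)):
        raise FlowSolverError(
            "singular nodal system: is some subnetwork isolated from the "
            "inlet/outlet? (topological pruning should prevent this)")

    # write back and derive segment quantities
    for i, nid in enumerate(node_ids):
        net.nodes[nid].pressure = float(x[i])
    flows = g * (x[ia] - x[ib])
    qt = kt * (0.5 * (x[ia] + x[ib]) - cs)
    areas = np.array([math.pi * net.segments[sid].diameter ** 2 / 4.0
                      for sid in seg_ids])
    velocities = np.abs(flows) / areas
    shears = np.array([wall_shear(net.segments[sid].diameter, q,
                                  net.segments[sid].viscosity)
                       for sid, q in zip(seg_ids, flows)])
    for s, sid in enumerate(seg_ids):
        seg = net.segments[sid]
        seg.flow = float(flows[s])
        seg.flow_trans = float(qt[s])
        seg.wall_shear = float(shears[s])

    # nodal residuals (free nodes): net flow imbalance
    resid = np.zeros(nn)
    np.add.at(resid, ia, -flows - 0.5 * qt)
    np.add.at(resid, ib, flows - 0.5 * qt)
    resid[~free] = 0.0

    seg_pos = {sid: s for s, sid in enumerate(seg_ids)}

    def boundary_flow(role: str) -> float:
        # a boundary node also supplies (inlet) or absorbs (outlet) its
        # half-share of the adjacent segments' transvascular leak, so the
        # global balance inlet = outlet + sum(Q_t) closes exactly
        total = 0.0
        for nid in node_ids:
            if net.nodes[nid].role == role:
                for seg in net.segments_at(nid):
                    s = seg_pos[seg.id]
                    q_away = flows[s] if seg.node_a == nid else -flows[s]
                    if role == "inlet":
                        total += q_away + 0.5 * qt[s]
                    else:
                        total += -q_away - 0.5 * qt[s]
        return total

    return FlowState(node_ids=node_ids, pressures=x, segment_ids=seg_ids,
                     flows=flows, transvascular=qt, velocities=velocities,
                     wall_shears=shears, residuals=resid,
                     iterations=iterations,
                     inlet_flow=boundary_flow("inlet"),
                     outlet_flow=boundary_flow("outlet"))


def mass_balance_residual(state: FlowState) -> float:
    """Relative global imbalance: inlet flow - outlet flow - sum(Q_t)."""
    q_in = state.inlet_flow
    q_out = state.outlet_flow
    q_t = float(np.sum(state.transvascular))
    scale = max(abs(q_in), abs(q_out), 1e-300)
    return abs(q_in - q_out - q_t) / scale
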