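"""Orchestration of the three solution approaches.

Approach 1: no network.  The tumor is a uniform blood source at a
constant intravascular pressure; a single interstitial solve gives the
baseline pressure field.

Approach 2: rigid network.  An angiogenic capillary network (pruned to
its perfusable loops) carries Poiseuille flow with fixed diameters and
uniform hematocrit; intravascular and interstitial pressures are
alternated until both relative errors fall below tolerance.

Approach 3: adaptive network.  On top of approach 2, every outer
iteration updates the hematocrit distribution by phase separation at
junctions, recomputes diameter- and hematocrit-dependent apparent
viscosities, and takes one structural-adaptation Euler step on the
capillary diameters; convergence is tested on P_b, P_i, D and H
simultaneously.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace

import numpy as np

from . import adaptation, angiogenesis, hemodynamics, rheology
from .config import SimulationConfig
from .interstitium import (InterstitialField, TissueDomain,
                           solve_interstitial_pressure)
from .vessel_graph import VesselNetwork, map_segments_to_grid, prune_topological


@dataclass
class RunResult:
    config: SimulationConfig
    field: InterstitialField
    network: VesselNetwork | None = None
    flow: hemodynamics.FlowState | None = None
    indicator: np.ndarray | None = None
    pb_cell: np.ndarray | None = None
    outer_iterations: int = 0
    converged: bool = True
    oscillating: bool = False  # structure cycling at a pressure plateau
    history: list[dict] = field(default_factory=list)
    max_pi_trace: list[float] = field(default_factory=list)

    @property
    def max_pi(self) -> float:
        return self.field.max_pressure

    def summary(self) -> dict:
        s = {
            "approach": self.config.approach,
            "seed": self.config.seed,
            "max_interstitial_pressure_Pa": float(self.max_pi),
            "argmax_cell": [int(i) for i in self.field.argmax],
            "outer_iterations": self.outer_iterations,
            "converged": self.converged,
        }
        if self.network is not None:
            s["n_nodes"] = self.network.n_nodes
            s["n_segments"] = self.network.n_segments
            diam = [seg.diameter for seg in self.network.segments.values()
                    if not seg.is_parent]
            if diam:
                s["capillary_diameter_um"] = {
                    "min": min(diam) * 1e6, "max": max(diam) * 1e6,
                    "mean": sum(diam) / len(diam) * 1e6}
        if self.flow is not None:
            s["inlet_flow_m3s"] = self.flow.inlet_flow
        return s


def _relative_error(new: np.ndarray, old: np.ndarray) -> float:
    """max |X_N - X_o| / max |X_N| (zero-safe)."""
    scale = np.max(np.abs(new))
    if scale == 0:
        return float(np.max(np.abs(new - old)))
    return float(np.max(np.abs(new - old)) / scale)


def run_approach1(config: SimulationConfig) -> RunResult:
    """Uniform-source baseline: no network, constant P_b in the tumor."""
    config = replace(config, approach=1)
    domain = TissueDomain(config.domain, config.tissue)
    n = config.domain.n
    if config.approach1_source == "tumor":
        indicator = domain.tumor_mask.astype(np.int8)
        pb_cell = np.where(domain.tumor_mask, config.uniform_pb, np.nan)
    else:
        indicator = np.ones((n, n), dtype=np.int8)
        pb_cell = np.full((n, n), config.uniform_pb)
    fld = solve_interstitial_pressure(domain, indicator, pb_cell,
                                      solver=config.solver)
    return RunResult(config=config, field=fld, indicator=indicator,
                     pb_cell=pb_cell, outer_iterations=1,
                     max_pi_trace=[fld.max_pressure])


def build_pruned_network(config: SimulationConfig) -> VesselNetwork:
    """Generate the angiogenic network for the configured seed and prune it."""
    domain = TissueDomain(config.domain, config.tissue)
    angio = replace(config.angio, n_sprouts=config.angio.n_sprouts)
    growth = angiogenesis.grow_network(
        angio, config.domain, domain.tumor_mask, seed=config.seed,
        parent_diameter=config.parent_diameter,
        capillary_diameter=config.capillary_diameter)
    net, _removed = prune_topological(growth.network)
    return net


def run_approach2(config: SimulationConfig,
                  network: VesselNetwork | None = None) -> RunResult:
    """Rigid-vessel coupled solve (fixed D, H = 0.45)."""
    config = replace(config, approach=2)
    return _run_coupled(config, network, adaptive=False)


def run_approach3(config: SimulationConfig,
                  network: VesselNetwork | None = None) -> RunResult:
    """Fully coupled solve with phase separation and diameter adaptation."""
    config = replace(config, approach=3)
    return _run_coupled(config, network, adaptive=True)


def _run_coupled(config: SimulationConfig, network: VesselNetwork | None,
                 adaptive: bool) -> RunResult:
    domain = TissueDomain(config.domain, config.tissue)
    net = network.copy() if network is not None else build_pruned_network(config)
    n, length = config.domain.n, config.domain.length

    # initial rheology: uniform hematocrit, diameter-dependent viscosity
    for seg in net.segments.values():
        if not seg.is_parent:
            seg.hematocrit = config.phase_sep.h_parent
    rheology.update_network_viscosity(net, config.viscosity)

    pi_grid = np.zeros((n, n))
    pb_nodes = None
    d_prev = _diameters(net)
    h_prev = _hematocrits(net)
    history: list[dict] = []
    trace: list[float] = []
    flow = None
    fld = None
    converged = False
    oscillating = False
    outer = 0

    for outer in range(1, config.coupling.max_outer + 1):
        flow = hemodynamics.solve_nodal_pressures(
            net, config.tissue, config.solver, pi_field=pi_grid,
            tumor_mask=domain.tumor_mask, n=n, length=length,
            inlet_pressure=config.inlet_pressure,
            outlet_pressure=config.outlet_pressure,
            x0=pb_nodes)
        if adaptive and config.phase_sep.enabled:
            h_before = {sid: s.hematocrit for sid, s in net.segments.items()}
            rheology.update_network_hematocrit(net, config.phase_sep)
            # damp the outer update: the critical-velocity cutoff makes the
            # junction rule bistable, and undamped H flips between states
            for sid, seg in net.segments.items():
                if not seg.is_parent:
                    seg.hematocrit = (h_before[sid]
                                      + config.phase_sep.relax
                                      * (seg.hematocrit - h_before[sid]))
        if adaptive:
            rheology.update_network_viscosity(net, config.viscosity)
        if adaptive and config.adaptation.enabled:
            adaptation.update_diameters(net, config.adaptation)

        indicator, pb_cell = map_segments_to_grid(net, n, length)
        fld = solve_interstitial_pressure(domain, indicator, pb_cell,
                                          solver=config.solver, p0=pi_grid)

        err_pb = (_relative_error(flow.pressures, pb_nodes)
                  if pb_nodes is not None else math.inf)
        err_pi = _relative_error(fld.pressure, pi_grid) if outer > 1 else math.inf
        d_new = _diameters(net)
        h_new = _hematocrits(net)
        err_d = _relative_error(d_new, d_prev) if outer > 1 else math.inf
        err_h = _relative_error(h_new, h_prev) if outer > 1 else math.inf

        pb_nodes = flow.pressures.copy()
        pi_grid = fld.pressure
        d_prev, h_prev = d_new, h_new
        trace.append(fld.max_pressure)
        history.append({"outer": outer, "err_pb": err_pb, "err_pi": err_pi,
                        "err_d": err_d, "err_h": err_h,
                        "max_pi": fld.max_pressure})

        tol_p = config.coupling.tol_pressure
        tol_s = config.coupling.tol_structure
        ok = err_pb < tol_p and err_pi < tol_p
        if adaptive:
            ok = ok and err_d < tol_s and err_h < tol_s
        if ok:
            converged = True
            break
        if adaptive and outer >= 60:
            # oscillation guard: the interstitial field has plateaued but a
            # few segments keep cycling around the hematocrit cutoff /
            # diameter clamps; further outer iterations change nothing
            recent = trace[-30:]
            plateaued = (max(recent) - min(recent)
                         < 1e-3 * max(abs(trace[-1]), 1.0))
            s_recent = [max(hh["err_d"], hh["err_h"])
                        for hh in history[-30:]]
            s_prev = [max(hh["err_d"], hh["err_h"])
                      for hh in history[-60:-30]]
            improving = np.median(s_recent) < 0.95 * np.median(s_prev)
            if plateaued and not improving:
                oscillating = True
                break

    return RunResult(config=config, field=fld, network=net, flow=flow,
                     indicator=indicator, pb_cell=pb_cell,
                     outer_iterations=outer, converged=converged,
                     oscillating=oscillating, history=history,
                     max_pi_trace=trace)


def _diameters(net: VesselNetwork) -> np.ndarray:
    return np.array([s.diameter for s in net.segments.values()])


def _hematocrits(net: VesselNetwork) -> np.ndarray:
    return np.array([s.hematocrit for s in net.segments.values()])


def compare_approaches(results: dict[int, RunResult]) -> dict[str, float]:
    """Max-pressure ratios between completed approaches."""
    shapes = {r.field.pressure.shape for r in results.values()}
    if len(shapes) > 1:
        raise ValueError("cannot compare runs on different domains")
    out = {}
    maxima = {a: r.max_pi for a, r in results.items()}
    for a in sorted(maxima):
        out[f"max_pi_approach{a}"] = maxima[a]
    for a in sorted(maxima):
        for b in sorted(maxima):
            if a < b:
                out[f"ratio_{b}_vs_{a}"] = maxima[b] / maxima[a]
    return out


def run_ensemble(config: SimulationConfig, approach: int,
                 seeds: list[int]) -> dict:
    """Run one approach over several angiogenesis seeds.

    Returns per-seed maxima plus the ensemble median and interquartile
    range of the maximum interstitial pressure.
    """
    runner = {1: run_approach1, 2: run_approach2, 3: run_approach3}[approach]
    maxima = []
    results = []
    for seed in seeds:
        cfg = replace(config, seed=int(seed))
        res = runner(cfg)
        maxima.append(res.max_pi)
        results.append(res)
    qs = statistics.quantiles(maxima, n=4) if len(maxima) > 1 else maxima * 3
    return {
        "approach": approach,
        "seeds": list(map(int, seeds)),
        "max_pi": maxima,
        "median_max_pi": float(np.median(maxima)),
        "iqr_max_pi": (qs[0], qs[2]),
        "results": results,
    }
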