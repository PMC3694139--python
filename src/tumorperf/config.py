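"""Simulation configuration.

Every physical constant of the model lives here as a named, overridable
field: tissue transport properties per region, blood rheology constants,
vessel adaptation sensitivities, boundary pressures and solver settings.
Defaults correspond to the standard parameterization for a 2 mm square
tissue domain with a 0.2 mm tumor abutting the right edge, perfused from a
parent vessel on the left edge.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal

from .units import MMHG_PA, um


@dataclass
class RegionProperties:
    """Transport properties of one tissue region (SI units)."""

    lp: float      # vessel-wall hydraulic conductivity, m/(Pa s)
    k: float       # interstitium hydraulic conductivity, m^2/(Pa s)
    sv: float      # vessel surface area per tissue volume, 1/m
    pi_b: float    # plasma oncotic pressure, Pa
    pi_i: float    # interstitial oncotic pressure, Pa
    sigma: float   # osmotic reflection coefficient

    @property
    def oncotic_drop(self) -> float:
        """Reflection-weighted oncotic pressure difference sigma*(pi_B - pi_i)."""
        return self.sigma * (self.pi_b - self.pi_i)


def _normal_tissue() -> RegionProperties:
    return RegionProperties(
        lp=0.36e-7 * 1e-2 / MMHG_PA,
        k=8.53e-9 * 1e-4 / MMHG_PA,
        sv=70.0 * 1e2,
        pi_b=20.0 * MMHG_PA,
        pi_i=10.0 * MMHG_PA,
        sigma=0.91,
    )


def _tumor_tissue() -> RegionProperties:
    return RegionProperties(
        lp=2.80e-7 * 1e-2 / MMHG_PA,
        k=4.13e-8 * 1e-4 / MMHG_PA,
        sv=200.0 * 1e2,
        pi_b=20.0 * MMHG_PA,
        pi_i=15.0 * MMHG_PA,
        sigma=0.82,
    )


@dataclass
class TissueConfig:
    normal: RegionProperties = field(default_factory=_normal_tissue)
    tumor: RegionProperties = field(default_factory=_tumor_tissue)

    def region(self, is_tumor: bool) -> RegionProperties:
        return self.tumor if is_tumor else self.normal


@dataclass
class DomainConfig:
    """Square tissue domain with a disc tumor at the right edge."""

    length: float = 2e-3          # domain side, m
    n: int = 100                  # grid cells per side
    tumor_radius: float = 0.2e-3  # m
    # Dirichlet interstitial pressure on the left (parent-vessel) edge, Pa.
    # The remaining three edges are no-flux.
    left_pressure: float = 0.0

    @property
    def h(self) -> float:
        return self.length / self.n


@dataclass
class ViscosityLaw:
    """Constants of the in-vitro apparent-viscosity fit mu_rel(D, H)."""

    mu_plasma: float = 1.2e-3     # Pa s
    # Parent-vessel apparent viscosity is pinned to the conventional bulk
    # value rather than evaluated from the small-tube fit, whose validity
    # range is narrower than a 28 um arteriole at H = 0.45.
    mu_parent: float = 3.1e-3     # Pa s


@dataclass
class PhaseSepParams:
    """Plasma-skimming (phase separation) rule at diverging bifurcations."""

    zeta: float = 0.5      # asymmetry strength of the hematocrit split
    u_cr: float = 2.5      # critical velocity ratio: slower branch gets H=0
    h_parent: float = 0.45 # discharge hematocrit held in the parent vessel
    h_max: float = 0.95    # clamp; excess red-cell flux goes to siblings
    relax: float = 0.5     # under-relaxation for the junction sweep
    tol: float = 1e-6
    max_iter: int = 200
    enabled: bool = True


@dataclass
class AdaptationParams:
    """Structural diameter adaptation sensitivities (shear/pressure/metabolic)."""

    tau_ref: float = 0.103    # Pa, shear offset avoiding log singularity
    k_p: float = 0.1          # 1/s, pressure-stimulus sensitivity
    k_m: float = 0.07         # 1/s, metabolic-stimulus sensitivity
    k_s: float = 0.35         # 1/s, intrinsic shrinking tendency
    q_ref: float = 4.87e-12   # m^3/s, parent-vessel reference flow
    q_ref_from_network: bool = True  # use max |Q_b| in the network instead
    dt: float = 0.1           # s, Euler remodeling step
    d_min: float = um(4.0)
    d_max: float = um(24.0)
    relax: float = 0.5        # under-relaxation of diameter updates
    metabolic_floor: float = 1e-6  # cap S_m at Q_b*H = floor * Q_ref
    enabled: bool = True


@dataclass
class AngioParams:
    """Discrete sprouting-angiogenesis walker on the tissue lattice."""

    n_sprouts: int = 5
    # Dimensionless constants of the endothelial tip-cell equation
    # (diffusion, saturating chemotaxis, haptotaxis) and of the TAF /
    # fibronectin dynamics.
    diffusion: float = 0.00035
    chemotaxis: float = 0.38
    chemotaxis_saturation: float = 0.6
    haptotaxis: float = 0.34
    taf_uptake: float = 0.1
    fib_production: float = 0.05
    fib_degradation: float = 0.1
    # Decay scale of the squared-distance TAF profile, scaled to the
    # parent-to-tumor approach distance so the chemotactic gradient peaks
    # mid-corridor.
    taf_decay_length: float = 0.36
    fib_decay_length: float = 0.45   # shape of the initial fibronectin profile
    # Initial fibronectin level at the parent vessel.  Kept low enough
    # that haptotaxis modulates migration without reversing it: sprouts
    # must be able to cross the domain and reach the tumor.
    fib_level: float = 0.3
    dt: float = 0.02                 # dimensionless walker time step
    max_steps: int = 4000            # enough for tips to cross the domain
    # A tip may branch only after maturing for this many steps since its
    # last branching event, and only on steps in which it advances.
    branch_age_min: int = 30
    # A tip may fuse with another sprout (anastomose) only once mature;
    # younger tips treat foreign vessels as obstacles.  This keeps
    # closely spaced sprouts from annihilating each other near the parent
    # vessel, so the final structure is nearly independent of the sprout
    # count (as observed for these networks).
    anastomosis_age_min: int = 60
    # Branching probability vs local TAF: right-continuous step schedule.
    branch_taf_thresholds: tuple[float, ...] = (0.3, 0.5, 0.7, 0.8)
    branch_probabilities: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 1.0)


@dataclass
class SolverConfig:
    # Both linear systems are sparse and well conditioned; the default
    # backend is a direct factorization (the grid operator is constant
    # across coupling iterations, so its LU factors are cached).
    # Classical SOR is available for both and agrees with the direct
    # route to solver precision.
    network_method: Literal["sor", "direct"] = "direct"
    grid_method: Literal["sor", "direct"] = "direct"
    omega_grid: float = 1.94      # SOR factor for the interstitial grid
    omega_network: float = 1.5    # SOR factor for the nodal network solve
    tol: float = 1e-6             # relative-change convergence threshold
    max_iter: int = 100_000


@dataclass
class CouplingConfig:
    tol_pressure: float = 1e-6    # relative error on P_b and P_i
    tol_structure: float = 1e-4   # relative error on D and H
    max_outer: int = 500


@dataclass
class SimulationConfig:
    approach: Literal[1, 2, 3] = 1
    seed: int = 0
    inlet_pressure: float = 3325.0    # Pa (25 mmHg)
    outlet_pressure: float = 1330.0   # Pa (10 mmHg)
    # No-network baseline (approach 1): intravascular pressure is uniform
    # and held constant at its initialization value (the outlet pressure),
    # with the blood source distributed over the whole domain.  Both are
    # config options; "tumor" restricts the source to the tumor disc.
    uniform_pb: float = 1330.0
    approach1_source: Literal["everywhere", "tumor"] = "everywhere"
    parent_diameter: float = um(28.0)
    capillary_diameter: float = um(12.0)
    domain: DomainConfig = field(default_factory=DomainConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)
    angio: AngioParams = field(default_factory=AngioParams)
    viscosity: ViscosityLaw = field(default_factory=ViscosityLaw)
    phase_sep: PhaseSepParams = field(default_factory=PhaseSepParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return _from_dict(cls, json.loads(text))


def _from_dict(cls, data):
    if not dataclasses.is_dataclass(cls):
        if cls in (tuple, "tuple") or (hasattr(cls, "__origin__") and cls.__origin__ is tuple):
            return tuple(data)
        return data
    kwargs = {}
    hints = {f.name: f.type for f in dataclasses.fields(cls)}
    types = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in hints:
            raise KeyError(f"unknown config key {key!r} for {cls.__name__}")
        f = types[key]
        target = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(target):
            kwargs[key] = _from_dict(type(target), value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
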