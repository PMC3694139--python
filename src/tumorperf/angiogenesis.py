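"""Discrete sprouting angiogenesis on the tissue lattice.

Endothelial tip cells start from sprout roots on the parent vessel and
execute a biased random walk toward the tumor, following the classic
discrete tip-cell scheme: movement probabilities come from the 5-point
discretization of a tip-density equation with random motility, saturating
chemotaxis up the tumor-angiogenic-factor (TAF) gradient, and haptotaxis
up the fibronectin gradient.  Tips branch with a probability that
increases with local TAF (once old enough) and fuse (anastomose) when
they step onto an occupied cell, which is what creates perfusable loops.
The trail of every tip becomes a chain of capillary segments on the
lattice, rooted in the parent vessel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AngioParams, DomainConfig
from .vessel_graph import Node, Segment, VesselNetwork, make_parent_vessel


class AngiogenesisError(RuntimeError):
    pass


@dataclass
class ChemFields:
    """Dimensionless TAF and fibronectin concentration grids."""

    taf: np.ndarray
    fibronectin: np.ndarray


def init_fields(params: AngioParams, tumor_mask: np.ndarray) -> ChemFields:
    """Initial TAF and fibronectin profiles.

    TAF decays with distance from the tumor surface (maximal on the
    tumor, nondimensionalized to [0, 1]); fibronectin decays away from
    the parent vessel at the left edge.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise AngiogenesisError("tumor mask is empty")
    n = tumor_mask.shape[0]
    # nondimensional cell-center coordinates
    coords = (np.arange(n) + 0.5) / n
    x, y = np.meshgrid(coords, coords, indexing="ij")
    ti, tj = np.nonzero(tumor_mask)
    # distance from each cell to the nearest tumor cell
    d2 = np.full((n, n), np.inf)
    tx, ty = x[ti, tj], y[ti, tj]
    # tumor masks are small; loop over tumor cells in chunks
    for cx, cy in zip(tx, ty):
        d2 = np.minimum(d2, (x - cx) ** 2 + (y - cy) ** 2)
    taf = np.exp(-d2 / params.taf_decay_length)
    taf[tumor_mask] = 1.0
    fib = params.fib_level * np.exp(-x ** 2 / params.fib_decay_length)
    return ChemFields(taf=taf, fibronectin=fib)


def movement_probabilities(tip: tuple[int, int], fields: ChemFields,
                           params: AngioParams
                           ) -> tuple[float, float, float, float, float]:
    """(P_stay, P_left, P_right, P_up, P_down) for one walker step.

    Derived from the explicit 5-point stencil of the tip-density
    equation; out-of-domain moves are masked and the five probabilities
    renormalized to sum to one.
    """
    i, j = tip
    c, f = fields.taf, fields.fibronectin
    n = c.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise AngiogenesisError(f"tip {tip} outside the grid")
    h = 1.0 / n
    k = params.dt
    base = k * params.diffusion / h ** 2
    chi = params.chemotaxis / (1.0 + params.chemotaxis_saturation * c[i, j])
    rho = params.haptotaxis

    def grad_pair(field_, axis):
        if axis == 0:
            plus = field_[min(i + 1, n - 1), j]
            minus = field_[max(i - 1, 0), j]
        else:
            plus = field_[i, min(j + 1, n - 1)]
            minus = field_[i, max(j - 1, 0)]
        return plus - minus

    drift_x = k / (4.0 * h ** 2) * (chi * grad_pair(c, 0) + rho * grad_pair(f, 0))
    drift_y = k / (4.0 * h ** 2) * (chi * grad_pair(c, 1) + rho * grad_pair(f, 1))

    p_right = max(base + drift_x, 0.0)
    p_left = max(base - drift_x, 0.0)
    p_up = max(base + drift_y, 0.0)
    p_down = max(base - drift_y, 0.0)
    p_stay = max(1.0 - (p_right + p_left + p_up + p_down), 0.0)

    # mask moves that leave the domain
    if i == 0:
        p_left = 0.0
    if i == n - 1:
        p_right = 0.0
    if j == 0:
        p_down = 0.0
    if j == n - 1:
        p_up = 0.0
    total = p_stay + p_left + p_right + p_up + p_down
    if total <= 0:
        raise AngiogenesisError(f"all moves masked at {tip}")
    return (p_stay / total, p_left / total, p_right / total,
            p_up / total, p_down / total)


def branch_probability(taf_value: float, params: AngioParams) -> float:
    for threshold, p in zip(params.branch_taf_thresholds,
                            params.branch_probabilities):
        if taf_value < threshold:
            return p
    return params.branch_probabilities[-1]


@dataclass
class _Tip:
    cell: tuple[int, int]
    node_id: int
    prev_cell: tuple[int, int] | None = None
    age: int = 0


@dataclass
class GrowthResult:
    network: VesselNetwork
    n_anastomoses: int
    n_branches: int
    steps: int
    fields: ChemFields = None
    live_tips: list = None  # tips still active when growth ended


def grow_network(params: AngioParams, domain: DomainConfig,
                 tumor_mask: np.ndarray, seed: int,
                 parent_diameter: float = 28e-6,
                 capillary_diameter: float = 12e-6) -> GrowthResult:
    """Run the sprouting walk and return the lattice capillary network.

    The parent vessel occupies the left edge; ``params.n_sprouts`` roots
    are spaced evenly along it.  Tips may invade and vascularize the
    tumor itself.  Growth ends when every tip has fused into a junction,
    or after ``max_steps`` walker steps.
    """
    rng = np.random.default_rng(seed)
    n = domain.n
    h = domain.h
    fields = init_fields(params, tumor_mask)
    net = make_parent_vessel(n, domain.length, diameter=parent_diameter)
    next_node = n
    next_seg = n  # parent used ids 0..n-2 for segments, 0..n-1 for nodes

    occupancy = np.full((n, n), -1, dtype=np.int64)
    for j in range(n):
        occupancy[0, j] = j  # parent nodes sit in column 0

    edges_seen: set[frozenset] = set()
    for seg in net.segments.values():
        edges_seen.add(frozenset((seg.node_a, seg.node_b)))

    # sprout roots evenly spaced along the parent, away from inlet/outlet
    root_rows = np.linspace(0, n - 1, params.n_sprouts + 2)[1:-1]
    root_rows = np.round(root_rows).astype(int)
    tips: list[_Tip] = [
        _Tip(cell=(0, int(j)), node_id=int(j)) for j in root_rows]

    n_anastomoses = 0
    n_branches = 0

    def node_at(cell: tuple[int, int]) -> int:
        nonlocal next_node
        nid = occupancy[cell]
        if nid >= 0:
            return int(nid)
        node = net.add_node(Node(next_node, (cell[0] + 0.5) * h,
                                 (cell[1] + 0.5) * h))
        occupancy[cell] = next_node
        next_node += 1
        return node.id

    def link(a: int, b: int) -> bool:
        nonlocal next_seg
        pair = frozenset((a, b))
        if a == b or pair in edges_seen:
            return False
        net.add_segment(Segment(next_seg, a, b, diameter=capillary_diameter,
                                length=h, hematocrit=0.45))
        edges_seen.add(pair)
        next_seg += 1
        return True

    moves = {1: (-1, 0), 2: (1, 0), 3: (0, 1), 4: (0, -1)}
    step = 0
    for step in range(1, params.max_steps + 1):
        if not tips:
            break
        new_tips: list[_Tip] = []
        for tip in tips:
            probs = movement_probabilities(tip.cell, fields, params)
            u = rng.random()
            acc = 0.0
            choice = 4
            for idx, p in enumerate(probs):
                acc += p
                if u < acc:
                    choice = idx
                    break
            tip.age += 1
            if choice == 0:
                new_tips.append(tip)
                continue
            di, dj = moves[choice]
            target = (tip.cell[0] + di, tip.cell[1] + dj)
            # the parent column is not a walk target (sprouts attach to
            # the parent only at their roots); immediate backtracking is
            # not a fusion event
            if target[0] < 1 or target == tip.prev_cell:
                new_tips.append(tip)
                continue
            occupied = occupancy[target] >= 0
            if occupied and tip.age < params.anastomosis_age_min:
                new_tips.append(tip)  # too young to fuse: blocked
                continue
            target_node = node_at(target)
            link(tip.node_id, target_node)
            if occupied:
                # anastomosis: stepping onto any existing vessel creates a
                # junction and retires the tip
                n_anastomoses += 1
                continue
            tip.prev_cell = tip.cell
            tip.cell = target
            tip.node_id = target_node
            new_tips.append(tip)
            # branching: only a mature, advancing tip may split, with
            # probability set by the local TAF level
            if tip.age >= params.branch_age_min:
                p_branch = branch_probability(fields.taf[tip.cell], params)
                if rng.random() < p_branch:
                    free = []
                    for di, dj in moves.values():
                        t = (tip.cell[0] + di, tip.cell[1] + dj)
                        if 1 <= t[0] < n and 0 <= t[1] < n and occupancy[t] < 0:
                            free.append(t)
                    if free:
                        btarget = free[rng.integers(len(free))]
                        btarget_node = node_at(btarget)
                        link(tip.node_id, btarget_node)
                        n_branches += 1
                        tip.age = 0
                        new_tips.append(_Tip(cell=btarget,
                                             node_id=btarget_node,
                                             prev_cell=tip.cell))
        tips = new_tips
        # local chemical dynamics where tip cells currently sit (uptake and
        # fibronectin turnover scale with tip density, not trail length)
        for tip in tips:
            c = tip.cell
            fields.taf[c] *= max(1.0 - params.dt * params.taf_uptake, 0.0)
            # deposition saturates at the perivascular matrix level, so a
            # lingering tip cannot build a fibronectin hill that pins it
            # in place by haptotaxis
            f_new = fields.fibronectin[c] + params.dt * (
                params.fib_production
                - params.fib_degradation * fields.fibronectin[c])
            fields.fibronectin[c] = min(f_new, params.fib_level)

    return GrowthResult(network=net, n_anastomoses=n_anastomoses,
                        n_branches=n_branches, steps=step, fields=fields,
                        live_tips=tips)
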