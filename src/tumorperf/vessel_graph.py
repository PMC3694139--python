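"""Graph data model for the capillary network.

Nodes sit at cell centers of the tissue lattice; segments run along
4-neighbor lattice edges, so a capillary segment has length equal to the
grid spacing h.  The parent vessel is a chain of fixed-diameter segments
along the left edge of the domain with an inlet node at one end and an
outlet node at the other.

The module also owns the two pruning rules applied to raw angiogenesis
output (non-loop removal and low-flow removal) and the mapping of segments
onto the tissue grid that feeds the interstitial source term.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NetworkError(ValueError):
    """Structural or validation problem in a vessel network."""


class NoPerfusedLoopError(NetworkError):
    """Topological pruning removed every capillary: no anastomosis formed."""


@dataclass
class Node:
    id: int
    x: float            # m
    y: float            # m
    pressure: float = math.nan   # intravascular pressure P_b, Pa
    role: str = "interior"       # interior | inlet | outlet

    @property
    def is_boundary(self) -> bool:
        return self.role in ("inlet", "outlet")


@dataclass
class Segment:
    id: int
    node_a: int
    node_b: int
    diameter: float          # m
    length: float            # m
    hematocrit: float = 0.45
    viscosity: float = math.nan   # apparent viscosity, Pa s
    flow: float = math.nan        # Q_b, m^3/s, signed positive a -> b
    flow_trans: float = math.nan  # Q_t, m^3/s, positive out of the vessel
    wall_shear: float = math.nan  # tau_w, Pa
    is_parent: bool = False

    def other(self, node_id: int) -> int:
        if node_id == self.node_a:
            return self.node_b
        if node_id == self.node_b:
            return self.node_a
        raise KeyError(f"node {node_id} not an endpoint of segment {self.id}")


@dataclass
class VesselNetwork:
    nodes: dict[int, Node] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    _adj: dict[int, list[int]] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise NetworkError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        self._adj[node.id] = []
        return node

    def add_segment(self, seg: Segment) -> Segment:
        if seg.id in self.segments:
            raise NetworkError(f"duplicate segment id {seg.id}")
        for nid in (seg.node_a, seg.node_b):
            if nid not in self.nodes:
                raise NetworkError(
                    f"segment {seg.id} references missing node {nid}")
        if seg.node_a == seg.node_b:
            raise NetworkError(f"segment {seg.id} is a self-loop")
        if seg.length <= 0:
            raise NetworkError(f"segment {seg.id} has non-positive length")
        self.segments[seg.id] = seg
        self._adj[seg.node_a].append(seg.id)
        self._adj[seg.node_b].append(seg.id)
        return seg

    def remove_segment(self, seg_id: int) -> None:
        seg = self.segments.pop(seg_id)
        self._adj[seg.node_a].remove(seg_id)
        self._adj[seg.node_b].remove(seg_id)

    def remove_isolated_nodes(self) -> list[int]:
        dead = [nid for nid, inc in self._adj.items()
                if not inc and not self.nodes[nid].is_boundary]
        for nid in dead:
            del self._adj[nid]
            del self.nodes[nid]
        return dead

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def degree(self, node_id: int) -> int:
        return len(self._adj[node_id])

    def segments_at(self, node_id: int) -> list[Segment]:
        return [self.segments[s] for s in self._adj[node_id]]

    def connected(self, c: int, k: int) -> bool:
        """Connectivity indicator I_ck between two nodes."""
        return any(self.segments[s].other(c) == k for s in self._adj[c])

    def has_flows(self) -> bool:
        return all(math.isfinite(s.flow) for s in self.segments.values())

    def component_of(self, start: int) -> set[int]:
        """Node ids reachable from ``start``."""
        seen = {start}
        stack = [start]
        while stack:
            nid = stack.pop()
            for sid in self._adj[nid]:
                other = self.segments[sid].other(nid)
                if other not in seen:
                    seen.add(other)
                    stack.append(other)
        return seen

    def copy(self) -> "VesselNetwork":
        return copy.deepcopy(self)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.node_a, seg.node_b, key=seg.id)
        return g


# ---------------------------------------------------------------------
# construction from tables

def build_network(nodes: pd.DataFrame, edges: pd.DataFrame,
                  capillary_diameter: float = 12e-6,
                  parent_hematocrit: float = 0.45) -> VesselNetwork:
    """Build a network from node and edge tables.

    ``nodes`` needs columns (id, x_m, y_m) and optionally role;
    ``edges`` needs (id, node_a, node_b) and optionally diameter_m,
    length_m, hematocrit.  Missing capillary diameters default to 12 um
    and the parent hematocrit to 0.45.
    """
    net = VesselNetwork()
    for row in nodes.itertuples(index=False):
        role = getattr(row, "role", "interior")
        pressure = float(getattr(row, "pressure_Pa", math.nan))
        net.add_node(Node(int(row.id), float(row.x_m), float(row.y_m),
                          pressure=pressure, role=str(role)))
    seen_pairs: set[frozenset] = set()
    for row in edges.itertuples(index=False):
        a, b = int(row.node_a), int(row.node_b)
        pair = frozenset((a, b))
        if pair in seen_pairs:
            raise NetworkError(f"duplicate edge between nodes {a} and {b}")
        seen_pairs.add(pair)
        if a not in net.nodes or b not in net.nodes:
            raise NetworkError(f"edge {row.id} references a missing node")
        length = float(getattr(row, "length_m", math.nan))
        if math.isnan(length):
            na, nb = net.nodes[a], net.nodes[b]
            length = math.hypot(na.x - nb.x, na.y - nb.y)
        is_parent = bool(getattr(row, "is_parent", False))
        diameter = float(getattr(row, "diameter_m", math.nan))
        if math.isnan(diameter):
            diameter = capillary_diameter
        hematocrit = float(getattr(row, "hematocrit", math.nan))
        if math.isnan(hematocrit):
            hematocrit = parent_hematocrit
        net.add_segment(Segment(int(row.id), a, b, diameter=diameter,
                                length=length, hematocrit=hematocrit,
                                is_parent=is_parent))
    return net


# ---------------------------------------------------------------------
# pruning

def prune_topological(net: VesselNetwork, in_place: bool = False
                      ) -> tuple[VesselNetwork, list[int]]:
    """Remove segments that cannot belong to a perfused loop.

    Repeatedly strips segments incident to a non-boundary node of degree
    < 2 until stable, then drops components not reachable from the
    inlet.  Returns the pruned network and the removed segment ids.
    Idempotent on its own output.
    """
    if not in_place:
        net = net.copy()
    removed: list[int] = []
    changed = True
    while changed:
        changed = False
        for nid in list(net.nodes):
            node = net.nodes[nid]
            if node.is_boundary:
                continue
            if 0 < net.degree(nid) < 2:
                for seg in list(net.segments_at(nid)):
                    net.remove_segment(seg.id)
                    removed.append(seg.id)
                changed = True
    net.remove_isolated_nodes()

    inlets = [nid for nid, n in net.nodes.items() if n.role == "inlet"]
    if inlets:
        reachable = net.component_of(inlets[0])
        for sid in list(net.segments):
            seg = net.segments[sid]
            if seg.node_a not in reachable:
                net.remove_segment(sid)
                removed.append(sid)
        net.remove_isolated_nodes()

    if not any(not s.is_parent for s in net.segments.values()):
        raise NoPerfusedLoopError(
            "topological pruning removed every capillary segment: "
            "the angiogenesis run produced no anastomosis")
    return net, removed


def prune_by_flow(net: VesselNetwork, fraction: float = 0.01,
                  in_place: bool = False) -> tuple[VesselNetwork, list[int]]:
    """Remove segments carrying less than ``fraction`` of the peak flow.

    Requires a completed flow solve; the default threshold is 1% of the
    maximum |Q_b| in the network.
    """
    if not net.has_flows():
        raise NetworkError("prune_by_flow requires solved segment flows")
    if not in_place:
        net = net.copy()
    removed: list[int] = []
    if fraction <= 0 or not net.segments:
        return net, removed
    qmax = max(abs(s.flow) for s in net.segments.values())
    for sid in list(net.segments):
        if abs(net.segments[sid].flow) < fraction * qmax:
            net.remove_segment(sid)
            removed.append(sid)
    net.remove_isolated_nodes()
    return net, removed


# ---------------------------------------------------------------------
# grid mapping

def grid_index(net_or_h, x: float, y: float, n: int, h: float) -> tuple[int, int]:
    """Cell (i, j) containing the point; nodes sit at cell centers."""
    i = int(math.floor(x / h))
    j = int(math.floor(y / h))
    # points exactly on the far boundary belong to the last cell
    i = min(max(i, 0), n - 1)
    j = min(max(j, 0), n - 1)
    return i, j


def map_segments_to_grid(net: VesselNetwork, n: int, length: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Map segments onto the grid: source indicator A and per-cell mean P_b.

    A(i, j) = 1 iff at least one segment endpoint lies in cell (i, j);
    with segments along lattice edges between cell centers this marks
    every cell a segment traverses.  The per-cell intravascular pressure
    is the unweighted mean of the endpoint nodal pressures of all
    incident segments.
    """
    h = length / n
    a = np.zeros((n, n), dtype=np.int8)
    psum = np.zeros((n, n))
    pcount = np.zeros((n, n), dtype=np.int64)
    for seg in net.segments.values():
        na, nb = net.nodes[seg.node_a], net.nodes[seg.node_b]
        for node in (na, nb):
            if not (-0.5 * h <= node.x <= length + 0.5 * h
                    and -0.5 * h <= node.y <= length + 0.5 * h):
                raise NetworkError(
                    f"segment {seg.id} endpoint outside the domain")
        pa, pb = na.pressure, nb.pressure
        for node in (na, nb):
            i, j = grid_index(net, node.x, node.y, n, h)
            a[i, j] = 1
            for p in (pa, pb):
                if math.isfinite(p):
                    psum[i, j] += p
                    pcount[i, j] += 1
    pb_cell = np.full((n, n), math.nan)
    mask = pcount > 0
    pb_cell[mask] = psum[mask] / pcount[mask]
    return a, pb_cell


# ---------------------------------------------------------------------
# parent vessel

def make_parent_vessel(n: int, length: float, diameter: float = 28e-6,
                       hematocrit: float = 0.45) -> VesselNetwork:
    """Chain of fixed-diameter segments along the left edge.

    Inlet node at the bottom end, outlet node at the top end; nodes at
    the cell centers of column 0.
    """
    h = length / n
    net = VesselNetwork()
    x = 0.5 * h
    for j in range(n):
        role = "inlet" if j == 0 else ("outlet" if j == n - 1 else "interior")
        net.add_node(Node(j, x, (j + 0.5) * h, role=role))
    for j in range(n - 1):
        net.add_segment(Segment(j, j, j + 1, diameter=diameter, length=h,
                                hematocrit=hematocrit, is_parent=True))
    return net


# ---------------------------------------------------------------------
# CSV dialect

NODE_COLUMNS = ["id", "x_m", "y_m", "role", "pressure_Pa"]
SEGMENT_COLUMNS = ["id", "node_a", "node_b", "diameter_m", "length_m",
                   "hematocrit", "flow_m3s", "pressure_a_Pa", "pressure_b_Pa",
                   "is_parent"]


def network_to_tables(net: VesselNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nrows = [(n.id, n.x, n.y, n.role, n.pressure)
             for n in net.nodes.values()]
    srows = [(s.id, s.node_a, s.node_b, s.diameter, s.length, s.hematocrit,
              s.flow, net.nodes[s.node_a].pressure,
              net.nodes[s.node_b].pressure, s.is_parent)
             for s in net.segments.values()]
    nodes = pd.DataFrame(nrows, columns=NODE_COLUMNS)
    segments = pd.DataFrame(srows, columns=SEGMENT_COLUMNS)
    return nodes, segments


def write_network(net: VesselNetwork, nodes_path, segments_path) -> None:
    nodes, segments = network_to_tables(net)
    nodes.to_csv(nodes_path, index=False, float_format="%.12g")
    segments.to_csv(segments_path, index=False, float_format="%.12g")


def read_network(nodes_path, segments_path) -> VesselNetwork:
    nodes = pd.read_csv(nodes_path)
    segments = pd.read_csv(segments_path)
    net = build_network(nodes, segments)
    if "flow_m3s" in segments.columns:
        for row in segments.itertuples(index=False):
            net.segments[int(row.id)].flow = float(row.flow_m3s)
    return net
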