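"""Small hand-checkable vessel networks for testing and examples.

Each generator returns a VesselNetwork whose flow solution can be
verified by hand: a single straight vessel, a Y-bifurcation, and a
diamond loop.  Geometry lives on a lattice with the given spacing; the
inlet sits at the left end and the outlet at the right end.
"""

from __future__ import annotations

from .vessel_graph import Node, Segment, VesselNetwork


def single_vessel(n_segments: int = 10, h: float = 20e-6,
                  diameter: float = 12e-6, viscosity: float = 2e-3
                  ) -> VesselNetwork:
    """Straight chain of equal segments; inlet left, outlet right."""
    net = VesselNetwork()
    for i in range(n_segments + 1):
        role = "inlet" if i == 0 else (
            "outlet" if i == n_segments else "interior")
        net.add_node(Node(i, i * h, 0.0, role=role))
    for i in range(n_segments):
        seg = net.add_segment(Segment(i, i, i + 1, diameter=diameter, length=h))
        seg.viscosity = viscosity
    return net


def y_bifurcation(h: float = 20e-6, d_parent: float = 16e-6,
                  d_daughters: tuple[float, float] = (12e-6, 12e-6),
                  viscosity: float = 2e-3) -> VesselNetwork:
    """One feeding segment splitting into two daughters that stay open.

    Both daughters end at outlet nodes so the flow split can be checked
    against the conductance ratio.
    """
    net = VesselNetwork()
    net.add_node(Node(0, 0.0, h, role="inlet"))
    net.add_node(Node(1, h, h))
    net.add_node(Node(2, 2 * h, 2 * h, role="outlet"))
    net.add_node(Node(3, 2 * h, 0.0, role="outlet"))
    specs = [(0, 0, 1, d_parent), (1, 1, 2, d_daughters[0]),
             (2, 1, 3, d_daughters[1])]
    for sid, a, b, d in specs:
        seg = net.add_segment(Segment(sid, a, b, diameter=d, length=h))
        seg.viscosity = viscosity
    return net


def diamond_loop(h: float = 20e-6, diameter: float = 12e-6,
                 viscosity: float = 2e-3,
                 limb_diameters: tuple[float, float] | None = None
                 ) -> VesselNetwork:
    """Four-node diamond: inlet, two parallel limbs, outlet."""
    d_top, d_bottom = limb_diameters or (diameter, diameter)
    net = VesselNetwork()
    net.add_node(Node(0, 0.0, h, role="inlet"))
    net.add_node(Node(1, h, 2 * h))
    net.add_node(Node(2, h, 0.0))
    net.add_node(Node(3, 2 * h, h, role="outlet"))
    specs = [(0, 0, 1, d_top), (1, 0, 2, d_bottom),
             (2, 1, 3, d_top), (3, 2, 3, d_bottom)]
    for sid, a, b, d in specs:
        seg = net.add_segment(Segment(sid, a, b, diameter=d, length=h))
        seg.viscosity = viscosity
    return net
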