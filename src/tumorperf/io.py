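"""Plain-text exporters: pressure-field matrices and legacy-VTK files.

The VTK writer emits ASCII structured-points files readable by ParaView;
it is deliberately minimal (scalars on a uniform 2-D grid) since that is
all the simulator produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .coupling import RunResult
from .vessel_graph import write_network


def write_matrix(path, field: np.ndarray) -> None:
    """Row-major text matrix, one grid line per row, 12 significant digits."""
    np.savetxt(path, np.asarray(field).T, fmt="%.12g")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path).T


def write_vtk_scalar(path, field: np.ndarray, name: str, spacing: float
                     ) -> None:
    """Legacy ASCII VTK structured-points file for one cell-centered scalar."""
    arr = np.asarray(field)
    nx, ny = arr.shape
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {spacing / 2:.9g} {spacing / 2:.9g} 0",
        f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}",
        f"POINT_DATA {nx * ny}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK expects x varying fastest
    flat = arr.T.reshape(-1)
    lines.extend(f"{v:.9g}" for v in flat)
    Path(path).write_text("\n".join(lines) + "\n")


def export_run(result: RunResult, outdir) -> dict:
    """Write the standard artifact set for one run; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config.domain.h
    write_matrix(outdir / "interstitial_pressure.txt", result.field.pressure)
    write_vtk_scalar(outdir / "interstitial_pressure.vtk",
                     result.field.pressure, "interstitial_pressure_Pa", h)
    if result.network is not None:
        write_network(result.network, outdir / "nodes.csv",
                      outdir / "segments.csv")
    if result.flow is not None:
        lines = ["node_id residual_m3s"]
        lines += [f"{nid} {r:.6e}" for nid, r in
                  zip(result.flow.node_ids, result.flow.residuals)]
        (outdir / "flow_residuals.txt").write_text("\n".join(lines) + "\n")
    if result.history:
        (outdir / "outer_iterations.json").write_text(
            json.dumps(result.history, indent=1) + "\n")
    summary = result.summary()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
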