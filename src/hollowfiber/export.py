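"""Field export: CSV tables and legacy-ASCII VTK structured grids.

The VTK writer emits the minimal legacy format (``STRUCTURED_GRID`` with
cell data), which ParaView and VisIt read directly; fields are attached as
cell scalars on the axisymmetric (x, r) plane.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["fields_to_frame", "fields_to_csv", "fields_to_vtk"]


def fields_to_frame(grid, flow=None, conc=None) -> pd.DataFrame:
    """Cell-centred long-format table of coordinates, region and fields."""
    nx, nr = grid.nx, grid.nr
    X, R = np.meshgrid(grid.xc, grid.rc, indexing="ij")
    data = {
        "x": X.ravel(),
        "r": R.ravel(),
        "region": grid.region.ravel(),
    }
    if flow is not None:
        data["p"] = flow.p.ravel()
        data["vx"] = (0.5 * (flow.u[:-1, :] + flow.u[1:, :])).ravel()
        data["vr"] = (0.5 * (flow.v[:, :-1] + flow.v[:, 1:])).ravel()
    if conc is not None:
        data["C"] = conc.Cb.ravel()
    return pd.DataFrame(data)


def fields_to_csv(path, grid, flow=None, conc=None) -> Path:
    path = Path(path)
    fields_to_frame(grid, flow, conc).to_csv(path, index=False)
    return path


def fields_to_vtk(path, grid, flow=None, conc=None) -> Path:
    """Write the grid (and any fields) as a legacy-ASCII VTK structured grid."""
    path = Path(path)
    nxp, nrp = grid.nx + 1, grid.nr + 1
    lines = [
        "# vtk DataFile Version 3.0",
        "hollowfiber axisymmetric (x, r) fields",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nxp} {nrp} 1",
        f"POINTS {nxp * nrp} double",
    ]
    for r in grid.r_faces:
        for x in grid.x_faces:
            lines.append(f"{x:.9e} {r:.9e} 0.0")
    lines.append(f"CELL_DATA {grid.nx * grid.nr}")

    def scalar(name, values_xr, fmt="{:.9e}"):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest, then r
        for j in range(grid.nr):
            for i in range(grid.nx):
                lines.append(fmt.format(values_xr[i, j]))

    region_code = {"tube": 0.0, "membrane": 1.0, "shell": 2.0}
    reg = np.vectorize(region_code.get)(grid.region)
    scalar("region", reg, fmt="{:.1f}")
    if flow is not None:
        scalar("p", flow.p)
        scalar("vx", 0.5 * (flow.u[:-1, :] + flow.u[1:, :]))
        scalar("vr", 0.5 * (flow.v[:, :-1] + flow.v[:, 1:]))
    if conc is not None:
        scalar("C", conc.Cb)
    path.write_text("\n".join(lines) + "\n")
    return path
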