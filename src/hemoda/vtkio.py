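"""Plain-text exports: VTK legacy structured-points fields and CSV tables."""

from __future__ import annotations

import numpy as np

from .geometry import GeometryMask
from .solver import VelocityField


def write_vtk_field(path, field: VelocityField, geom: GeometryMask) -> None:
    """Write cell-centered velocity, pressure and the fluid mask as an ASCII
    VTK legacy STRUCTURED_POINTS file (point data on the cell-center lattice).
    """
    nx, ny = geom.shape
    h = geom.spacing
    uc, vc = field.cell_center_velocity()
    fluid = geom.is_fluid
    n = nx * ny
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"hemoda velocity field t={field.time:.6f}s\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write(f"ORIGIN {0.5 * h:.8e} {0.5 * h:.8e} 0.0\n")
        f.write(f"SPACING {h:.8e} {h:.8e} {h:.8e}\n")
        f.write(f"POINT_DATA {n}\n")
        f.write("VECTORS velocity float\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{uc[i, j]:.6e} {vc[i, j]:.6e} 0.0\n")
        f.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{field.p[i, j]:.6e}\n")
        f.write("SCALARS fluid_mask int 1\nLOOKUP_TABLE default\n")
        for j in range(ny):
            for i in range(nx):
                f.write(f"{int(fluid[i, j])}\n")


def observations_to_frame(obs) -> "pd.DataFrame":
    """Tidy table (voxel center x, y, component, value, variance)."""
    import pandas as pd

    rows = []
    for k in range(obs.n_voxels):
        x, y = obs.voxel_centers[k]
        for c, comp in enumerate(("u", "v")):
            rows.append((obs.time, x, y, comp, obs.values[k, c], obs.variance))
    return pd.DataFrame(
        rows, columns=["time_s", "x_m", "y_m", "component", "value", "variance"]
    )
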