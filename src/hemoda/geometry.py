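"""Masked 2D vessel geometries on a regular Cartesian grid.

Geometries are cell-flag masks on an ``nx x ny`` grid with spacing ``h``
(meters).  Cells are labelled fluid, wall, or as members of an inlet/outlet
port; ports are contiguous strips of fluid cells on the domain boundary where
flow rates (inlets) or flow-split ratios (outlets) are prescribed.

Three builders are provided: a straight channel, a T-shaped bifurcation
(1 inlet, 2 outlets) and a "loop" network (2 inlets, 2 outlets joined by two
collateral connectors) that mimics the redundant pathways of the circle of
Willis at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

WALL = 0
FLUID = 1
INLET_BASE = 10  # inlet i -> flag INLET_BASE + i
OUTLET_BASE = 20  # outlet j -> flag OUTLET_BASE + j

_EDGES = ("left", "right", "bottom", "top")


@dataclass(frozen=True)
class Port:
    """A contiguous strip of boundary cells where flow is prescribed.

    ``cells`` are (i, j) indices of the port cells; ``edge`` names the domain
    boundary the strip touches.  The port's prescribed faces are the domain
    boundary faces of those cells; ``normal`` is the inward unit direction.
    """

    role: str  # "inlet" | "outlet"
    index: int  # 0-based within its role
    edge: str  # left/right/bottom/top
    cells: tuple[tuple[int, int], ...]

    @property
    def normal(self) -> tuple[int, int]:
        return {
            "left": (1, 0),
            "right": (-1, 0),
            "bottom": (0, 1),
            "top": (0, -1),
        }[self.edge]

    @property
    def width_cells(self) -> int:
        return len(self.cells)


@dataclass
class GeometryMask:
    """Cell-flag mask plus port metadata for a 2D vascular domain."""

    cell_flag: np.ndarray  # (nx, ny) int
    spacing: float  # m
    ports: list[Port] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.cell_flag = np.asarray(self.cell_flag, dtype=int)

    # -- basic queries -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_flag.shape

    @property
    def is_fluid(self) -> np.ndarray:
        """Boolean (nx, ny): fluid including port cells."""
        return self.cell_flag >= FLUID

    @property
    def n_fluid(self) -> int:
        return int(self.is_fluid.sum())

    @property
    def inlets(self) -> list[Port]:
        return [p for p in self.ports if p.role == "inlet"]

    @property
    def outlets(self) -> list[Port]:
        return [p for p in self.ports if p.role == "outlet"]

    @property
    def n_inlets(self) -> int:
        return len(self.inlets)

    @property
    def n_outlets(self) -> int:
        return len(self.outlets)

    @property
    def extent(self) -> tuple[float, float]:
        nx, ny = self.shape
        return nx * self.spacing, ny * self.spacing

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.shape
        x = (np.arange(nx) + 0.5) * self.spacing
        y = (np.arange(ny) + 0.5) * self.spacing
        return x, y

    # -- wall adjacency (for wall shear stress) ------------------------
    def wall_adjacency(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Pairs (fluid cell, unit normal pointing from the cell into the wall).

        Domain-exterior faces count as walls unless they belong to a port.
        """
        nx, ny = self.shape
        fluid = self.is_fluid
        port_faces = {
            (c, p.normal) for p in self.ports for c in p.cells
        }  # (cell, inward normal)
        out = []
        for i in range(nx):
            for j in range(ny):
                if not fluid[i, j]:
                    continue
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    outside = not (0 <= ni < nx and 0 <= nj < ny)
                    if outside:
                        # boundary face; a port face is open, not a wall
                        if ((i, j), (-di, -dj)) in port_faces:
                            continue
                        out.append(((i, j), (di, dj)))
                    elif not fluid[ni, nj]:
                        out.append(((i, j), (di, dj)))
        return out

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        fluid = self.is_fluid
        if fluid.sum() == 0:
            raise ValueError("geometry has no fluid cells")
        _, n_comp = ndimage.label(fluid)
        if n_comp != 1:
            raise ValueError(f"fluid region has {n_comp} connected components")
        nx, ny = self.shape
        for p in self.ports:
            if p.edge not in _EDGES:
                raise ValueError(f"unknown edge {p.edge!r}")
            idx = [c[1] if p.edge in ("left", "right") else c[0] for c in p.cells]
            if sorted(idx) != list(range(min(idx), min(idx) + len(idx))):
                raise ValueError(f"port {p.role}-{p.index} cells not contiguous")
            for i, j in p.cells:
                on_edge = {
                    "left": i == 0,
                    "right": i == nx - 1,
                    "bottom": j == 0,
                    "top": j == ny - 1,
                }[p.edge]
                if not on_edge or not fluid[i, j]:
                    raise ValueError(
                        f"port {p.role}-{p.index} cell {(i, j)} not a boundary fluid cell"
                    )


def _cells_to_int(x: float, h: float, name: str) -> int:
    n = x / h
    if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
        raise ValueError(f"spacing does not divide {name} ({x} / {h})")
    return int(round(n))


def make_geometry(
    kind: str, length: float, width: float, spacing: float
) -> GeometryMask:
    """Build one of the canned 2D test geometries.

    Parameters
    ----------
    kind : {"straight", "bifurcation", "loop"}
        ``straight``: channel ``length x width``, inlet left, outlet right.
        ``bifurcation``: T-shape; inlet channel feeding a transverse channel
        with outlets at the bottom and top boundaries.
        ``loop``: square ``length x length`` domain holding two vertical limbs
        of width ``width`` (inlets at the bottom, outlets at the top) joined by
        two horizontal collateral connectors — a desk-scale analogue of a
        redundant arterial ring.
    length, width, spacing : float
        Meters.  ``spacing`` must divide both and resolve the channel width
        with at least 8 cells (boundary layers are unresolvable below that).
    """
    w = _cells_to_int(width, spacing, "width")
    if w < 8:
        raise ValueError(
            f"width/spacing = {w} cells across the channel; need >= 8"
        )
    L = _cells_to_int(length, spacing, "length")

    if kind == "straight":
        flag = np.full((L, w), FLUID, dtype=int)
        flag[0, :] = INLET_BASE
        flag[-1, :] = OUTLET_BASE
        ports = [
            Port("inlet", 0, "left", tuple((0, j) for j in range(w))),
            Port("outlet", 0, "right", tuple((L - 1, j) for j in range(w))),
        ]
        geom = GeometryMask(flag, spacing, ports)

    elif kind == "bifurcation":
        if L < 2 * w:
            raise ValueError("bifurcation needs length >= 2*width")
        ny = 3 * w
        flag = np.full((L, ny), WALL, dtype=int)
        flag[: L - w, w : 2 * w] = FLUID  # feeding channel
        flag[L - w :, :] = FLUID  # transverse channel
        flag[0, w : 2 * w] = INLET_BASE
        flag[L - w :, 0] = OUTLET_BASE
        flag[L - w :, ny - 1] = OUTLET_BASE + 1
        ports = [
            Port("inlet", 0, "left", tuple((0, j) for j in range(w, 2 * w))),
            Port("outlet", 0, "bottom", tuple((i, 0) for i in range(L - w, L))),
            Port("outlet", 1, "top", tuple((i, ny - 1) for i in range(L - w, L))),
        ]
        geom = GeometryMask(flag, spacing, ports)

    elif kind == "loop":
        if L < 5 * w:
            raise ValueError("loop needs length >= 5*width")
        flag = np.full((L, L), WALL, dtype=int)
        lx = slice(w, 2 * w)  # left limb columns
        rx = slice(L - 2 * w, L - w)  # right limb columns
        flag[lx, :] = FLUID
        flag[rx, :] = FLUID
        mid = slice(2 * w, L - 2 * w)
        flag[mid, w : 2 * w] = FLUID  # lower connector
        flag[mid, L - 2 * w : L - w] = FLUID  # upper connector
        flag[lx, 0] = INLET_BASE
        flag[rx, 0] = INLET_BASE + 1
        flag[lx, L - 1] = OUTLET_BASE
        flag[rx, L - 1] = OUTLET_BASE + 1
        ports = [
            Port("inlet", 0, "bottom", tuple((i, 0) for i in range(w, 2 * w))),
            Port(
                "inlet", 1, "bottom", tuple((i, 0) for i in range(L - 2 * w, L - w))
            ),
            Port("outlet", 0, "top", tuple((i, L - 1) for i in range(w, 2 * w))),
            Port(
                "outlet", 1, "top", tuple((i, L - 1) for i in range(L - 2 * w, L - w))
            ),
        ]
        geom = GeometryMask(flag, spacing, ports)

    else:
        raise ValueError(f"unknown geometry kind {kind!r}")

    geom.validate()
    return geom
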