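"""Incompressible 2D Navier-Stokes on a masked staggered (MAC) grid.

The forward model for the assimilation experiments: rigid walls, Newtonian
incompressible blood (rho = 1055 kg/m^3, eta = 4 mPa s by default), laminar
transient flow advanced with an explicit advection-diffusion step followed by
a pressure projection that renders every fluid cell divergence-free.

Staggering convention (cell indices ``(i, j)``, spacing ``h``):

* ``u`` lives on x-faces, shape ``(nx+1, ny)``; ``u[i, j]`` sits at
  ``(i*h, (j+0.5)*h)``.
* ``v`` lives on y-faces, shape ``(nx, ny+1)``; ``v[i, j]`` sits at
  ``((i+0.5)*h, j*h)``.
* ``p`` is cell-centered, shape ``(nx, ny)``.

Wall faces carry exactly zero velocity (no-slip, no-penetration); tangential
velocities use ghost reflection across walls so the no-slip plane falls on the
cell interface.  Inlets impose a parabolic profile with a prescribed
instantaneous flow rate; outlets use a flow-split condition: a zero-gradient
copy of the adjacent interior profile corrected (with a parabolic weighting
that preserves no-slip) so each outlet carries exactly its split ratio of the
instantaneous total inflow.  Global mass balance therefore holds to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .geometry import GeometryMask, Port


class CFLError(RuntimeError):
    """Advective CFL limit exceeded for the configured time step."""


class SolverNumericsError(RuntimeError):
    """Non-finite values appeared in the state."""


@dataclass(frozen=True)
class FluidProps:
    """Fluid constants and the model time step (SI units)."""

    density: float = 1055.0  # kg/m^3
    dynamic_viscosity: float = 4.0e-3  # Pa s
    dt: float = 1.0e-3  # s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0 or self.dt <= 0:
            raise ValueError("density, viscosity and dt must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass
class VelocityField:
    """Staggered velocity state plus cell-centered pressure at one time."""

    u: np.ndarray  # (nx+1, ny)
    v: np.ndarray  # (nx, ny+1)
    p: np.ndarray  # (nx, ny)
    time: float = 0.0

    def copy(self) -> "VelocityField":
        return VelocityField(self.u.copy(), self.v.copy(), self.p.copy(), self.time)

    def cell_center_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components interpolated to cell centers, shape (nx, ny)."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc


def _port_face_index(port: Port):
    """(array_name, fixed_index, along_indices, inward_sign) of a port's faces."""
    cells = port.cells
    if port.edge == "left":
        return "u", 0, np.array([c[1] for c in cells]), +1.0
    if port.edge == "right":
        return "u", None, np.array([c[1] for c in cells]), -1.0  # index nx set later
    if port.edge == "bottom":
        return "v", 0, np.array([c[0] for c in cells]), +1.0
    if port.edge == "top":
        return "v", None, np.array([c[0] for c in cells]), -1.0  # index ny set later
    raise ValueError(port.edge)


class FlowSolver:
    """Projection-method integrator bound to one geometry and fluid."""

    def __init__(
        self,
        geom: GeometryMask,
        props: FluidProps | None = None,
        advection_scheme: str = "upwind",
        projection_tol: float = 1e-10,
    ):
        if advection_scheme not in ("upwind", "centered"):
            raise ValueError(f"unknown advection scheme {advection_scheme!r}")
        self.geom = geom
        self.props = props or FluidProps()
        self.advection_scheme = advection_scheme
        self.projection_tol = projection_tol
        self._build_masks()
        self._build_poisson()

    # ------------------------------------------------------------------
    # static structure
    # ------------------------------------------------------------------
    def _build_masks(self) -> None:
        geom = self.geom
        nx, ny = geom.shape
        fluid = geom.is_fluid
        self.nx, self.ny = nx, ny
        Fp = np.zeros((nx + 2, ny + 2), dtype=bool)
        Fp[1:-1, 1:-1] = fluid  # exterior counts as wall

        # free faces: strictly between two fluid cells (never on the domain edge)
        u_free = np.zeros((nx + 1, ny), dtype=bool)
        u_free[1:nx, :] = fluid[:-1, :] & fluid[1:, :]
        v_free = np.zeros((nx, ny + 1), dtype=bool)
        v_free[:, 1:ny] = fluid[:, :-1] & fluid[:, 1:]
        self.u_free, self.v_free = u_free, v_free

        # prescribed (port) faces on the domain boundary
        self.port_faces = []
        u_presc = np.zeros((nx + 1, ny), dtype=bool)
        v_presc = np.zeros((nx, ny + 1), dtype=bool)
        for port in geom.ports:
            comp, fixed, along, sign = _port_face_index(port)
            if fixed is None:
                fixed = nx if comp == "u" else ny
            if comp == "u":
                u_presc[fixed, along] = True
            else:
                v_presc[along, fixed] = True
            self.port_faces.append((port, comp, fixed, along, sign))
        self.u_prescribed, self.v_prescribed = u_presc, v_presc

        # ghost rules for tangential neighbors across walls / open ports:
        # reflect (-u) across a rigid wall, copy (zero-gradient) past a port.
        def flanks_u(i_arr, j):  # cells flanking u-face column j
            return Fp[i_arr, j + 1], Fp[i_arr + 1, j + 1]

        iu = np.arange(nx + 1)
        up_wall = np.zeros((nx + 1, ny), dtype=bool)
        dn_wall = np.zeros((nx + 1, ny), dtype=bool)
        for j in range(ny):
            a, b = flanks_u(iu, j + 1) if j + 1 < ny else (np.zeros(nx + 1, bool),) * 2
            up_wall[:, j] = ~(a | b) if j + 1 < ny else True
            a, b = flanks_u(iu, j - 1) if j - 1 >= 0 else (np.zeros(nx + 1, bool),) * 2
            dn_wall[:, j] = ~(a | b) if j - 1 >= 0 else True
        # open (port) exteriors: zero-gradient instead of reflection
        u_open_top = np.zeros(nx + 1, dtype=bool)
        u_open_bot = np.zeros(nx + 1, dtype=bool)
        v_open_left = np.zeros(ny + 1, dtype=bool)
        v_open_right = np.zeros(ny + 1, dtype=bool)
        for port in geom.ports:
            cols = np.array([c[0] for c in port.cells])
            rows = np.array([c[1] for c in port.cells])
            if port.edge == "top":
                for i in range(nx + 1):
                    if (i - 1 in cols) and (i in cols):
                        u_open_top[i] = True
            elif port.edge == "bottom":
                for i in range(nx + 1):
                    if (i - 1 in cols) and (i in cols):
                        u_open_bot[i] = True
            elif port.edge == "left":
                for j in range(ny + 1):
                    if (j - 1 in rows) and (j in rows):
                        v_open_left[j] = True
            elif port.edge == "right":
                for j in range(ny + 1):
                    if (j - 1 in rows) and (j in rows):
                        v_open_right[j] = True
        self.u_up_reflect = up_wall.copy()
        self.u_up_copy = np.zeros_like(up_wall)
        self.u_up_copy[:, ny - 1] = u_open_top
        self.u_up_reflect[:, ny - 1] &= ~u_open_top
        self.u_dn_reflect = dn_wall.copy()
        self.u_dn_copy = np.zeros_like(dn_wall)
        self.u_dn_copy[:, 0] = u_open_bot
        self.u_dn_reflect[:, 0] &= ~u_open_bot

        def flanks_v(i, j_arr):
            return Fp[i + 1, j_arr], Fp[i + 1, j_arr + 1]

        jv = np.arange(ny + 1)
        rt_wall = np.zeros((nx, ny + 1), dtype=bool)
        lt_wall = np.zeros((nx, ny + 1), dtype=bool)
        for i in range(nx):
            if i + 1 < nx:
                a, b = flanks_v(i + 1, jv)
                rt_wall[i, :] = ~(a | b)
            else:
                rt_wall[i, :] = True
            if i - 1 >= 0:
                a, b = flanks_v(i - 1, jv)
                lt_wall[i, :] = ~(a | b)
            else:
                lt_wall[i, :] = True
        self.v_rt_reflect = rt_wall.copy()
        self.v_rt_copy = np.zeros_like(rt_wall)
        self.v_rt_copy[nx - 1, :] = v_open_right
        self.v_rt_reflect[nx - 1, :] &= ~v_open_right
        self.v_lt_reflect = lt_wall.copy()
        self.v_lt_copy = np.zeros_like(lt_wall)
        self.v_lt_copy[0, :] = v_open_left
        self.v_lt_reflect[0, :] &= ~v_open_left

        self.fluid = fluid

    def _build_poisson(self) -> None:
        nx, ny, h = self.nx, self.ny, self.geom.spacing
        fluid = self.fluid
        idx = -np.ones((nx, ny), dtype=int)
        cells = np.argwhere(fluid)
        idx[fluid] = np.arange(len(cells))
        self.cell_index = idx
        self.cells = cells
        n = len(cells)
        rows, cols, vals = [], [], []
        inv_h2 = 1.0 / h**2

        def add_face(c1, c2):
            a, b = idx[c1], idx[c2]
            rows.extend([a, a, b, b])
            cols.extend([a, b, b, a])
            vals.extend([-inv_h2, inv_h2, -inv_h2, inv_h2])

        for i in range(1, nx):
            for j in range(ny):
                if self.u_free[i, j]:
                    add_face((i - 1, j), (i, j))
        for i in range(nx):
            for j in range(1, ny):
                if self.v_free[i, j]:
                    add_face((i, j - 1), (i, j))
        L = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n, n)
        ).tolil()
        # pin one cell to fix the Neumann null space
        L[0, :] = 0.0
        L[0, 0] = 1.0
        self._lu = splu(L.tocsc())

    # ------------------------------------------------------------------
    # diagnostics helpers
    # ------------------------------------------------------------------
    def initial_state(self, time: float = 0.0) -> VelocityField:
        nx, ny = self.nx, self.ny
        return VelocityField(
            np.zeros((nx + 1, ny)), np.zeros((nx, ny + 1)), np.zeros((nx, ny)), time
        )

    def divergence(self, state: VelocityField) -> np.ndarray:
        """Discrete divergence on fluid cells (zeros elsewhere)."""
        h = self.geom.spacing
        div = (
            state.u[1:, :] - state.u[:-1, :] + state.v[:, 1:] - state.v[:, :-1]
        ) / h
        div[~self.fluid] = 0.0
        return div

    def port_flux(self, state: VelocityField, port_pos: int) -> float:
        """Signed flux through port ``port_pos`` (positive = inward for inlets,
        positive = outward for outlets)."""
        port, comp, fixed, along, sign = self.port_faces[port_pos]
        h = self.geom.spacing
        arr = state.u if comp == "u" else state.v
        vals = arr[fixed, along] if comp == "u" else arr[along, fixed]
        flux = float(np.sum(vals) * h)
        return sign * flux if port.role == "inlet" else -sign * flux

    # ------------------------------------------------------------------
    # boundary conditions
    # ------------------------------------------------------------------
    def _port_shape(self, port: Port) -> np.ndarray:
        """Parabolic (no-slip) weighting across a port, unit peak."""
        w = port.width_cells * self.geom.spacing
        s = (np.arange(port.width_cells) + 0.5) * self.geom.spacing - 0.5 * w
        return 1.0 - (2.0 * s / w) ** 2

    def _set_port_values(self, state, pos, inward_values) -> None:
        port, comp, fixed, along, sign = self.port_faces[pos]
        arr = state.u if comp == "u" else state.v
        if comp == "u":
            arr[fixed, along] = sign * inward_values
        else:
            arr[along, fixed] = sign * inward_values

    def _apply_bc(self, state: VelocityField, bc, t: float) -> None:
        h = self.geom.spacing
        inflows = np.atleast_1d(np.asarray(bc.inflow_rates(t), dtype=float))
        inlet_ports = [pf for pf in self.port_faces if pf[0].role == "inlet"]
        if len(inflows) != len(inlet_ports):
            raise ValueError("inflow_rates length does not match inlet count")
        profile_fn = getattr(bc, "inlet_profile", None)
        total_in = 0.0
        for pos, pf in enumerate(self.port_faces):
            port = pf[0]
            if port.role != "inlet":
                continue
            k = port.index
            if profile_fn is not None:
                w = port.width_cells * h
                s = (np.arange(port.width_cells) + 0.5) * h - 0.5 * w
                vals = np.asarray(profile_fn(k, s, t), dtype=float)
            else:
                shape = self._port_shape(port)
                q = inflows[k]
                denom = float(np.sum(shape) * h)
                vals = shape * (q / denom)
            self._set_port_values(state, pos, vals)
            total_in += float(np.sum(vals) * h)

        ratios = np.atleast_1d(np.asarray(bc.outlet_ratios(t), dtype=float))
        outlet_ports = [pf for pf in self.port_faces if pf[0].role == "outlet"]
        if len(ratios) != len(outlet_ports):
            raise ValueError("outlet_ratios length does not match outlet count")
        if outlet_ports and not np.isclose(ratios.sum(), 1.0, atol=1e-9):
            raise ValueError(f"outlet split ratios sum to {ratios.sum()}, not 1")
        for pos, pf in enumerate(self.port_faces):
            port, comp, fixed, along, sign = pf
            if port.role != "outlet":
                continue
            # zero-gradient copy of the adjacent interior faces
            arr = state.u if comp == "u" else state.v
            interior = fixed - 1 if sign < 0 else fixed + 1
            vals = (
                arr[interior, along].copy()
                if comp == "u"
                else arr[along, interior].copy()
            )
            inward = sign * vals  # inward-positive convention; outflow is negative
            outward = -inward
            target = ratios[port.index] * total_in
            shape = self._port_shape(port)
            c = (target - float(np.sum(outward) * h)) / (float(np.sum(shape)) * h)
            outward = outward + c * shape
            self._set_port_values(state, pos, -outward)

    # ------------------------------------------------------------------
    # time stepping
    # ------------------------------------------------------------------
    def _ghost(self, arr, shifted, reflect, copy):
        out = shifted
        out = np.where(reflect, -arr, out)
        out = np.where(copy, arr, out)
        return out

    def _advect_diffuse(self, state: VelocityField) -> tuple[np.ndarray, np.ndarray]:
        h = self.geom.spacing
        nu = self.props.kinematic_viscosity
        u, v = state.u, state.v
        nx, ny = self.nx, self.ny

        # --- u momentum ---
        uE = np.zeros_like(u)
        uE[:-1, :] = u[1:, :]
        uW = np.zeros_like(u)
        uW[1:, :] = u[:-1, :]
        uN = np.zeros_like(u)
        uN[:, :-1] = u[:, 1:]
        uN = self._ghost(u, uN, self.u_up_reflect, self.u_up_copy)
        uS = np.zeros_like(u)
        uS[:, 1:] = u[:, :-1]
        uS = self._ghost(u, uS, self.u_dn_reflect, self.u_dn_copy)
        v_at_u = np.zeros_like(u)
        v_at_u[1:nx, :] = 0.25 * (
            v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:]
        )
        if self.advection_scheme == "upwind":
            adv_u = np.where(u > 0, u * (u - uW), u * (uE - u)) / h
            adv_u += np.where(v_at_u > 0, v_at_u * (u - uS), v_at_u * (uN - u)) / h
        else:
            adv_u = u * (uE - uW) / (2 * h) + v_at_u * (uN - uS) / (2 * h)
        lap_u = (uE - 2 * u + uW + uN - 2 * u + uS) / h**2

        # --- v momentum ---
        vN = np.zeros_like(v)
        vN[:, :-1] = v[:, 1:]
        vS = np.zeros_like(v)
        vS[:, 1:] = v[:, :-1]
        vE = np.zeros_like(v)
        vE[:-1, :] = v[1:, :]
        vE = self._ghost(v, vE, self.v_rt_reflect, self.v_rt_copy)
        vW = np.zeros_like(v)
        vW[1:, :] = v[:-1, :]
        vW = self._ghost(v, vW, self.v_lt_reflect, self.v_lt_copy)
        u_at_v = np.zeros_like(v)
        u_at_v[:, 1:ny] = 0.25 * (
            u[:-1, :-1] + u[1:, :-1] + u[:-1, 1:] + u[1:, 1:]
        )
        if self.advection_scheme == "upwind":
            adv_v = np.where(v > 0, v * (v - vS), v * (vN - v)) / h
            adv_v += np.where(u_at_v > 0, u_at_v * (v - vW), u_at_v * (vE - v)) / h
        else:
            adv_v = v * (vN - vS) / (2 * h) + u_at_v * (vE - vW) / (2 * h)
        lap_v = (vE - 2 * v + vW + vN - 2 * v + vS) / h**2

        dt = self.props.dt
        ustar = np.where(self.u_free, u + dt * (nu * lap_u - adv_u), u)
        vstar = np.where(self.v_free, v + dt * (nu * lap_v - adv_v), v)
        return ustar, vstar

    def project(self, state: VelocityField) -> VelocityField:
        """One pressure projection: make the state divergence-free without
        touching wall or port faces."""
        h, dt, rho = self.geom.spacing, self.props.dt, self.props.density
        div = self.divergence(state)
        rhs = (rho / dt) * div[self.fluid]
        rhs -= rhs.mean()  # enforce Neumann compatibility exactly
        rhs[0] = 0.0  # pinned cell
        p_vec = self._lu.solve(rhs)
        p = np.zeros((self.nx, self.ny))
        p[self.fluid] = p_vec
        fac = dt / (rho * h)
        u, v = state.u.copy(), state.v.copy()
        gpx = np.zeros_like(u)
        gpx[1:-1, :] = p[1:, :] - p[:-1, :]
        u = np.where(self.u_free, u - fac * gpx, u)
        gpy = np.zeros_like(v)
        gpy[:, 1:-1] = p[:, 1:] - p[:, :-1]
        v = np.where(self.v_free, v - fac * gpy, v)
        return VelocityField(u, v, p, state.time)

    def check_cfl(self, state: VelocityField) -> float:
        vmax = max(
            float(np.max(np.abs(state.u))), float(np.max(np.abs(state.v)))
        )
        cfl = vmax * self.props.dt / self.geom.spacing
        if cfl >= 1.0:
            raise CFLError(
                f"CFL = {cfl:.3f} >= 1 for dt = {self.props.dt} s "
                f"(max |v| = {vmax:.3g} m/s, spacing = {self.geom.spacing} m)"
            )
        return cfl

    def step(self, state: VelocityField, bc) -> VelocityField:
        """Advance one time step dt under boundary conditions ``bc``.

        ``bc`` must provide ``inflow_rates(t)`` (per-inlet flow rate per unit
        depth, m^2/s) and ``outlet_ratios(t)`` (per-outlet split ratios summing
        to 1); an optional ``inlet_profile(port, s, t)`` overrides the
        parabolic inlet shape.
        """
        self.check_cfl(state)
        t_new = state.time + self.props.dt
        ustar, vstar = self._advect_diffuse(state)
        ustar = np.where(self.u_free | self.u_prescribed, ustar, 0.0)
        vstar = np.where(self.v_free | self.v_prescribed, vstar, 0.0)
        tmp = VelocityField(ustar, vstar, state.p, t_new)
        self._apply_bc(tmp, bc, t_new)
        new = self.project(tmp)
        if not (np.all(np.isfinite(new.u)) and np.all(np.isfinite(new.v))):
            raise SolverNumericsError(
                f"non-finite velocity after step to t = {t_new:.6f} s"
            )
        return new

    def run_forward(
        self,
        state0: VelocityField,
        bc,
        t_end: float,
        save_every: float,
    ) -> list[VelocityField]:
        """Integrate from ``state0`` and return snapshots at multiples of
        ``save_every`` (including the initial state)."""
        dt = self.props.dt
        n_steps = int(round(t_end / dt))
        if abs(n_steps * dt - t_end) > 1e-9 * max(t_end, dt):
            raise ValueError("t_end must be a multiple of dt")
        stride = int(round(save_every / dt))
        if stride <= 0 or abs(stride * dt - save_every) > 1e-9 * save_every:
            raise ValueError("save_every must be a positive multiple of dt")
        if n_steps % stride != 0:
            raise ValueError("t_end must be a multiple of save_every")
        out = [state0.copy()]
        state = state0
        for k in range(1, n_steps + 1):
            try:
                state = self.step(state, bc)
            except (CFLError, SolverNumericsError) as err:
                raise type(err)(
                    f"{err} (step {k} of {n_steps}, t = {state.time:.6f} s)"
                ) from err
            if k % stride == 0:
                out.append(state.copy())
        return out


@dataclass(frozen=True)
class SteadyBC:
    """Constant inflow rates and outlet split ratios (test/validation helper)."""

    inflows: tuple[float, ...]
    ratios: tuple[float, ...] = (1.0,)
    inlet_profile: object = None

    def inflow_rates(self, t):
        return np.asarray(self.inflows, dtype=float)

    def outlet_ratios(self, t):
        return np.asarray(self.ratios, dtype=float)
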