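#!/usr/bin/env python
"""Validate the 2D channel solver against closed-form flows.

Steady plane Poiseuille flow at three grid resolutions (expecting monotone,
roughly second-order convergence of the velocity profile) and the oscillatory
Womersley-type channel flow at alpha ~ 2.9 (period-aggregated L2 error).
Writes results/solver_validation.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from hemoda.analytic import poiseuille_profile, womersley_number, womersley_profile
from hemoda.geometry import make_geometry
from hemoda.solver import FlowSolver, FluidProps, SteadyBC

OUT = Path("results")


def poiseuille_case(ncell: int, dt: float, n_steps: int) -> float:
    sp = 0.004 / ncell
    geom = make_geometry("straight", 0.02, 0.004, sp)
    solver = FlowSolver(geom, FluidProps(dt=dt))
    q = 0.05 * 0.004
    state = solver.initial_state()
    bc = SteadyBC(inflows=(q,), ratios=(1.0,))
    for _ in range(n_steps):
        state = solver.step(state, bc)
    y = (np.arange(ncell) + 0.5) * sp - 0.002
    G = 3.0 * 4e-3 * q / (2.0 * 0.002**3)
    ua = poiseuille_profile(0.002, G, 4e-3, y)
    umid = state.u[geom.shape[0] // 2, :]
    return float(np.linalg.norm(umid - ua) / np.linalg.norm(ua))


def womersley_case(ncell: int = 16, freq: float = 1.25) -> float:
    props = FluidProps(dt=1e-3)
    sp = 0.004 / ncell
    geom = make_geometry("straight", 0.02, 0.004, sp)
    solver = FlowSolver(geom, props)
    h, G = 0.002, 100.0

    class BC:
        def inflow_rates(self, t):
            return np.array([0.0])

        def outlet_ratios(self, t):
            return np.array([1.0])

        def inlet_profile(self, port, s, t):
            return womersley_profile(h, G, freq, props, s, t)

    state = solver.initial_state()
    y = (np.arange(ncell) + 0.5) * sp - h
    state.u[:, :] = womersley_profile(h, G, freq, props, y, 0.0)[None, :]
    state.u = np.where(solver.u_free | solver.u_prescribed, state.u, 0.0)
    n_per = int(round(1.0 / freq / props.dt))
    num = den = 0.0
    bc = BC()
    for k in range(2 * n_per):
        state = solver.step(state, bc)
        if k >= n_per:
            ua = womersley_profile(h, G, freq, props, y, state.time)
            num += np.sum((state.u[geom.shape[0] // 2, :] - ua) ** 2)
            den += np.sum(ua**2)
    return float(np.sqrt(num / den))


def main() -> int:
    rows = []
    print("steady plane Poiseuille (0.05 m/s mean, 4 mm channel):")
    for ncell, dt, n in ((8, 1e-3, 1200), (16, 1e-3, 1500), (32, 5e-4, 3000)):
        err = poiseuille_case(ncell, dt, n)
        rows.append(("poiseuille", ncell, err))
        print(f"  {ncell:3d} cells across -> L2 profile error {100 * err:.3f}%")
    props = FluidProps()
    alpha = womersley_number(0.002, 1.25, props.density, props.dynamic_viscosity)
    err = womersley_case()
    rows.append(("womersley", 16, err))
    print(
        f"pulsatile channel (alpha = {alpha:.2f}): period L2 error "
        f"{100 * err:.3f}%"
    )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["case", "cells_across", "l2_error"]).to_csv(
        OUT / "solver_validation.csv", index=False
    )
    print(f"wrote {OUT / 'solver_validation.csv'}")
    errs = [r[2] for r in rows[:3]]
    ok = errs[0] > errs[1] > errs[2] and errs[1] < 0.01 and rows[3][2] < 0.02
    print("validation", "PASSED" if ok else "FAILED")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
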