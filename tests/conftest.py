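import numpy as np
import pytest

from hemoda.geometry import make_geometry
from hemoda.solver import FlowSolver, FluidProps, SteadyBC


@pytest.fixture(scope="session")
def straight8():
    """Straight channel, 8 cells across (40x8)."""
    return make_geometry("straight", 0.02, 0.004, 0.0005)


@pytest.fixture(scope="session")
def steady_channel(straight8):
    """Steady laminar channel flow, iterated close to steady state."""
    solver = FlowSolver(straight8, FluidProps())
    bc = SteadyBC(inflows=(0.05 * 0.004,), ratios=(1.0,))
    state = solver.initial_state()
    for _ in range(1200):
        state = solver.step(state, bc)
    return solver, bc, state


@pytest.fixture(scope="session")
def small_loop():
    """Smallest loop network (40x40, 8-cell channels)."""
    return make_geometry("loop", 0.02, 0.004, 0.0005)


def poiseuille_from_rate(q, halfwidth, viscosity):
    """Pressure gradient giving flow rate q per unit depth."""
    return 3.0 * viscosity * q / (2.0 * halfwidth**3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
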