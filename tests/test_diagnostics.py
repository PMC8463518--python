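import numpy as np
import pytest

from hemoda.analytic import poiseuille_profile
from hemoda.diagnostics import (
    CrossSection,
    ensemble_variance,
    flow_rate,
    truth_errors,
    uncertainty_report,
    wall_shear_stress,
)
from hemoda.geometry import make_geometry
from hemoda.solver import FlowSolver


def _poiseuille_field(geom, solver, G, eta=4e-3):
    """Analytic parabolic channel field sampled onto the staggered grid."""
    f = solver.initial_state()
    ncell = geom.shape[1]
    h = geom.spacing * ncell / 2
    y = (np.arange(ncell) + 0.5) * geom.spacing - h
    f.u[:, :] = poiseuille_profile(h, G, eta, y)[None, :]
    f.u = np.where(solver.u_free | solver.u_prescribed, f.u, 0.0)
    return f


@pytest.fixture(scope="module")
def channel16():
    geom = make_geometry("straight", 0.02, 0.004, 0.00025)
    return geom, FlowSolver(geom)


# --------------------------------------------------------------- flow rate
def test_flow_rate_uniform(straight8):
    solver = FlowSolver(straight8)
    f = solver.initial_state()
    f.u[:, :] = 0.1
    sec = CrossSection("mid", "x", 20, 0, 8)
    assert flow_rate(f, straight8, sec) == pytest.approx(4e-4)


def test_flow_rate_poiseuille_closed_form(channel16):
    geom, solver = channel16
    G, eta, h = 100.0, 4e-3, 2e-3
    f = _poiseuille_field(geom, solver, G, eta)
    u_max = G * h**2 / (2 * eta)
    sec = CrossSection("mid", "x", geom.shape[0] // 2, 0, geom.shape[1])
    q = flow_rate(f, geom, sec)
    # midpoint-rule quadrature of the parabola: O(spacing^2) discrepancy
    assert q == pytest.approx(4.0 / 3.0 * u_max * h, rel=3e-3)


def test_flow_rate_rejects_wall_crossing(small_loop):
    solver = FlowSolver(small_loop)
    f = solver.initial_state()
    sec = CrossSection("bad", "y", 20, 0, 40)  # spans walls and both limbs
    with pytest.raises(ValueError, match="wall"):
        flow_rate(f, small_loop, sec)


# ---------------------------------------------------------------------- WSS
def test_wss_poiseuille_closed_form(channel16):
    """tau_w = G*h: with G = 100 Pa/m, h = 2 mm -> 0.2 Pa; the 3-point
    stencil is exact for the parabola."""
    geom, solver = channel16
    f = _poiseuille_field(geom, solver, 100.0)
    df = wall_shear_stress(f, geom, viscosity=4e-3, stencil=3)
    inner = df[(df.i > 4) & (df.i < geom.shape[0] - 5)]
    assert np.allclose(np.abs(inner["tau"]), 0.2, rtol=1e-10)


def test_wss_two_point_first_order():
    errs = []
    for ncell in (8, 16):
        geom = make_geometry("straight", 0.02, 0.004, 0.004 / ncell)
        solver = FlowSolver(geom)
        f = _poiseuille_field(geom, solver, 100.0)
        df = wall_shear_stress(f, geom, viscosity=4e-3, stencil=2)
        errs.append(abs(np.abs(df["tau"]).mean() - 0.2))
    assert errs[1] < 0.6 * errs[0]  # halves with the grid: first order


def test_wss_zero_field_and_viscosity_linearity(straight8):
    solver = FlowSolver(straight8)
    zero = solver.initial_state()
    assert np.allclose(wall_shear_stress(zero, straight8, 4e-3)["tau"], 0.0)
    f = _poiseuille_field(straight8, solver, 100.0)
    t1 = wall_shear_stress(f, straight8, 4e-3)["tau"]
    t2 = wall_shear_stress(f, straight8, 8e-3)["tau"]
    assert np.allclose(t2, 2 * t1)


# ------------------------------------------------------------- variances
def test_ensemble_variance_examples(rng):
    assert ensemble_variance([0.0, 2.0]) == pytest.approx(2.0)
    assert ensemble_variance([3.0, 3.0, 3.0]) == pytest.approx(0.0)
    x = rng.normal(size=12)
    two_pass = np.sum((x - x.mean()) ** 2) / (len(x) - 1)  # brute-force oracle
    assert ensemble_variance(x) == pytest.approx(two_pass, rel=1e-12)


def test_uncertainty_report_arithmetic():
    times = np.array([0.0, 1.0, 2.0])
    analysis = np.array([[0.0, 2.0], [1.0, 3.0], [0.0, 4.0]])  # vars 2, 2, 8
    openloop = np.array([[0.0, 2.0], [0.0, 4.0], [-2.0, 2.0]])  # vars 2, 8, 8
    rep = uncertainty_report(times, analysis, openloop, obs_variance=20.0)
    t = rep.table
    assert t["reduction_vs_openloop_pct"].iloc[0] == pytest.approx(0.0)
    assert t["reduction_vs_openloop_pct"].iloc[1] == pytest.approx(75.0)
    assert t["reduction_vs_obs_pct"].iloc[0] == pytest.approx(90.0)
    assert t["reduction_vs_obs_pct"].iloc[2] == pytest.approx(60.0)


def test_uncertainty_report_zero_reference_is_nan():
    times = np.array([0.0])
    vals = np.array([[1.0, 1.0]])  # zero variance
    rep = uncertainty_report(times, vals, vals, obs_variance=0.0)
    assert np.isnan(rep.table["reduction_vs_openloop_pct"].iloc[0])
    assert np.isnan(rep.table["reduction_vs_obs_pct"].iloc[0])


def test_reductions_invariant_to_rescaling(rng):
    times = np.arange(3.0)
    a = rng.normal(size=(3, 6))
    o = rng.normal(size=(3, 6))
    r1 = uncertainty_report(times, a, o, 1.3)
    r2 = uncertainty_report(times, 1e3 * a, 1e3 * o, 1e6 * 1.3)
    for col in ("reduction_vs_openloop_pct", "reduction_vs_obs_pct"):
        assert np.allclose(r1.table[col], r2.table[col])


# ------------------------------------------------------------ truth errors
def test_truth_errors(straight8, rng):
    solver = FlowSolver(straight8)
    truth = [_poiseuille_field(straight8, solver, 100.0) for _ in range(2)]
    same = truth_errors([t.copy() for t in truth], truth, straight8)
    assert np.allclose(same["rmse"], 0.0)
    shifted = []
    for t in truth:
        s = t.copy()
        s.u = s.u + 0.05
        shifted.append(s)
    rep = truth_errors(shifted, truth, straight8)
    assert np.allclose(rep["rmse"], 0.05, rtol=1e-12)
    # brute-force cellwise oracle on a random perturbation
    pert = truth[0].copy()
    pert.u = pert.u + rng.normal(scale=0.01, size=pert.u.shape)
    rep = truth_errors([pert], [truth[0]], straight8)
    du = 0.5 * (pert.u[:-1] + pert.u[1:]) - 0.5 * (truth[0].u[:-1] + truth[0].u[1:])
    brute = np.sqrt(np.mean(du[straight8.is_fluid] ** 2))
    assert rep["rmse"].iloc[0] == pytest.approx(brute, rel=1e-12)


def test_truth_errors_grid_mismatch(straight8):
    solver = FlowSolver(straight8)
    other = make_geometry("straight", 0.02, 0.004, 0.00025)
    s2 = FlowSolver(other).initial_state()
    with pytest.raises(ValueError, match="grid"):
        truth_errors([solver.initial_state()], [s2], straight8)
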