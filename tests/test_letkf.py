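import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoda.geometry import make_geometry
from hemoda.letkf import (
    LocalizationSpec,
    decompose,
    letkf_analysis,
    letkf_update,
    local_weights,
    map_to_obs_space,
)
from hemoda.observe import Binner, NoiseModel
from hemoda.solver import FlowSolver, SteadyBC
from hemoda.state import StateIndex

GLOBAL = LocalizationSpec(radius=np.inf)


def exact_kalman(members, H, r_diag, y):
    """Oracle: textbook Kalman update using the ensemble sample statistics."""
    N = members.shape[1]
    xb = members.mean(axis=1)
    X = members - xb[:, None]
    Pb = X @ X.T / (N - 1)
    S = H @ Pb @ H.T + np.diag(r_diag)
    K = Pb @ H.T @ np.linalg.inv(S)
    xa = xb + K @ (y - H @ xb)
    Pa = (np.eye(len(xb)) - K @ H) @ Pb
    return xa, Pa


# --------------------------------------------------------------- decompose
def test_decompose_worked_example():
    ens = decompose(np.array([[0.0, 2.0]]))
    assert ens.mean == pytest.approx([1.0])
    assert np.allclose(ens.perturbations, [[-1.0, 1.0]])


def test_decompose_round_trip(rng):
    members = rng.normal(size=(7, 5))
    ens = decompose(members)
    rebuilt = ens.mean[:, None] + ens.perturbations
    assert np.allclose(rebuilt, members, rtol=0, atol=1e-15)
    assert np.allclose(ens.perturbations.sum(axis=1), 0.0, atol=1e-12)


def test_decompose_needs_two_members():
    with pytest.raises(ValueError):
        decompose(np.ones((3, 1)))


def test_map_to_obs_space(rng):
    members = rng.normal(size=(4, 6))
    ens = decompose(members)
    H = rng.normal(size=(3, 4))
    ob = map_to_obs_space(ens, lambda col: H @ col)
    # linear h: mean of images equals image of mean; Y = H X
    assert np.allclose(ob.mean, H @ ens.mean)
    assert np.allclose(ob.perturbations, H @ ens.perturbations)
    same = map_to_obs_space(ens, lambda col: col)  # identity operator
    assert np.allclose(same.members, ens.members)
    flat = decompose(np.tile(members[:, :1], (1, 5)))
    assert np.allclose(map_to_obs_space(flat, lambda c: H @ c).perturbations, 0.0)


# ----------------------------------------------------------- local weights
def test_scalar_worked_example():
    """Background {0, 2}, obs 3, R = 2: the scalar KF gives mean 2, var 1."""
    la = local_weights(
        Y_local=np.array([[-1.0, 1.0]]),
        r_local=np.array([2.0]),
        innovation=np.array([2.0]),
        n_members=2,
    )
    X = np.array([[-1.0, 1.0]])
    mean_inc = (X @ la.w_mean)[0]
    assert mean_inc == pytest.approx(1.0)  # background mean 1 -> analysis 2
    Xa = X @ la.W
    assert (Xa @ Xa.T)[0, 0] / (2 - 1) == pytest.approx(1.0)  # variance 1


def test_no_observations_is_identity():
    la = local_weights(np.empty((0, 4)), np.empty(0), np.empty(0), 4)
    assert np.allclose(la.W, np.eye(4))
    assert np.allclose(la.w_mean, 0.0)


def test_huge_r_returns_background():
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(3, 6))
    Y -= Y.mean(axis=1, keepdims=True)
    la = local_weights(Y, np.full(3, 1e12), rng.normal(size=3), 6)
    assert np.allclose(la.w_mean, 0.0, atol=1e-9)
    assert np.allclose(la.P_a, np.eye(6) / 5, atol=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_square_root_consistency(seed):
    """W is the symmetric root: W W^T = (N-1) P_a and W maps 1 to 1."""
    rng = np.random.default_rng(seed)
    N, p = 8, 5
    Y = rng.normal(size=(p, N))
    Y -= Y.mean(axis=1, keepdims=True)
    la = local_weights(Y, rng.uniform(0.5, 2, p), rng.normal(size=p), N)
    assert np.linalg.norm(la.W @ la.W.T - (N - 1) * la.P_a) <= 1e-10 * N
    assert np.allclose(la.W, la.W.T, atol=1e-12)
    assert np.allclose(la.W @ np.ones(N), np.ones(N), atol=1e-9)


# -------------------------------------------------------- global analysis
def test_matches_exact_kalman_filter(rng):
    """Linear-Gaussian equivalence: mean and covariance to 1e-8 when the
    perturbations span the state space (N > state dim)."""
    for _ in range(25):
        n = int(rng.integers(1, 6))
        m = int(rng.integers(1, 6))
        N = 50
        members = rng.normal(size=(n, N))
        H = rng.normal(size=(m, n))
        r = rng.uniform(0.5, 2.0, size=m)
        y = rng.normal(size=m)
        out = letkf_analysis(members, H @ members, y, r, GLOBAL)
        xa, Pa = exact_kalman(members, H, r, y)
        Xa = out - out.mean(axis=1, keepdims=True)
        assert np.abs(out.mean(axis=1) - xa).max() < 1e-8
        assert np.abs(Xa @ Xa.T / (N - 1) - Pa).max() < 1e-8


def test_perfect_observations_pull_to_pseudoinverse(rng):
    """R -> 0 with invertible h: the analysis mean approaches H^+ y, with the
    residual shrinking proportionally to R."""
    n, N = 3, 50
    members = rng.normal(size=(n, N))
    H = np.eye(n)
    y = rng.normal(size=n)
    target = np.linalg.pinv(H) @ y
    errs = []
    for r in (1e-4, 1e-6, 1e-8):
        out = letkf_analysis(members, H @ members, y, np.full(n, r), GLOBAL)
        errs.append(np.abs(out.mean(axis=1) - target).max())
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-6


def test_variance_never_increases(rng):
    members = rng.normal(size=(4, 30))
    H = rng.normal(size=(6, 4))
    out = letkf_analysis(
        members, H @ members, rng.normal(size=6), np.full(6, 0.5), GLOBAL
    )
    var_b = np.var(members, axis=1, ddof=1)
    var_a = np.var(out, axis=1, ddof=1)
    assert np.all(var_a <= var_b + 1e-12)


def test_zero_spread_returns_background():
    members = np.ones((3, 5))
    out = letkf_analysis(
        members, members[:1] * 2, np.array([7.0]), np.array([1.0]), GLOBAL
    )
    assert np.array_equal(out, members)


# ----------------------------------------------------------- localization
def _toy_system(rng, n=6, m=4, N=20):
    members = rng.normal(size=(n, N))
    coords = np.column_stack([np.linspace(0, 1, n), np.zeros(n)])
    obs_coords = np.column_stack([np.linspace(0.1, 0.9, m), np.zeros(m)])
    H = rng.normal(size=(m, n))
    y = rng.normal(size=m)
    r = rng.uniform(0.5, 2, m)
    return members, H, y, r, coords, obs_coords


def test_large_radius_equals_global(rng):
    members, H, y, r, coords, obs_coords = _toy_system(rng)
    loc = LocalizationSpec(radius=10.0)  # far beyond the domain diameter
    local = letkf_analysis(
        members, H @ members, y, r, loc, state_coords=coords, obs_coords=obs_coords
    )
    glob = letkf_analysis(members, H @ members, y, r, GLOBAL)
    assert np.allclose(local, glob, atol=1e-12)


def test_radius_zero_is_identity(rng):
    members, H, y, r, coords, obs_coords = _toy_system(rng)
    loc = LocalizationSpec(radius=0.0)
    out = letkf_analysis(
        members, H @ members, y, r, loc, state_coords=coords, obs_coords=obs_coords
    )
    assert np.array_equal(out, members)


def test_obs_cap_truncates_with_warning(rng):
    members, H, y, r, coords, obs_coords = _toy_system(rng)
    loc = LocalizationSpec(radius=10.0, obs_cap=2)
    with pytest.warns(RuntimeWarning, match="obs_cap"):
        out = letkf_analysis(
            members, H @ members, y, r, loc,
            state_coords=coords, obs_coords=obs_coords,
        )
    assert out.shape == members.shape


def test_gaspari_cohn_taper_runs(rng):
    members, H, y, r, coords, obs_coords = _toy_system(rng)
    loc = LocalizationSpec(radius=0.5, taper="gaspari-cohn")
    out = letkf_analysis(
        members, H @ members, y, r, loc, state_coords=coords, obs_coords=obs_coords
    )
    assert np.all(np.isfinite(out))
    # tapering weakens the update relative to plain boxcar at equal radius
    box = letkf_analysis(
        members, H @ members, y, r, LocalizationSpec(radius=0.5),
        state_coords=coords, obs_coords=obs_coords,
    )
    inc_t = np.linalg.norm(out.mean(axis=1) - members.mean(axis=1))
    inc_b = np.linalg.norm(box.mean(axis=1) - members.mean(axis=1))
    assert inc_t <= inc_b + 1e-12


# ------------------------------------------------------- field-level update
@pytest.fixture(scope="module")
def field_setup():
    geom = make_geometry("straight", 0.02, 0.004, 0.0005)
    solver = FlowSolver(geom)
    bc = SteadyBC(inflows=(0.04 * 0.004,), ratios=(1.0,))
    base = solver.initial_state()
    for _ in range(60):
        base = solver.step(base, bc)
    return geom, solver, base


def _member_fields(solver, base, n, scale_rng):
    out = []
    for _ in range(n):
        f = base.copy()
        s = scale_rng.uniform(0.8, 1.2)
        f.u *= s
        f.v *= s
        out.append(f)
    return out


def test_identical_members_unchanged(field_setup):
    geom, solver, base = field_setup
    fields = [base.copy() for _ in range(4)]
    binner = Binner(geom, 0.002)
    obs = binner.observe(base, noise=NoiseModel(seed=1))
    out = letkf_update(fields, obs, geom, LocalizationSpec(radius=np.inf))
    for f in out:  # zero spread: analysis = background
        assert np.allclose(f.u, base.u, atol=1e-12)


def test_update_moves_toward_truth(field_setup):
    geom, solver, base = field_setup
    rng = np.random.default_rng(5)
    fields = _member_fields(solver, base, 10, rng)
    binner = Binner(geom, 0.002)
    obs = binner.observe(base, noise=NoiseModel(snr=1e6, seed=2))  # near-perfect
    out = letkf_update(fields, obs, geom, LocalizationSpec(radius=5e-3))
    err_b = np.mean([np.abs(f.u - base.u).mean() for f in fields])
    err_a = np.mean([np.abs(f.u - base.u).mean() for f in out])
    assert err_a < 0.5 * err_b


def test_projected_update_keeps_walls_zero_and_divergence_free(field_setup):
    geom, solver, base = field_setup
    rng = np.random.default_rng(6)
    fields = _member_fields(solver, base, 8, rng)
    binner = Binner(geom, 0.002)
    obs = binner.observe(base, noise=NoiseModel(seed=3))
    out = letkf_update(
        fields, obs, geom, LocalizationSpec(radius=5e-3), solver=solver
    )
    wall = ~(solver.u_free | solver.u_prescribed)
    for f in out:
        assert np.all(f.u[wall] == 0.0)
        assert np.abs(solver.divergence(f)).max() < 1e-8  # re-projected
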