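"""Local ensemble transform Kalman filter (deterministic square-root form).

The analysis is computed in the N-dimensional ensemble space.  With background
perturbations ``X`` (state x N), observation-space perturbations ``Y``
(obs x N), diagonal observation covariance ``R`` and innovation
``d = y_obs - mean(h(x^b))``:

    P_a = [ (N-1) I / rho + Y^T R^-1 Y ]^-1          (ensemble-space covariance)
    w_mean = P_a Y^T R^-1 d                          (mean-update weights)
    W = sqrt( (N-1) P_a )                            (symmetric square root)
    member_i = x_mean + X (w_mean + W e_i)

``rho >= 1`` is an optional multiplicative covariance inflation (1 = off).
Localization repeats this update independently for every state component,
restricting ``Y``, ``R`` and ``d`` to observations whose positions lie within
a cutoff radius of that component's physical coordinate; components sharing an
identical local observation set share one weight computation.

The symmetric square root is the unique SPD root from the eigendecomposition
of ``P_a``; it maps the all-ones vector to itself (up to the inflation
factor), so analysis perturbations keep a zero column sum and the analysis
mean is the mean of the analysis members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class LocalizationSpec:
    """Observation-localization and filter options.

    radius: cutoff distance in meters (np.inf = global update, 0 = no update).
    taper: "boxcar" (hard cutoff) or "gaspari-cohn" (smooth, radius = support).
    inflation: multiplicative background-covariance inflation, >= 1.
    obs_cap: maximum local observations per grid point (None = unlimited).
    """

    radius: float = 7.0e-3
    taper: str = "boxcar"
    inflation: float = 1.0
    obs_cap: int | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.inflation < 1.0:
            raise ValueError("inflation must be >= 1")
        if self.taper not in ("boxcar", "gaspari-cohn"):
            raise ValueError(f"unknown taper {self.taper!r}")


@dataclass
class StateEnsemble:
    """Member matrix (state dim x N) with cached mean and perturbations."""

    members: np.ndarray
    mean: np.ndarray
    perturbations: np.ndarray  # X, columns sum to zero

    @property
    def n_members(self) -> int:
        return self.members.shape[1]

    def covariance(self) -> np.ndarray:
        X = self.perturbations
        return X @ X.T / (self.n_members - 1)


@dataclass
class LocalAnalysis:
    """Ensemble-space analysis for one local observation set."""

    P_a: np.ndarray  # (N, N)
    W: np.ndarray  # symmetric square root of (N-1) P_a
    w_mean: np.ndarray  # (N,)


def decompose(members: np.ndarray) -> StateEnsemble:
    """Split a (state dim x N) member matrix into mean and perturbations."""
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.shape[1] < 2:
        raise ValueError("need at least 2 ensemble members")
    mean = members.mean(axis=1)
    X = members - mean[:, None]
    return StateEnsemble(members, mean, X)


def map_to_obs_space(ensemble: StateEnsemble, h) -> StateEnsemble:
    """Apply the observation operator to every member and decompose.

    The mean is the mean of the member images (identical to h(mean) for a
    linear h such as spatial binning, and still well-defined otherwise).
    ``h`` maps one member column to an observation vector.
    """
    images = np.column_stack([h(ensemble.members[:, i])
                              for i in range(ensemble.n_members)])
    return decompose(images)


def gaspari_cohn(r: np.ndarray) -> np.ndarray:
    """Gaspari-Cohn 5th-order taper on normalized distance r in [0, 1].

    Compact support at r = 1 (the localization radius); c = 1/2 in the
    standard two-branch piecewise form.
    """
    r = np.abs(np.asarray(r, dtype=float))
    z = 2.0 * r  # distance in units of c = radius/2
    out = np.zeros_like(z)
    near = z <= 1.0
    far = (z > 1.0) & (z < 2.0)
    zn = z[near]
    out[near] = (
        -0.25 * zn**5 + 0.5 * zn**4 + 0.625 * zn**3 - 5.0 / 3.0 * zn**2 + 1.0
    )
    zf = z[far]
    out[far] = (
        zf**5 / 12.0
        - 0.5 * zf**4
        + 0.625 * zf**3
        + 5.0 / 3.0 * zf**2
        - 5.0 * zf
        + 4.0
        - 2.0 / (3.0 * zf)
    )
    return out


def local_weights(
    Y_local: np.ndarray,
    r_local: np.ndarray,
    innovation: np.ndarray,
    n_members: int,
    inflation: float = 1.0,
) -> LocalAnalysis:
    """Ensemble-space weights from the local observations of one grid point.

    Y_local : (p, N) observation-space perturbations restricted to the local set.
    r_local : (p,) diagonal observation error variances (possibly taper-scaled).
    innovation : (p,) local y_obs - mean(h(x^b)).
    """
    N = n_members
    p = Y_local.shape[0] if Y_local.ndim == 2 else 0
    if p == 0:
        s = float(np.sqrt(inflation))
        return LocalAnalysis(
            P_a=np.eye(N) * inflation / (N - 1),
            W=np.eye(N) * s,
            w_mean=np.zeros(N),
        )
    if not np.all(np.isfinite(innovation)):
        bad = int(np.flatnonzero(~np.isfinite(innovation))[0])
        raise ValueError(f"non-finite innovation at local observation {bad}")
    if np.any(r_local <= 0):
        raise ValueError("observation error variances must be positive")
    S = Y_local / r_local[:, None]  # R^-1 Y
    A = (N - 1) / inflation * np.eye(N) + Y_local.T @ S
    evals, evecs = eigh(A)
    inv = evecs / evals[None, :]
    P_a = inv @ evecs.T
    W = np.sqrt(N - 1) * (evecs / np.sqrt(evals)[None, :]) @ evecs.T
    w_mean = P_a @ (S.T @ innovation)
    return LocalAnalysis(P_a=P_a, W=W, w_mean=w_mean)


def letkf_analysis(
    members: np.ndarray,
    obs_images: np.ndarray,
    y_obs: np.ndarray,
    r_diag: np.ndarray,
    loc: LocalizationSpec,
    state_coords: np.ndarray | None = None,
    obs_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Core LETKF update on flat arrays; returns the analysis member matrix.

    members : (n, N) background states.  obs_images : (m, N) member images
    under the observation operator.  y_obs, r_diag : (m,) observations and
    diagonal error variances.  Coordinates are required unless
    ``loc.radius`` is infinite (global update).
    """
    bg = decompose(members)
    ob = decompose(obs_images)
    N = bg.n_members
    innovation = np.asarray(y_obs, dtype=float) - ob.mean
    r_diag = np.asarray(r_diag, dtype=float)

    if np.isinf(loc.radius):
        la = local_weights(ob.perturbations, r_diag, innovation, N, loc.inflation)
        Wa = la.w_mean[:, None] + la.W
        return bg.mean[:, None] + bg.perturbations @ Wa

    if loc.radius == 0.0 or len(y_obs) == 0:
        return members.copy()

    state_coords = np.asarray(state_coords, dtype=float)
    obs_coords = np.asarray(obs_coords, dtype=float)
    tree = cKDTree(obs_coords)
    neighborhoods = tree.query_ball_point(state_coords, loc.radius)

    analysis = members.copy()
    groups: dict[tuple[int, ...], list[int]] = {}
    if loc.taper == "boxcar":
        # boxcar weights depend only on the observation set: grid points with
        # identical neighborhoods share one ensemble-space solve
        for g, idx in enumerate(neighborhoods):
            groups.setdefault(tuple(sorted(idx)), []).append(g)
    else:
        # tapered R depends on each point's own distances: no sharing
        for g, idx in enumerate(neighborhoods):
            groups[(-g - 1, *sorted(idx))] = [g]

    capped = False
    for key, rows in groups.items():
        idx = np.array([k for k in key if k >= 0], dtype=int)
        if len(idx) == 0:
            continue  # no data: analysis = background
        if loc.obs_cap is not None and len(idx) > loc.obs_cap:
            capped = True
            # keep the observations nearest to the group's centroid
            centroid = state_coords[rows].mean(axis=0)
            dist = np.linalg.norm(obs_coords[idx] - centroid, axis=1)
            idx = idx[np.argsort(dist)[: loc.obs_cap]]
        r_loc = r_diag[idx]
        if loc.taper == "gaspari-cohn":
            centroid = state_coords[rows].mean(axis=0)
            dist = np.linalg.norm(obs_coords[idx] - centroid, axis=1)
            taper = gaspari_cohn(dist / loc.radius)
            keep = taper > 1e-12
            idx, taper = idx[keep], taper[keep]
            if len(idx) == 0:
                continue
            r_loc = r_diag[idx] / taper
        la = local_weights(
            ob.perturbations[idx, :], r_loc, innovation[idx], N, loc.inflation
        )
        Wa = la.w_mean[:, None] + la.W
        rows = np.array(rows)
        analysis[rows, :] = bg.mean[rows, None] + bg.perturbations[rows, :] @ Wa
    if capped:
        warnings.warn(
            f"local observation count exceeded obs_cap = {loc.obs_cap}; "
            "neighborhoods truncated to the nearest observations",
            RuntimeWarning,
            stacklevel=2,
        )
    return analysis


def letkf_update(
    fields: list,
    obs,
    geom,
    loc: LocalizationSpec,
    solver=None,
    h=None,
    codec=None,
):
    """Field-level LETKF update for one observation time.

    fields : background member VelocityFields.
    obs : ObservationSet (provides the observation vector, variances and
        voxel-center coordinates).
    h : callable mapping a VelocityField to the observation vector; defaults
        to the spatial binning operator matching ``obs``.
    solver : if given, each analysis member is re-projected to the
        divergence-free space (walls and port faces are untouched).

    Wall faces remain exactly zero by construction: only free interior faces
    are part of the assimilated state.
    """
    from .observe import binning_observer
    from .state import StateIndex

    codec = codec or StateIndex(geom, solver)
    h = h or binning_observer(geom, obs)
    members = np.column_stack([codec.pack(f) for f in fields])
    images = np.column_stack([h(f) for f in fields])
    y, r_diag, obs_coords = obs.vector(), obs.error_variances(), obs.vector_coords()
    analysis = letkf_analysis(
        members, images, y, r_diag, loc,
        state_coords=codec.coords, obs_coords=obs_coords,
    )
    if np.array_equal(analysis, members):
        return [f.copy() for f in fields]  # empty neighborhoods everywhere
    out = []
    for i, f in enumerate(fields):
        g = codec.unpack(analysis[:, i], template=f)
        if solver is not None:
            g = solver.project(g)
        out.append(g)
    return out
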