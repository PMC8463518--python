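"""Uncertain pulsatile boundary conditions as a sampled ensemble.

Inflow rates and outlet outflows are known only as per-frame (knot) means and
standard deviations, mirroring sample statistics extracted from PC-MRI flow
measurements.  Each ensemble member draws an independent Gaussian value at
every knot (truncated to positive flows by resampling), and a natural cubic
spline through the member's own draws yields a continuous trajectory.
Outflow draws are converted to flow-split ratios by dividing by the per-knot
total, so the solver's flow-split outlet condition guarantees mass balance.

Draws are independent across knots by default (smoothness comes purely from
the interpolation); an optional AR(1) knot correlation is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_interp_spline

_MAX_RESAMPLE = 1000


def flow_split_ratios(outflow_draws: np.ndarray) -> np.ndarray:
    """Normalize positive per-outlet outflow values to split ratios."""
    draws = np.asarray(outflow_draws, dtype=float)
    if np.any(draws <= 0):
        raise ValueError("outflow draws must be positive (truncate-resample first)")
    return draws / draws.sum()


def cubic_trajectory(knot_times, knot_values):
    """Continuous trajectory through the knots.

    Natural cubic spline for >= 4 knots (C^2 inside the span); for 3 knots a
    quadratic, for 2 a linear interpolant.  Evaluation outside the knot span
    clamps to the nearest knot value.
    """
    t = np.asarray(knot_times, dtype=float)
    x = np.asarray(knot_values, dtype=float)
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate knot times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot times must be strictly increasing")
    if len(t) < 2:
        raise ValueError("need at least 2 knots")
    if len(t) >= 4:
        spl = CubicSpline(t, x, bc_type="natural")
    else:
        spl = make_interp_spline(t, x, k=len(t) - 1)
    t0, t1 = t[0], t[-1]

    def f(tau):
        tau = np.clip(np.asarray(tau, dtype=float), t0, t1)
        return spl(tau)

    return f


@dataclass
class BCKnots:
    """Per-frame mean/sd of inflow rates and outlet outflows.

    Shapes: ``times`` (K,); inlet arrays (K, n_inlets); outlet arrays
    (K, n_outlets).  Units are flow rate per unit depth (m^2/s) for the 2D
    model (m^3/s in a 3D setting).
    """

    times: np.ndarray
    inflow_mean: np.ndarray
    inflow_sd: np.ndarray
    outflow_mean: np.ndarray
    outflow_sd: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("inflow_mean", "inflow_sd", "outflow_mean", "outflow_sd"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.shape[0] != len(self.times):
                arr = arr.T
            if arr.shape[0] != len(self.times):
                raise ValueError(f"{name} knot count mismatch")
            setattr(self, name, arr)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(self.inflow_sd < 0) or np.any(self.outflow_sd < 0):
            raise ValueError("standard deviations must be >= 0")

    @property
    def n_inlets(self) -> int:
        return self.inflow_mean.shape[1]

    @property
    def n_outlets(self) -> int:
        return self.outflow_mean.shape[1]

    # -- CSV round trip (columns: time_s, vessel_id, role, mean, sd) ----
    def to_csv(self, path) -> None:
        rows = []
        for k, t in enumerate(self.times):
            for i in range(self.n_inlets):
                rows.append((t, f"inlet-{i}", "inlet",
                             self.inflow_mean[k, i], self.inflow_sd[k, i]))
            for j in range(self.n_outlets):
                rows.append((t, f"outlet-{j}", "outlet",
                             self.outflow_mean[k, j], self.outflow_sd[k, j]))
        pd.DataFrame(
            rows, columns=["time_s", "vessel_id", "role", "mean", "sd"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BCKnots":
        df = pd.read_csv(path)
        times = np.sort(df["time_s"].unique())
        inlets = sorted(df.loc[df.role == "inlet", "vessel_id"].unique())
        outlets = sorted(df.loc[df.role == "outlet", "vessel_id"].unique())

        def grab(ids, col):
            out = np.empty((len(times), len(ids)))
            for c, vid in enumerate(ids):
                sub = df[df.vessel_id == vid].sort_values("time_s")
                out[:, c] = sub[col].to_numpy()
            return out

        return cls(
            times,
            grab(inlets, "mean"), grab(inlets, "sd"),
            grab(outlets, "mean"), grab(outlets, "sd"),
        )


@dataclass
class BCMember:
    """One continuous boundary-condition trajectory (solver-facing)."""

    inflow_fns: list  # per inlet, callable t -> m^2/s
    ratio_fns: list  # per outlet, callable t -> raw (unnormalized) ratio

    def inflow_rates(self, t) -> np.ndarray:
        return np.array([f(t) for f in self.inflow_fns], dtype=float)

    def outlet_ratios(self, t) -> np.ndarray:
        # splined ratios sum to 1 exactly by linearity of the interpolant;
        # clip + renormalize guards against cubic overshoot below zero
        raw = np.array([f(t) for f in self.ratio_fns], dtype=float)
        raw = np.maximum(raw, 1e-12)
        return raw / raw.sum()


@dataclass
class BCEnsemble:
    """N member trajectories sampled from the knot Gaussians."""

    members: list  # of BCMember
    knots: BCKnots
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)

    def __getitem__(self, i) -> BCMember:
        return self.members[i]

    def to_frame(self, times) -> pd.DataFrame:
        """Sampled inflow trajectories evaluated on ``times`` (for export)."""
        rows = []
        for m, mem in enumerate(self.members):
            for t in np.asarray(times, dtype=float):
                q = mem.inflow_rates(t)
                for i, qi in enumerate(q):
                    rows.append((m, t, f"inlet-{i}", qi))
        return pd.DataFrame(rows, columns=["member", "time_s", "vessel_id", "rate"])


def _truncated_normal(rng, mean, sd) -> float:
    """One positive Gaussian draw (resample-on-negative truncation)."""
    if sd == 0:
        return float(mean)
    for _ in range(_MAX_RESAMPLE):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError(
        f"could not draw a positive flow from N({mean}, {sd}^2) "
        f"in {_MAX_RESAMPLE} tries"
    )


def _knot_draws(rng, mean_col, sd_col, correlation: float) -> np.ndarray:
    """Per-knot truncated-Gaussian draws, optionally AR(1)-correlated."""
    K = len(mean_col)
    if correlation == 0.0:
        return np.array(
            [_truncated_normal(rng, mean_col[k], sd_col[k]) for k in range(K)]
        )
    # correlated standard normals, then shift/scale and truncate by clipping
    z = np.empty(K)
    z[0] = rng.standard_normal()
    for k in range(1, K):
        z[k] = correlation * z[k - 1] + np.sqrt(
            1 - correlation**2
        ) * rng.standard_normal()
    draws = mean_col + sd_col * z
    tiny = 1e-12 * np.maximum(mean_col, 1.0)
    return np.maximum(draws, tiny)


def sample_bc_ensemble(
    knots: BCKnots,
    n_members: int,
    seed: int,
    knot_correlation: float = 0.0,
) -> BCEnsemble:
    """Draw N continuous boundary trajectories from the knot statistics."""
    if n_members < 2:
        raise ValueError("need at least 2 ensemble members")
    rng = np.random.default_rng(seed)
    t = knots.times
    members = []
    for _ in range(n_members):
        inflow_fns = [
            cubic_trajectory(
                t, _knot_draws(rng, knots.inflow_mean[:, i], knots.inflow_sd[:, i],
                               knot_correlation)
            )
            for i in range(knots.n_inlets)
        ]
        out_draws = np.column_stack(
            [
                _knot_draws(rng, knots.outflow_mean[:, j], knots.outflow_sd[:, j],
                            knot_correlation)
                for j in range(knots.n_outlets)
            ]
        )
        ratios = np.apply_along_axis(flow_split_ratios, 1, out_draws)
        ratio_fns = [
            cubic_trajectory(t, ratios[:, j]) for j in range(knots.n_outlets)
        ]
        members.append(BCMember(inflow_fns, ratio_fns))
    return BCEnsemble(members, knots, seed)


def mean_bc(knots: BCKnots) -> BCMember:
    """The deterministic mean trajectory (used as the twin-experiment truth)."""
    t = knots.times
    inflow_fns = [
        cubic_trajectory(t, knots.inflow_mean[:, i]) for i in range(knots.n_inlets)
    ]
    ratios = np.apply_along_axis(flow_split_ratios, 1, knots.outflow_mean)
    ratio_fns = [cubic_trajectory(t, ratios[:, j]) for j in range(knots.n_outlets)]
    return BCMember(inflow_fns, ratio_fns)
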