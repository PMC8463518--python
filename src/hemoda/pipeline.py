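"""End-to-end twin experiments: truth, observations, open loop, assimilation.

The default configuration is the desk-scale analogue of a subject-specific
study: a looped two-inlet/two-outlet network (collateral pathways like an
arterial ring) on a 64x64 grid at 0.5 mm spacing, 25 ensemble members, 17
assimilation windows of 54 model steps (1 ms each), coarse 2 mm observation
voxels, PC-MRI noise with VENC = 0.9 m/s and SNR = 55, and a 7 mm
localization radius.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundary import BCEnsemble, BCKnots, mean_bc, sample_bc_ensemble
from .diagnostics import (
    CrossSection,
    ensemble_variance,
    flow_rate,
    truth_errors,
    uncertainty_report,
    wall_shear_stress,
)
from .geometry import GeometryMask, make_geometry
from .letkf import LocalizationSpec, letkf_update
from .observe import Binner, NoiseModel, binning_observer
from .solver import FlowSolver, FluidProps
from .state import StateIndex
from .twin import TwinDataset, make_twin_dataset


@dataclass
class RunConfig:
    """All knobs of a twin experiment (SI units, unit-suffixed keys)."""

    geometry_kind: str = "loop"
    length_m: float = 0.032
    width_m: float = 0.004
    spacing_m: float = 0.0005

    density_kg_m3: float = 1055.0
    viscosity_pa_s: float = 4.0e-3
    dt_s: float = 1.0e-3
    advection_scheme: str = "upwind"
    projection_tol: float = 1.0e-10

    venc_m_s: float = 0.9
    snr: float = 55.0
    wrap_enabled: bool = False

    radius_m: float = 7.0e-3
    taper: str = "boxcar"
    inflation: float = 1.0
    obs_cap: int | None = None

    n_members: int = 25
    n_windows: int = 17
    window_steps: int = 54
    voxel_ratio: int = 4
    fluid_fraction_threshold: float = 0.5

    # default pulsatile waveform (means) and knot uncertainty; amplitudes
    # sized so the worst member (draws + junction overshoot) stays well
    # inside the explicit solver's CFL envelope at dt = 1 ms, h = 0.5 mm
    base_velocity_m_s: float = 0.05
    pulse_velocity_m_s: float = 0.085
    pulse_center_s: float = 0.20
    pulse_width_s: float = 0.10
    inlet_scales: tuple = (1.2, 0.8)
    bc_sd_fraction: float = 0.10

    truth_bc_mode: str = "draw"  # "draw": truth BC is a seeded draw from the
    # knot Gaussians (statistically consistent twin); "mean": knot means
    seed: int = 0
    knots_csv: str | None = None
    outdir: str = "results/run"

    # -- derived objects ------------------------------------------------
    @property
    def window_s(self) -> float:
        return self.window_steps * self.dt_s

    def seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        bc, noise, filt, truth = (
            int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
        )
        return {"bc": bc, "noise": noise, "filter": filt, "truth": truth}

    def truth_bc(self, knots: BCKnots):
        if self.truth_bc_mode == "mean":
            return mean_bc(knots)
        if self.truth_bc_mode == "draw":
            return sample_bc_ensemble(knots, 2, self.seeds()["truth"]).members[0]
        raise ValueError(f"unknown truth_bc_mode {self.truth_bc_mode!r}")

    def geometry(self) -> GeometryMask:
        return make_geometry(
            self.geometry_kind, self.length_m, self.width_m, self.spacing_m
        )

    def props(self) -> FluidProps:
        return FluidProps(self.density_kg_m3, self.viscosity_pa_s, self.dt_s)

    def noise(self) -> NoiseModel:
        return NoiseModel(
            self.venc_m_s, self.snr, self.wrap_enabled, self.seeds()["noise"]
        )

    def localization(self) -> LocalizationSpec:
        return LocalizationSpec(self.radius_m, self.taper, self.inflation,
                                self.obs_cap)

    def knots(self, geom: GeometryMask | None = None) -> BCKnots:
        if self.knots_csv is not None:
            return BCKnots.from_csv(self.knots_csv)
        geom = geom or self.geometry()
        return default_knots(self, geom)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["inlet_scales"] = list(self.inlet_scales)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        if "inlet_scales" in d:
            d["inlet_scales"] = tuple(d["inlet_scales"])
        return cls(**d)


def default_knots(cfg: RunConfig, geom: GeometryMask) -> BCKnots:
    """Pulsatile knot statistics: a Gaussian systolic pulse over a diastolic
    baseline, one knot per observation frame (plus t = 0), knot sd a fixed
    fraction of the mean."""
    times = np.arange(cfg.n_windows + 1) * cfg.window_s
    v_mean = cfg.base_velocity_m_s + cfg.pulse_velocity_m_s * np.exp(
        -(((times - cfg.pulse_center_s) / cfg.pulse_width_s) ** 2)
    )
    scales = np.asarray(cfg.inlet_scales[: geom.n_inlets], dtype=float)
    if len(scales) != geom.n_inlets:
        scales = np.ones(geom.n_inlets)
    q = v_mean[:, None] * scales[None, :] * cfg.width_m  # (K, n_inlets)
    total = q.sum(axis=1)
    out_mean = np.tile((total / geom.n_outlets)[:, None], (1, geom.n_outlets))
    return BCKnots(
        times,
        inflow_mean=q,
        inflow_sd=cfg.bc_sd_fraction * q,
        outflow_mean=out_mean,
        outflow_sd=cfg.bc_sd_fraction * out_mean,
    )


# ----------------------------------------------------------------------
# monitored cross-sections and wall segments (loop geometry)
# ----------------------------------------------------------------------
def monitored_sections(geom: GeometryMask, cfg: RunConfig) -> list[CrossSection]:
    """Cross-sections tracked in the reports, derived from the geometry."""
    w = int(round(cfg.width_m / cfg.spacing_m))
    nx, ny = geom.shape
    if cfg.geometry_kind == "loop":
        # sections sit strictly between the junctions: there the flux is set
        # by the interior pressure balance, not pinned by the port conditions
        L = nx
        return [
            CrossSection("M-left", "y", L // 2, w, 2 * w),
            CrossSection("M-right", "y", L // 2, L - 2 * w, L - w),
            CrossSection("C-lower", "x", L // 2, w, 2 * w),
            CrossSection("C-upper", "x", L // 2, L - 2 * w, L - w),
        ]
    if cfg.geometry_kind == "straight":
        return [CrossSection("mid", "x", nx // 2, 0, ny)]
    if cfg.geometry_kind == "bifurcation":
        return [
            CrossSection("inflow", "x", nx // 4, w, 2 * w),
            CrossSection("O-bottom", "y", w, nx - w, nx),
            CrossSection("O-top", "y", ny - w, nx - w, nx),
        ]
    raise ValueError(cfg.geometry_kind)


def wall_segment_labels(geom: GeometryMask, cfg: RunConfig) -> dict:
    """Label wall-adjacent faces by branch; returns {label: [(i, j, ni, nj)]}"""
    w = int(round(cfg.width_m / cfg.spacing_m))
    nx, _ = geom.shape
    adjacency = geom.wall_adjacency()
    if cfg.geometry_kind != "loop":
        return {"all": [(i, j, di, dj) for (i, j), (di, dj) in adjacency]}
    segments: dict[str, list] = {
        "left-limb": [],
        "right-limb": [],
        "lower-connector": [],
        "upper-connector": [],
    }
    for (i, j), (di, dj) in adjacency:
        if w <= i < 2 * w:
            segments["left-limb"].append((i, j, di, dj))
        elif nx - 2 * w <= i < nx - w:
            segments["right-limb"].append((i, j, di, dj))
        elif j < nx // 2:
            segments["lower-connector"].append((i, j, di, dj))
        else:
            segments["upper-connector"].append((i, j, di, dj))
    return segments


# ----------------------------------------------------------------------
# experiment stages
# ----------------------------------------------------------------------
@dataclass
class EnsembleRun:
    """Member states at every window time plus per-cycle diagnostics."""

    window_times: np.ndarray
    states: list  # [window][member] -> VelocityField
    diagnostics: pd.DataFrame
    background: list | None = None  # assimilation only: pre-update states
    failures: list = field(default_factory=list)

    def member_values(self, fn) -> np.ndarray:
        """(T, N) array of a scalar diagnostic per window and member."""
        return np.array([[fn(s) for s in window] for window in self.states])

    def mean_fields(self) -> list:
        out = []
        for window in self.states:
            m = window[0].copy()
            m.u = np.mean([s.u for s in window], axis=0)
            m.v = np.mean([s.v for s in window], axis=0)
            m.p = np.mean([s.p for s in window], axis=0)
            out.append(m)
        return out


def _advance(solver: FlowSolver, state, bc, n_steps: int):
    for _ in range(n_steps):
        state = solver.step(state, bc)
    return state


def _spread(codec: StateIndex, states) -> float:
    m = np.column_stack([codec.pack(s) for s in states])
    return float(np.sqrt(np.mean(np.var(m, axis=1, ddof=1))))


def run_open_loop(
    cfg: RunConfig,
    bc_ensemble: BCEnsemble,
    solver: FlowSolver | None = None,
) -> EnsembleRun:
    """Propagate all members with their sampled BCs and no assimilation."""
    geom = solver.geom if solver is not None else cfg.geometry()
    solver = solver or FlowSolver(geom, cfg.props(), cfg.advection_scheme, cfg.projection_tol)
    codec = StateIndex(geom, solver)
    t_end = cfg.n_windows * cfg.window_s
    trajectories, failures = [], []
    for m in range(cfg.n_members):
        try:
            snaps = solver.run_forward(
                solver.initial_state(), bc_ensemble[m], t_end, cfg.window_s
            )
            trajectories.append(snaps[1:])
        except Exception as err:  # noqa: BLE001 - report, keep going
            failures.append((m, str(err)))
            trajectories.append(None)
    ok = [tr for tr in trajectories if tr is not None]
    if not ok:
        raise RuntimeError(f"all members failed: {failures}")
    states = [[tr[k] for tr in ok] for k in range(cfg.n_windows)]
    times = np.arange(1, cfg.n_windows + 1) * cfg.window_s
    diag = pd.DataFrame(
        {
            "cycle": np.arange(1, cfg.n_windows + 1),
            "time": times,
            "spread": [_spread(codec, w) for w in states],
        }
    )
    return EnsembleRun(times, states, diag, failures=failures)


def run_assimilation(
    cfg: RunConfig,
    twin: TwinDataset,
    bc_ensemble: BCEnsemble,
    solver: FlowSolver | None = None,
    spread_floor: float = 1e-10,
) -> EnsembleRun:
    """Cycle loop: forecast all members one window, LETKF update at the
    observation time, continue from the analysis ensemble."""
    geom = solver.geom if solver is not None else cfg.geometry()
    solver = solver or FlowSolver(geom, cfg.props(), cfg.advection_scheme, cfg.projection_tol)
    codec = StateIndex(geom, solver)
    loc = cfg.localization()
    h = binning_observer(geom, twin.observations[0])
    states = [solver.initial_state() for _ in range(cfg.n_members)]
    background, analysis, rows = [], [], []
    for k in range(cfg.n_windows):
        t0 = _time.perf_counter()
        states = [
            _advance(solver, s, bc_ensemble[m], cfg.window_steps)
            for m, s in enumerate(states)
        ]
        obs = twin.observations[k]
        background.append([s.copy() for s in states])
        images = np.column_stack([h(s) for s in states])
        innovation = obs.vector() - images.mean(axis=1)
        # raw analysis (the reported state estimate) ...
        raw = letkf_update(states, obs, geom, loc, solver=None, codec=codec)
        analysis.append([s.copy() for s in raw])
        # ... and a divergence-consistent copy to initialize the next forecast
        # (skipped when the update was a no-op, e.g. radius 0)
        if any(
            not (np.array_equal(r.u, s.u) and np.array_equal(r.v, s.v))
            for r, s in zip(raw, states)
        ):
            states = [solver.project(r) for r in raw]
        bg_spread = _spread(codec, background[-1])
        an_spread = _spread(codec, raw)
        if an_spread < spread_floor:
            import warnings

            warnings.warn(
                f"analysis spread collapsed to {an_spread:.3e} at cycle {k + 1}",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append(
            {
                "cycle": k + 1,
                "time": obs.time,
                "innovation_norm": float(np.linalg.norm(innovation)),
                "background_spread": bg_spread,
                "analysis_spread": an_spread,
                "wall_clock_s": _time.perf_counter() - t0,
            }
        )
    times = np.arange(1, cfg.n_windows + 1) * cfg.window_s
    return EnsembleRun(times, analysis, pd.DataFrame(rows), background=background)


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def observation_flow_variance(
    section: CrossSection, binner: Binner, sigma2: float, spacing: float
) -> tuple[int, float]:
    """Variance of the section flow rate estimated from voxel observations.

    The rate estimate sums the normal-component voxel values times the voxel
    size across the section; with independent per-voxel errors of variance
    sigma^2 the rate variance is n_voxels * sigma^2 * voxel_size^2.
    """
    vox = binner.voxel_size
    centers = binner.centers
    line = section.index * spacing
    lo, hi = section.start * spacing, section.stop * spacing
    axis = 1 if section.normal == "y" else 0
    tr = 1 - axis
    # single voxel row nearest the section line (round down at ties)
    rows = np.unique(np.round((centers[:, axis] - vox / 2) / vox).astype(int))
    best = rows[np.argmin(np.abs((rows + 0.5) * vox - line))]
    on = (
        (np.abs(centers[:, axis] - (best + 0.5) * vox) < vox / 4)
        & (centers[:, tr] > lo - vox / 2)
        & (centers[:, tr] < hi + vox / 2)
    )
    n = int(on.sum())
    return n, n * sigma2 * vox**2


def peak_systole_time(twin: TwinDataset) -> float:
    """Observation time of maximum total truth inflow."""
    bc = twin.truth_bc if twin.truth_bc is not None else mean_bc(twin.knots)
    times = twin.window_times
    totals = [bc.inflow_rates(t).sum() for t in times]
    return float(times[int(np.argmax(totals))])


def report(
    cfg: RunConfig,
    twin: TwinDataset,
    open_loop: EnsembleRun,
    analysis: EnsembleRun,
    solver: FlowSolver | None = None,
) -> dict:
    """Fig.-3-style summary: flow-rate and WSS uncertainty, RMSE vs truth."""
    geom = solver.geom if solver is not None else cfg.geometry()
    solver = solver or FlowSolver(geom, cfg.props(), cfg.advection_scheme, cfg.projection_tol)
    binner = Binner(
        geom, cfg.voxel_ratio * cfg.spacing_m, cfg.fluid_fraction_threshold
    )
    sigma2 = twin.noise.sigma_v**2
    t_peak = peak_systole_time(twin)
    times = analysis.window_times

    sections = monitored_sections(geom, cfg)
    section_tables = {}
    flow_summary = []
    for sec in sections:
        an_vals = analysis.member_values(lambda s: flow_rate(s, geom, sec))
        ol_vals = open_loop.member_values(lambda s: flow_rate(s, geom, sec))
        n_vox, var_obs = observation_flow_variance(
            sec, binner, sigma2, cfg.spacing_m
        )
        rep = uncertainty_report(times, an_vals, ol_vals, var_obs)
        truth_rates = [flow_rate(f, geom, sec) for f in twin.truth[1:]]
        rep.table["truth_rate"] = truth_rates
        rep.table["analysis_mean"] = an_vals.mean(axis=1)
        rep.table["openloop_mean"] = ol_vals.mean(axis=1)
        section_tables[sec.label] = rep.table
        peak = rep.peak_row(t_peak)
        flow_summary.append(
            {
                "section": sec.label,
                "n_obs_voxels": n_vox,
                "peak_var_analysis": peak["var_analysis"],
                "peak_var_openloop": peak["var_openloop"],
                "peak_var_obs": peak["var_obs"],
                "peak_reduction_vs_openloop_pct": peak["reduction_vs_openloop_pct"],
                "peak_reduction_vs_obs_pct": peak["reduction_vs_obs_pct"],
            }
        )

    # WSS per wall segment at peak systole: one stress table per member,
    # then segment averages of |tau|
    k_peak = int(np.argmin(np.abs(times - t_peak)))
    segments = wall_segment_labels(geom, cfg)
    face_segment = {
        (i, j, di, dj): label
        for label, faces in segments.items()
        for (i, j, di, dj) in faces
    }

    def segment_means(state) -> dict:
        df = wall_shear_stress(state, geom, cfg.viscosity_pa_s)
        df["segment"] = [
            face_segment[(r.i, r.j, r.normal_i, r.normal_j)]
            for r in df.itertuples()
        ]
        return df.groupby("segment")["tau"].apply(
            lambda s: float(np.nanmean(np.abs(s)))
        ).to_dict()

    an_means = [segment_means(s) for s in analysis.states[k_peak]]
    ol_means = [segment_means(s) for s in open_loop.states[k_peak]]
    wss_summary = []
    for label in segments:
        an = [m[label] for m in an_means]
        ol = [m[label] for m in ol_means]
        va, vo = float(ensemble_variance(an)), float(ensemble_variance(ol))
        wss_summary.append(
            {
                "segment": label,
                "mean_wss_analysis": float(np.mean(an)),
                "mean_wss_openloop": float(np.mean(ol)),
                "var_analysis": va,
                "var_openloop": vo,
                "variance_ratio_openloop_over_analysis": vo / va if va > 0 else np.nan,
            }
        )

    rmse_an = truth_errors(analysis.mean_fields(), twin.truth[1:], geom)
    rmse_ol = truth_errors(open_loop.mean_fields(), twin.truth[1:], geom)
    rmse = pd.DataFrame(
        {
            "time": rmse_an["time"],
            "rmse_analysis": rmse_an["rmse"],
            "rmse_openloop": rmse_ol["rmse"],
        }
    )

    summary = {
        "peak_systole_time_s": t_peak,
        "mean_rmse_analysis": float(rmse["rmse_analysis"].mean()),
        "mean_rmse_openloop": float(rmse["rmse_openloop"].mean()),
        "rmse_reduction_pct": float(
            100.0 * (1.0 - rmse["rmse_analysis"].mean() / rmse["rmse_openloop"].mean())
        ),
        "flow": flow_summary,
        "wss": wss_summary,
    }
    return {
        "summary": summary,
        "rmse": rmse,
        "sections": section_tables,
    }


def write_report(result: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as f:
        json.dump(result["summary"], f, indent=2, default=float)
    result["rmse"].to_csv(outdir / "rmse.csv", index=False)
    for label, table in result["sections"].items():
        table.to_csv(outdir / f"flow_{label}.csv", index=False)


def run_twin_experiment(cfg: RunConfig, outdir=None) -> dict:
    """Generate twin data, run open loop and assimilation, and report.

    Returns {"twin", "open_loop", "analysis", "report", ...}; writes tables
    under ``outdir`` when given.
    """
    geom = cfg.geometry()
    props = cfg.props()
    solver = FlowSolver(geom, props, cfg.advection_scheme, cfg.projection_tol)
    seeds = cfg.seeds()
    knots = cfg.knots(geom)
    twin = make_twin_dataset(
        geom,
        props,
        knots,
        cfg.noise(),
        n_windows=cfg.n_windows,
        window_steps=cfg.window_steps,
        voxel_size=cfg.voxel_ratio * cfg.spacing_m,
        fluid_fraction_threshold=cfg.fluid_fraction_threshold,
        solver=solver,
        truth_bc=cfg.truth_bc(knots),
    )
    bc_ens = sample_bc_ensemble(knots, cfg.n_members, seeds["bc"])
    open_loop = run_open_loop(cfg, bc_ens, solver=solver)
    analysis = run_assimilation(cfg, twin, bc_ens, solver=solver)
    rep = report(cfg, twin, open_loop, analysis, solver=solver)
    if outdir is not None:
        from .twin import save_truth_vtk

        outdir = Path(outdir)
        twin.save(outdir / "twin")
        save_truth_vtk(twin, geom, outdir / "twin")
        open_loop.diagnostics.to_csv(outdir / "openloop_cycles.csv", index=False)
        analysis.diagnostics.to_csv(outdir / "analysis_cycles.csv", index=False)
        write_report(rep, outdir)
        cfg.to_yaml(outdir / "config.yaml")
        manifest = dict(twin.manifest)
        manifest.update({"seeds": seeds, "n_members": cfg.n_members})
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
    return {
        "geom": geom,
        "solver": solver,
        "twin": twin,
        "bc_ensemble": bc_ens,
        "open_loop": open_loop,
        "analysis": analysis,
        "report": rep,
    }
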