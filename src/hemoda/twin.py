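"""Twin-experiment data generation.

A single "truth" trajectory is integrated with the knot-mean boundary
conditions, then binned to the coarse voxel grid and corrupted with the
phase-contrast noise model at every observation window — the synthetic
stand-in for a gated multi-frame PC-MRI acquisition (default: 17 frames, one
per assimilation window of 54 model steps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boundary import BCKnots, mean_bc
from .geometry import GeometryMask
from .observe import Binner, NoiseModel, ObservationSet
from .solver import FlowSolver, FluidProps, VelocityField
from .vtkio import observations_to_frame, write_vtk_field


@dataclass
class TwinDataset:
    """Ground truth + synthetic observations + generation metadata."""

    truth: list  # VelocityField at window times (incl. t = 0)
    observations: list  # ObservationSet, one per window (t > 0)
    noise: NoiseModel
    knots: BCKnots
    manifest: dict
    truth_bc: object = None  # BCMember that generated the truth

    @property
    def n_windows(self) -> int:
        return len(self.observations)

    @property
    def window_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as f:
            json.dump(self.manifest, f, indent=2)
        frames = [observations_to_frame(o) for o in self.observations]
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "observations.csv", index=False
        )
        self.knots.to_csv(outdir / "bc_knots.csv")


def make_twin_dataset(
    geom: GeometryMask,
    props: FluidProps,
    knots: BCKnots,
    noise: NoiseModel,
    n_windows: int = 17,
    window_steps: int = 54,
    voxel_size: float | None = None,
    fluid_fraction_threshold: float = 0.5,
    solver: FlowSolver | None = None,
    initial_state: VelocityField | None = None,
    truth_bc=None,
) -> TwinDataset:
    """Integrate one fixed truth trajectory from rest and observe every window.

    ``truth_bc`` is the truth's boundary trajectory (a ``BCMember``); by
    default the knot-mean trajectory.  In a statistically consistent twin the
    truth is a draw from the same knot Gaussians the ensemble samples (so the
    ensemble spread represents the actual background error); the pipeline
    passes such a draw in by default.
    """
    solver = solver or FlowSolver(geom, props)
    voxel_size = voxel_size if voxel_size is not None else 4 * geom.spacing
    binner = Binner(geom, voxel_size, fluid_fraction_threshold)
    window = window_steps * props.dt
    t_end = n_windows * window
    bc = truth_bc if truth_bc is not None else mean_bc(knots)
    state0 = initial_state if initial_state is not None else solver.initial_state()
    truth = solver.run_forward(state0, bc, t_end, save_every=window)
    rng = np.random.default_rng(noise.seed)
    observations = [
        binner.observe(fld, noise=noise, rng=rng) for fld in truth[1:]
    ]
    manifest = {
        "geometry_shape": list(geom.shape),
        "spacing_m": geom.spacing,
        "density_kg_m3": props.density,
        "viscosity_pa_s": props.dynamic_viscosity,
        "dt_s": props.dt,
        "n_windows": n_windows,
        "window_steps": window_steps,
        "window_s": window,
        "voxel_size_m": voxel_size,
        "fluid_fraction_threshold": fluid_fraction_threshold,
        "venc_m_s": noise.venc,
        "snr": noise.snr,
        "sigma_v_m_s": noise.sigma_v,
        "wrap_enabled": noise.wrap_enabled,
        "noise_seed": noise.seed,
        "n_observed_voxels": binner.n_voxels,
        "truth_bc": "knot-mean trajectory" if truth_bc is None else "supplied draw",
    }
    return TwinDataset(truth, observations, noise, knots, manifest, truth_bc=bc)


def save_truth_vtk(dataset: TwinDataset, geom: GeometryMask, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, fld in enumerate(dataset.truth):
        write_vtk_field(outdir / f"truth_{k:03d}.vtk", fld, geom)
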