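# hemoda — ensemble data assimilation for hemodynamic state estimation

Blood-flow estimates in complex vascular networks come from two imperfect
sources: phase-contrast MRI (PC-MRI) velocity maps, which are direct but
noisy and coarse, and computational fluid dynamics (CFD), which is finely
resolved and conservative but hostage to uncertain inflow/outflow boundary
conditions.  `hemoda` fuses the two with a **local ensemble transform Kalman
filter (LETKF)**: an ensemble of CFD simulations with perturbed boundary
conditions supplies the background state and its covariance, and coarse-voxel
velocity observations correct it every measurement frame.  The package is a
complete, desk-scale *twin-experiment* laboratory for this procedure —
2D vascular geometries, a known synthetic truth, PC-MRI-like observations —
so every estimate can be scored against an exact reference.

It is aimed at researchers in biomedical data assimilation and
uncertainty quantification who want a fully testable, reproducible
implementation of the assimilation machinery rather than a clinical tool.

## The method

State: the velocity field *x* of an incompressible 2D Navier–Stokes model
(rigid walls, ρ = 1055 kg/m³, η = 4 mPa·s, Δt = 1 ms; staggered-grid
projection method).  Observations per frame:

    y_obs = h(x) + ε,       ε ~ N(0, R),   R = σ_v² I,
    σ_v = √2/π · VENC / SNR          (PC-MRI velocity noise; 0.9 m/s, 55)

where *h* is a spatial binning operator (per-voxel mean of cell-centered
velocities).  With background ensemble mean x̄ᵇ, perturbations Xᵇ and their
observation-space images Yᵇ (N members), the square-root analysis is

    P̃ᵃ  = [(N−1) I + Yᵇᵀ R⁻¹ Yᵇ]⁻¹
    x̄ᵃ  = x̄ᵇ + Xᵇ P̃ᵃ Yᵇᵀ R⁻¹ (y_obs − ȳᵇ)
    Xᵃ  = Xᵇ Wᵃ,     Wᵃ Wᵃᵀ = (N−1) P̃ᵃ    (symmetric square root)
    xᵃ⁽ⁱ⁾ = x̄ᵃ + Xᵃ⁽ⁱ⁾

computed *locally*: each grid point uses only observations within a cutoff
radius (default 7 mm), which suppresses spurious long-range sample
correlations and makes the update embarrassingly parallel.  Boundary-condition
uncertainty is sampled from per-frame Gaussians (knot mean ± sd) with natural
cubic interpolation in time; outflows become flow-split ratios.

## Worked example

```bash
python analysis/02_twin_experiment.py
```

runs the default study — a looped two-inlet/two-outlet network (a minimal
collateral-pathway analogue, 64×64 cells at 0.5 mm), 25 members, 17
assimilation cycles of 54 ms, 2 mm observation voxels — and prints:

```
RMSE vs truth (mean over 17 analysis times):
  open loop : 5.5588e-03 m/s
  analysis  : 2.2867e-03 m/s   (58.9% lower)

peak-systole flow-rate variance reductions:
  M-left   vs open loop   93.8%   vs observations   84.5%
  M-right  vs open loop   93.8%   vs observations   84.4%
  C-lower  vs open loop   89.8%   vs observations   85.5%
  C-upper  vs open loop   93.8%   vs observations   84.6%

wall-shear-stress uncertainty (open-loop var / analysis var):
  left-limb        x5.2   (mean |WSS| 0.90 Pa analysis, 0.91 Pa open loop)
  ...
```

Read it as: the assimilated state estimate is ~2.4× closer to the truth than
the model-only "open loop" ensemble mean, and its flow-rate uncertainty at
peak systole is far below both the model spread and what the noisy
observations alone would give — the whole point of fusing the two.
`hemoda all --seed 1 --outdir results/run` does the same from the command
line; `generate`, `openloop`, `assimilate` and `report` run the stages
separately.

Other entry points: `analysis/01_validate_solver.py` (closed-form solver
validation), `analysis/03_localization_sweep.py` (radius sensitivity).

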