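# Methods

## Overview

`hemoda` estimates time-resolved vascular velocity fields by sequentially
fusing an ensemble of CFD forecasts with coarse, noisy velocity observations
through a local ensemble transform Kalman filter (LETKF).  Everything runs at
desk scale in 2D so that the full chain — forward model, uncertainty
sampling, observation synthesis, assimilation, diagnostics — is exactly
testable against closed forms and a known synthetic truth.

## Forward model

Incompressible Navier–Stokes on a masked Cartesian staggered (MAC) grid:

* blood treated as Newtonian, ρ = 1055 kg/m³, η = 4 mPa·s; rigid walls;
  laminar, transient; Δt = 1 ms by default;
* explicit advection (first-order upwind by default, centered optional) and
  diffusion, followed by a pressure projection (sparse Cholesky-like LU of the
  masked 5-point Laplacian, factorized once per geometry).  After every step
  the discrete divergence of each fluid cell is at rounding level and global
  mass balance holds to < 10⁻⁶ relative;
* no-slip via ghost reflection across wall faces, so the zero-velocity plane
  falls exactly on the cell interface; normal wall-face velocities are
  identically zero;
* inlets impose a parabolic profile carrying a prescribed instantaneous flow
  rate (rescaled so the *discrete* flux is exact); outlets use a flow-split
  condition — a zero-gradient copy of the adjacent interior profile plus a
  parabolic-weighted correction forcing the outlet to carry exactly its split
  ratio of the instantaneous total inflow (the correction shape preserves
  no-slip and handles near-zero-flux instants gracefully);
* the advective CFL number is checked every step and the step aborts with a
  diagnostic if it reaches 1.

Validation (tests and `analysis/01_validate_solver.py`): steady plane
Poiseuille profile error is ~1.4% / 0.36% / 0.09% L2 at 8 / 16 / 32 cells
across the channel (second-order), and the oscillatory channel flow at
Womersley number α ≈ 2.9 matches the closed-form solution to ~0.8%
period-aggregated L2.  Dimensionality is a deliberate reduction: a 3D
patient-specific model changes the cost, not the structure, of the
assimilation problem, and 2D admits exact oracles.

Geometries are channel masks: `straight`, `bifurcation` (T-shape, 1 inlet /
2 outlets), and `loop` — two vertical limbs joined by two transverse
connectors (2 inlets, 2 outlets), a minimal analogue of a collateral arterial
ring where redundant pathways make internal flow splits genuinely uncertain.
Channel widths must resolve ≥ 8 cells; below that the boundary layer is
meaningless.

## Boundary-condition uncertainty

Inflow rates and outlet outflows are known only as per-frame (knot) means and
standard deviations, as if extracted from repeated PC-MRI flow measurements.
Each ensemble member draws an independent Gaussian at every knot (resampled
until positive — a truncation that matters only when sd is comparable to the
mean), and a natural cubic spline through its own draws produces the
continuous trajectory; evaluation outside the knot span clamps.  Outflow
draws are normalized per knot to flow-split ratios; because splining is
linear, the splined ratios still sum to one at every time (a clip-renormalize
guard handles hypothetical cubic overshoot below zero).  Draws are
independent across knots — temporal smoothness comes entirely from the
interpolation; an AR(1) knot correlation is available as an option.

## Synthetic observations (twin experiments)

A single truth trajectory is integrated and observed every window
(default: 17 frames, 54 model steps ≈ 54 ms apart, emulating a gated
acquisition; 54.4 ms does not divide 1 ms, so the window rounds to 54 steps
and the actual value is recorded in the manifest).  The observation operator
is plain spatial binning: each isotropic voxel (default 2 mm = 4 cells)
reports the mean of cell-centered velocities over the fluid cells it covers;
voxels with fluid fraction < θ = 0.5 are dropped, emulating vessels below
image resolution.  Noise is additive i.i.d. Gaussian per component with
σ_v = √2/π·VENC/SNR (0.9 m/s and 55 give σ_v ≈ 7.37 mm/s); R is diagonal
with that single variance.  A phase-wrap forward model
(v ↦ ((v+VENC) mod 2·VENC) − VENC) exists but is off by default, since
clinical pipelines unwrap before use.

The truth's boundary trajectory is, by default, a fixed seeded draw from the
same knot Gaussians the ensemble samples.  This is the statistically
consistent twin: the truth is exchangeable with the members, so the ensemble
spread is an honest estimate of the background error, which is exactly the
assumption the Kalman update rests on.  (With the truth pinned to the knot
means — available as `truth_bc_mode: mean` — the background mean is unbiased
by construction, the spread overstates the mean's error by roughly √N, and
assimilating noisier observations can only degrade the mean; that
configuration answers a different, and less relevant, question.)

What the generator does *not* emulate: k-space acquisition physics, gating
jitter, eddy currents, intra-voxel dephasing, segmentation error, or any
point-spread function — the binning operator is a top-hat.  Passing twin
tests therefore demonstrates the assimilation machinery, not robustness to
real MRI artifacts.

## The LETKF

Deterministic square-root filter in ensemble space (N = 25 members by
default).  For perturbations X (state) and Y (observation space), diagonal R
and innovation d:

    P̃ᵃ = [(N−1)I/ρ + Yᵀ R⁻¹ Y]⁻¹          ρ = multiplicative inflation (1 = off)
    w̄  = P̃ᵃ Yᵀ R⁻¹ d
    W  = √((N−1) P̃ᵃ)                       symmetric SPD root via eigh
    member i ← x̄ + X (w̄ + W eᵢ)

The symmetric root maps the ones vector to itself, so analysis perturbations
keep zero column sum and the analysis mean is the member mean.  The mean
update uses the mean of the member images rather than h(x̄) — identical for
the linear binning operator and well-defined for nonlinear h.  Localization:
each state component (a staggered velocity face, with its physical
coordinate) uses only observations whose voxel centers lie within the cutoff
radius (default 7 mm; Euclidean distance, ignoring vessel topology — a
straight-line ball may bridge adjacent vessels).  Hard cutoff (boxcar) by
default; a Gaspari–Cohn taper (R inflated by the inverse taper) is optional.
Components with identical local observation sets share one ensemble-space
solve, which cuts the per-cycle cost several-fold.  An observation cap per
grid point truncates to the nearest voxels with a warning.  With zero local
observations (or zero background spread) the analysis equals the background;
with radius 0 the update is exactly the identity.

Two states of the analysis are kept deliberately distinct:

* the **raw analysis** (the square-root equations verbatim) is what all
  diagnostics and reports measure — it is the filter's state estimate; and
* a **projected copy** (one pressure projection, port faces untouched)
  initializes the next forecast, so propagation always starts
  divergence-consistent.

The distinction matters: the projection preserves each member's own port
fluxes, so wherever a cross-section's flux is pinned by the boundary
conditions (e.g. between the last junction and an outlet) it reverts the
filter's flux correction.  Measuring the projected states would test the
boundary conditions, not the assimilation; the monitored cross-sections are
likewise placed between junctions, where flux is set by the interior pressure
balance.  The state vector contains velocities only (no pressure, no
augmented boundary parameters).

## Default study conditions

Loop network 32×32 mm at 0.5 mm spacing (64×64 cells), channel width 4 mm;
25 members; 17 windows × 54 steps; voxels 2 mm, θ = 0.5; VENC 0.9 m/s,
SNR 55; radius 7 mm, boxcar, no inflation.  The pulsatile waveform is a
Gaussian systolic pulse over a diastolic baseline (peak ≈ 0.2 s), knot sd =
10% of the mean, and asymmetric inlets (60/40) so the collateral connectors
carry flow.  Amplitudes (0.05 + 0.085 m/s mean velocity) are sized so the
worst member — peak draw, parabolic peak factor 1.5, junction overshoot —
stays near CFL ≈ 0.7 under the explicit scheme at Δt = 1 ms; this bounds
velocities to the slower end of the cerebral range (Re ≈ 140), the price of
keeping the printed model time step on a desk-scale grid.  These problem
sizes keep a full twin experiment (truth + 25 open-loop + 25 assimilated
members, ~47k solver steps) at a few minutes on one core.

## Numerical choices and edge cases

* Pressure Poisson: Neumann problem; the RHS is mean-subtracted (exact
  compatibility) and one cell pinned to fix the gauge.
* Ensemble-space inverse and square root by symmetric eigendecomposition;
  no explicit Kalman gain is ever formed.
* Observation values/variances are stored per voxel and component; the
  observation vector stacks u-components then v-components, each voxel
  contributing its center coordinate twice.
* Degenerate inputs: zero ensemble spread, zero local observations, radius 0,
  R → ∞ all reduce to "analysis = background" without division by zero;
  non-finite innovations raise with the offending voxel index.
* Reproducibility: one master seed fans out (via `SeedSequence`) into
  boundary-draw, noise, filter and truth seeds; single-threaded runs are
  bit-reproducible, and the per-cycle diagnostics log records spreads,
  innovation norms and wall-clock times.

## Known limitations

2D only; rigid walls and Newtonian rheology; first-order temporal accuracy;
top-hat observation operator without a point-spread function; localization
distance ignores vessel topology; background and observation errors are
assumed independent and Gaussian; no multiplicative-inflation tuning was
attempted (default off).  The wall-shear-stress stencils (2-point default,
3-point optional) are first- and second-order one-sided approximations; the
3-point form is exact for parabolic profiles but noisier near thin branches.
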