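"""PC-MRI-like velocity observations: spatial binning, noise and phase wrap.

The observation operator is a spatial binning: each coarse isotropic voxel
reports the arithmetic mean of the model's cell-centered velocities over the
fluid cells it covers, per component.  Voxels whose fluid fraction falls below
a threshold produce no observation, emulating vessels below the imaging
resolution.

Velocity noise follows the phase-contrast model: additive i.i.d. Gaussian per
component with standard deviation

    sigma_v = sqrt(2)/pi * VENC / SNR,

where VENC is the velocity-encoding limit and SNR the magnitude-image
signal-to-noise ratio (defaults 0.9 m/s and 55).  Velocities beyond +-VENC
alias back into [-VENC, VENC); the wrap is available as an optional forward
model and is off by default (clinical pipelines unwrap before use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryMask
from .solver import VelocityField


def sigma_v(venc: float, snr: float) -> float:
    """Velocity noise standard deviation sqrt(2)/pi * VENC / SNR (m/s)."""
    if venc <= 0 or snr <= 0:
        raise ValueError("VENC and SNR must be positive")
    return np.sqrt(2.0) / np.pi * venc / snr


def phase_wrap(values: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into [-VENC, VENC): v -> ((v + VENC) mod 2 VENC) - VENC."""
    return np.mod(np.asarray(values, dtype=float) + venc, 2.0 * venc) - venc


@dataclass(frozen=True)
class NoiseModel:
    """Phase-contrast velocity noise parameters."""

    venc: float = 0.9  # m/s
    snr: float = 55.0
    wrap_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.venc <= 0 or self.snr <= 0:
            raise ValueError("VENC and SNR must be positive")

    @property
    def sigma_v(self) -> float:
        return sigma_v(self.venc, self.snr)


def corrupt(values: np.ndarray, noise: NoiseModel, rng=None) -> np.ndarray:
    """Add Gaussian velocity noise (and optionally the phase-wrap alias).

    Deterministic given ``noise.seed`` when no generator is supplied; a caller
    producing a sequence of frames passes one generator through all of them.
    """
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    out = np.asarray(values, dtype=float) + noise.sigma_v * rng.standard_normal(
        np.shape(values)
    )
    if noise.wrap_enabled:
        out = phase_wrap(out, noise.venc)
    return out


@dataclass
class ObservationSet:
    """Coarse-voxel velocity observations at one time."""

    time: float
    voxel_centers: np.ndarray  # (M, 2) meters
    voxel_size: float  # m
    values: np.ndarray  # (M, 2): u, v per voxel
    variance: float  # per-component observation error variance (m^2/s^2)
    fluid_fraction_threshold: float = 0.5

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_centers)

    def vector(self) -> np.ndarray:
        """Flat observation vector [u voxels..., v voxels...]."""
        return np.concatenate([self.values[:, 0], self.values[:, 1]])

    def error_variances(self) -> np.ndarray:
        return np.full(2 * self.n_voxels, self.variance)

    def vector_coords(self) -> np.ndarray:
        return np.vstack([self.voxel_centers, self.voxel_centers])


class Binner:
    """Spatial binning operator for one geometry and voxel size."""

    def __init__(
        self,
        geom: GeometryMask,
        voxel_size: float,
        fluid_fraction_threshold: float = 0.5,
    ):
        h = geom.spacing
        ratio = voxel_size / h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"voxel_size {voxel_size} is not an integer multiple of the "
                f"model spacing {h}"
            )
        self.ratio = int(round(ratio))
        self.geom = geom
        self.voxel_size = voxel_size
        self.threshold = fluid_fraction_threshold
        nx, ny = geom.shape
        r = self.ratio
        nvx = -(-nx // r)
        nvy = -(-ny // r)
        fluid = geom.is_fluid
        centers, slices = [], []
        for a in range(nvx):
            for b in range(nvy):
                sl = (slice(a * r, min((a + 1) * r, nx)),
                      slice(b * r, min((b + 1) * r, ny)))
                frac = fluid[sl].sum() / float(r * r)
                if frac >= self.threshold and fluid[sl].sum() > 0:
                    centers.append(((a + 0.5) * voxel_size, (b + 0.5) * voxel_size))
                    slices.append(sl)
        self.centers = np.array(centers).reshape(-1, 2)
        self.slices = slices
        self._fluid = fluid

    @property
    def n_voxels(self) -> int:
        return len(self.slices)

    def apply(self, fld: VelocityField) -> np.ndarray:
        """Per-voxel (M, 2) mean of cell-centered velocities over fluid cells."""
        uc, vc = fld.cell_center_velocity()
        out = np.empty((self.n_voxels, 2))
        for k, sl in enumerate(self.slices):
            m = self._fluid[sl]
            out[k, 0] = uc[sl][m].mean()
            out[k, 1] = vc[sl][m].mean()
        return out

    def vector_apply(self, fld: VelocityField) -> np.ndarray:
        vals = self.apply(fld)
        return np.concatenate([vals[:, 0], vals[:, 1]])

    def observe(
        self, fld: VelocityField, noise: NoiseModel | None = None, rng=None
    ) -> ObservationSet:
        """Bin a field into an ObservationSet; corrupt it if a noise model is
        given (noise-free with variance 0 otherwise)."""
        vals = self.apply(fld)
        var = 0.0
        if noise is not None:
            vals = corrupt(vals, noise, rng=rng)
            var = noise.sigma_v**2
        return ObservationSet(
            time=fld.time,
            voxel_centers=self.centers.copy(),
            voxel_size=self.voxel_size,
            values=vals,
            variance=var,
            fluid_fraction_threshold=self.threshold,
        )


def bin_velocity(
    field: VelocityField,
    geom: GeometryMask,
    voxel_size: float,
    fluid_fraction_threshold: float = 0.5,
) -> ObservationSet:
    """Noise-free binned observations of ``field`` (convenience wrapper)."""
    return Binner(geom, voxel_size, fluid_fraction_threshold).observe(field)


def binning_observer(geom: GeometryMask, obs: ObservationSet):
    """Callable h(field) -> flat observation vector consistent with ``obs``."""
    binner = Binner(geom, obs.voxel_size, obs.fluid_fraction_threshold)
    if binner.n_voxels != obs.n_voxels:
        raise ValueError(
            "observation mask mismatch: geometry yields "
            f"{binner.n_voxels} voxels, observations have {obs.n_voxels}"
        )
    return binner.vector_apply
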