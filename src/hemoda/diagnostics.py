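"""Quantities of interest: flow rates, wall shear stress, uncertainty metrics.

Flow rates are face-normal velocity sums over labelled cross-sections
(m^2/s: volumetric rate per unit depth in 2D).  Wall shear stress is the
viscosity times the one-sided wall-normal gradient of the stream-wise
(wall-tangential) velocity at each wall face.  Uncertainty reductions follow
the convention 100 * (1 - var_analysis / var_reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeometryMask
from .solver import VelocityField


@dataclass(frozen=True)
class CrossSection:
    """A transverse line of faces: ``normal`` axis ("x" or "y"), face index
    along that axis, and the half-open transverse cell range [start, stop)."""

    label: str
    normal: str  # "x": u-faces at i=index; "y": v-faces at j=index
    index: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.normal not in ("x", "y"):
            raise ValueError("normal must be 'x' or 'y'")
        if self.stop <= self.start:
            raise ValueError("empty cross-section")


def _section_valid(section: CrossSection, geom: GeometryMask) -> None:
    fluid = geom.is_fluid
    sl = np.arange(section.start, section.stop)
    if section.normal == "x":
        i = section.index
        ok = np.all(fluid[max(i - 1, 0), sl]) and np.all(
            fluid[min(i, geom.shape[0] - 1), sl]
        )
    else:
        j = section.index
        ok = np.all(fluid[sl, max(j - 1, 0)]) and np.all(
            fluid[sl, min(j, geom.shape[1] - 1)]
        )
    if not ok:
        raise ValueError(f"cross-section {section.label!r} crosses wall cells")


def flow_rate(field: VelocityField, geom: GeometryMask,
              section: CrossSection) -> float:
    """Signed flow rate per unit depth through the section (m^2/s)."""
    _section_valid(section, geom)
    h = geom.spacing
    sl = np.arange(section.start, section.stop)
    if section.normal == "x":
        vals = field.u[section.index, sl]
    else:
        vals = field.v[sl, section.index]
    return float(np.sum(vals) * h)


def wall_shear_stress(
    field: VelocityField,
    geom: GeometryMask,
    viscosity: float,
    stencil: int = 2,
) -> pd.DataFrame:
    """Signed wall shear stress per wall face (Pa).

    For each (fluid cell, wall normal) adjacency the stream-wise velocity is
    the cell-centered component tangential to the wall; its one-sided gradient
    toward the wall (no-slip value 0 on the wall plane, half a cell from the
    first center) gives tau_w = eta * du_t/dn.

    stencil=2: linear through the wall and the first center (first order).
    stencil=3: parabolic through the wall and the first two centers,
    tau = eta * (9 u1 - u2) / (3 h); exact for parabolic profiles.
    Faces with fewer than 2 fluid cells along the normal are skipped for the
    3-point stencil (recorded with NaN).
    """
    if stencil not in (2, 3):
        raise ValueError("stencil must be 2 or 3")
    h = geom.spacing
    uc, vc = field.cell_center_velocity()
    fluid = geom.is_fluid
    nx, ny = geom.shape
    rows = []
    for (i, j), (di, dj) in geom.wall_adjacency():
        tang = uc if dj != 0 else vc  # stream-wise = tangential to the wall
        u1 = tang[i, j]
        if stencil == 2:
            tau = viscosity * u1 / (0.5 * h)
        else:
            i2, j2 = i - di, j - dj  # second cell, away from the wall
            if 0 <= i2 < nx and 0 <= j2 < ny and fluid[i2, j2]:
                u2 = tang[i2, j2]
                tau = viscosity * (9.0 * u1 - u2) / (3.0 * h)
            else:
                tau = np.nan
        rows.append((i, j, di, dj, tau))
    return pd.DataFrame(rows, columns=["i", "j", "normal_i", "normal_j", "tau"])


def ensemble_variance(values) -> np.ndarray:
    """Unbiased sample variance across members (last axis)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] < 2:
        raise ValueError("need at least 2 members")
    return np.var(arr, axis=-1, ddof=1)


@dataclass
class UncertaintyReport:
    """Per-time variances of a scalar quantity and reduction percentages."""

    table: pd.DataFrame  # time, var_analysis, var_openloop, var_obs, reductions

    def peak_row(self, peak_time: float) -> pd.Series:
        k = int(np.argmin(np.abs(self.table["time"].to_numpy() - peak_time)))
        return self.table.iloc[k]


def _reduction(var_analysis, var_ref):
    var_ref = np.asarray(var_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (1.0 - np.asarray(var_analysis) / var_ref)
    return np.where(var_ref > 0, out, np.nan)


def uncertainty_report(
    times,
    analysis_values: np.ndarray,
    openloop_values: np.ndarray,
    obs_variance,
) -> UncertaintyReport:
    """Variance comparison of a scalar quantity across modalities.

    analysis_values, openloop_values : (T, N) per-time member values.
    obs_variance : (T,) or scalar observation-propagated variance.
    """
    times = np.asarray(times, dtype=float)
    var_a = ensemble_variance(analysis_values)
    var_o = ensemble_variance(openloop_values)
    var_y = np.broadcast_to(np.asarray(obs_variance, dtype=float), times.shape)
    df = pd.DataFrame(
        {
            "time": times,
            "var_analysis": var_a,
            "var_openloop": var_o,
            "var_obs": var_y,
            "reduction_vs_openloop_pct": _reduction(var_a, var_o),
            "reduction_vs_obs_pct": _reduction(var_a, var_y),
        }
    )
    return UncertaintyReport(df)


def truth_errors(
    estimates: list[VelocityField],
    truth: list[VelocityField],
    geom: GeometryMask,
) -> pd.DataFrame:
    """Fluid-cell RMSE of velocity magnitude per matched time point."""
    if len(estimates) != len(truth):
        raise ValueError("trajectory lengths differ")
    fluid = geom.is_fluid
    rows = []
    for est, tru in zip(estimates, truth):
        if est.u.shape != tru.u.shape:
            raise ValueError("grid mismatch between estimate and truth")
        ue, ve = est.cell_center_velocity()
        ut, vt = tru.cell_center_velocity()
        err = np.hypot(ue - ut, ve - vt)[fluid]
        rows.append((tru.time, float(np.sqrt(np.mean(err**2)))))
    return pd.DataFrame(rows, columns=["time", "rmse"])
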