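"""Closed-form channel flows used as solver oracles.

Plane Poiseuille flow and its oscillatory (Womersley-type) counterpart in a
2D channel of half-width ``h``:

    rho du/dt = G(t) + eta d2u/dy2,   u(+-h, t) = 0,

with ``G(t) = G`` (steady) or ``G cos(omega t)`` (pulsatile).  The pulsatile
solution is the standard complex-amplitude result

    u(y, t) = Re[ G/(i rho omega) * (1 - cosh(L y)/cosh(L h)) * e^{i omega t} ],
    L = sqrt(i omega / nu),

which reduces to the quasi-steady parabola G (h^2 - y^2) / (2 eta) as
``omega -> 0``.
"""

from __future__ import annotations

import numpy as np


def poiseuille_profile(halfwidth: float, pressure_gradient: float,
                       viscosity: float, y):
    """Steady plane-Poiseuille velocity u(y) = G (h^2 - y^2) / (2 eta)."""
    y = np.asarray(y, dtype=float)
    return pressure_gradient / (2.0 * viscosity) * (halfwidth**2 - y**2)


def poiseuille_rate(halfwidth: float, pressure_gradient: float,
                    viscosity: float) -> float:
    """Flow rate per unit depth, Q = 2 G h^3 / (3 eta)."""
    return 2.0 * pressure_gradient * halfwidth**3 / (3.0 * viscosity)


def womersley_complex_amplitude(halfwidth: float, pressure_amplitude: float,
                                frequency: float, density: float,
                                viscosity: float, y):
    """Complex velocity amplitude u_hat(y) of the oscillatory channel flow."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    y = np.asarray(y, dtype=complex)
    omega = 2.0 * np.pi * frequency
    nu = viscosity / density
    lam = np.sqrt(1j * omega / nu)
    amp = pressure_amplitude / (1j * density * omega)
    return amp * (1.0 - np.cosh(lam * y) / np.cosh(lam * halfwidth))


def womersley_profile(halfwidth: float, pressure_amplitude: float,
                      frequency: float, props, y, t: float):
    """Oscillatory plane-channel velocity under G(t) = G cos(2 pi f t).

    ``props`` supplies ``density`` and ``dynamic_viscosity`` (any object with
    those attributes).  Returns the real velocity at position(s) ``y``
    (measured from the centerline) and time ``t``.
    """
    uhat = womersley_complex_amplitude(
        halfwidth, pressure_amplitude, frequency,
        props.density, props.dynamic_viscosity, y,
    )
    omega = 2.0 * np.pi * frequency
    return np.real(uhat * np.exp(1j * omega * t))


def womersley_number(halfwidth: float, frequency: float, density: float,
                     viscosity: float) -> float:
    """alpha = h sqrt(omega / nu); >~ 3 means a distinctly blunted profile."""
    omega = 2.0 * np.pi * frequency
    return halfwidth * np.sqrt(omega * density / viscosity)
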