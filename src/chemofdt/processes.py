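"""Elementary stochastic processes and linear filters shared across modules."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ou_series", "adaptation_filter", "adaptation_gain_sq"]


def ou_series(n: int, dt: float, tau: float, var: float, rng: np.random.Generator,
              x0: float | None = None) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path, exact AR(1) discretization.

    Correlation time ``tau`` (s), stationary variance ``var``; initialized from
    the stationary law unless ``x0`` is given.
    """
    if tau <= 0 or var < 0:
        raise ValueError("tau must be > 0 and var >= 0")
    x = np.empty(n)
    sd = math.sqrt(var)
    x[0] = sd * rng.standard_normal() if x0 is None else x0
    phi = math.exp(-dt / tau)
    amp = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + amp * eps[i - 1]
    return x


def adaptation_filter(x: np.ndarray, dt: float, omega_rb: float,
                      alpha: float = 0.0, z0: float | None = None) -> np.ndarray:
    """Apply the linear two-state adaptation filter H(ω)=(iω+α·ω_RB)/(iω+ω_RB).

    ``omega_rb`` is the adaptation rate in rad/s; ``alpha`` the residual
    (unadapted) fraction, 0 = perfect adaptation.  Implemented as
    y = x − (1−α)·z with z a unit-DC-gain first-order low pass of x (exact
    exponential update, trapezoidal input).  ``z0`` defaults to x[0]
    (pre-adapted start).
    """
    if omega_rb < 0 or not (0.0 <= alpha <= 1.0):
        raise ValueError("need omega_rb >= 0 and 0 <= alpha <= 1")
    x = np.asarray(x, dtype=float)
    if omega_rb == 0:
        return x.copy()
    z = np.empty_like(x)
    z[0] = x[0] if z0 is None else z0
    phi = math.exp(-omega_rb * dt)
    for i in range(1, len(x)):
        xm = 0.5 * (x[i] + x[i - 1])
        z[i] = phi * z[i - 1] + (1.0 - phi) * xm
    return x - (1.0 - alpha) * z


def adaptation_gain_sq(omega: np.ndarray, omega_rb: float, alpha: float) -> np.ndarray:
    """|H(ω)|² of the two-state adaptation filter (ω in rad/s)."""
    w2 = np.asarray(omega, dtype=float) ** 2
    return (w2 + (alpha * omega_rb) ** 2) / (w2 + omega_rb ** 2)
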