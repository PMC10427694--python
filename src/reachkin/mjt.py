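"""Closed-form minimum-jerk trajectory (MJT) reference model.

The minimum-jerk trajectory is the point-to-point movement that minimizes
the time integral of squared jerk (the third derivative of position).  For
a one-dimensional movement from ``x0`` to ``xf`` over duration ``d`` the
unique minimizer is a quintic polynomial in normalized time ``tau = (t -
t_s) / d``:

    x(t) = x0 + (xf - x0) * (10 tau^3 - 15 tau^4 + 6 tau^5)
    v(t) = (xf - x0) / d * (30 tau^2 - 60 tau^3 + 30 tau^4)

with zero velocity and acceleration at both endpoints, a single bell-shaped
velocity peak of ``1.875 * (xf - x0) / d`` at the temporal midpoint, and a
jerk cost of ``720 * (xf - x0)^2 / d^5``.

Positions are expressed in percent of workspace width throughout, matching
the cursor-control experiments this package analyzes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MJTParams",
    "ReferenceTrace",
    "mjt_position",
    "mjt_velocity",
    "mjt_position_clamped",
    "mjt_jerk_cost",
    "sample_mjt",
    "PEAK_VELOCITY_COEFF",
]

#: Dimensionless peak of 30 tau^2 - 60 tau^3 + 30 tau^4, attained at tau = 0.5.
PEAK_VELOCITY_COEFF = 1.875


@dataclass(frozen=True)
class MJTParams:
    """Parameters of a point-to-point minimum-jerk movement.

    Parameters
    ----------
    x0, xf : float
        Start and target position, in percent of workspace width.  ``x0 ==
        xf`` is permitted and yields a constant trajectory.
    d : float
        Movement duration in seconds (must be positive).
    t_s : float, default 0.0
        Start time in seconds.  Traces are conventionally re-based so that
        movement onset is time zero.
    """

    x0: float
    xf: float
    d: float
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"movement duration must be positive, got d={self.d}")

    @property
    def t_f(self) -> float:
        return self.t_s + self.d

    @property
    def amplitude(self) -> float:
        return self.xf - self.x0

    @property
    def peak_velocity(self) -> float:
        """Analytic peak speed, ``1.875 * |xf - x0| / d`` (%/s)."""
        return PEAK_VELOCITY_COEFF * abs(self.amplitude) / self.d


@dataclass(frozen=True)
class ReferenceTrace:
    """A sampled reference trajectory: times (s), positions (%), velocities (%/s)."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if not (t.shape == x.shape == v.shape):
            raise ValueError("times, positions and velocities must share a shape")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "velocities", v)

    def __len__(self) -> int:
        return self.times.size


def _tau(params: MJTParams, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    lo, hi = params.t_s, params.t_f
    # tolerate float fuzz at the endpoints only
    eps = 1e-9 * max(1.0, params.d)
    if np.any(t < lo - eps) or np.any(t > hi + eps):
        raise ValueError(
            f"time outside the movement interval [{lo}, {hi}]; "
            "use mjt_position_clamped to extend with the boundary values"
        )
    return np.clip((t - lo) / params.d, 0.0, 1.0)


def mjt_position(params: MJTParams, t) -> np.ndarray | float:
    """Minimum-jerk position x(t) in % workspace width.

    ``t`` may be scalar or array, and must lie within ``[t_s, t_f]``.
    """
    tau = _tau(params, t)
    out = params.x0 + params.amplitude * (tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau)))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def mjt_velocity(params: MJTParams, t) -> np.ndarray | float:
    """Minimum-jerk velocity v(t) in %/s."""
    tau = _tau(params, t)
    out = (params.amplitude / params.d) * (tau**2 * (30.0 + tau * (-60.0 + 30.0 * tau)))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def mjt_position_clamped(params: MJTParams, t) -> np.ndarray | float:
    """Position with t clamped into [t_s, t_f]; x0 before onset, xf after the end.

    Intended for plotting/overlay against longer observed traces, where the
    reference is naturally flat outside the movement interval.
    """
    t = np.clip(np.asarray(t, dtype=float), params.t_s, params.t_f)
    return mjt_position(params, t)


def _analytic_jerk(params: MJTParams, t: np.ndarray) -> np.ndarray:
    # third derivative of the quintic: A/d^3 * (60 - 360 tau + 360 tau^2)
    tau = (t - params.t_s) / params.d
    return (params.amplitude / params.d**3) * (60.0 - 360.0 * tau + 360.0 * tau**2)


def mjt_jerk_cost(obj: MJTParams | ReferenceTrace, n_quad: int = 2001) -> float:
    """Integral of squared jerk over the movement, in %^2 / s^5.

    For :class:`MJTParams` the analytic third derivative is integrated with
    a composite trapezoid rule on ``n_quad`` points (the closed form is
    ``720 * (xf - x0)^2 / d^5``).  For a sampled :class:`ReferenceTrace`
    the jerk is estimated by repeated finite differencing of position,
    which needs at least 4 samples.
    """
    if isinstance(obj, MJTParams):
        t = np.linspace(obj.t_s, obj.t_f, n_quad)
        return float(np.trapezoid(_analytic_jerk(obj, t) ** 2, t))
    if len(obj) < 4:
        raise ValueError("jerk cost from samples needs at least 4 points")
    t, x = obj.times, obj.positions
    v = np.gradient(x, t)
    a = np.gradient(v, t)
    j = np.gradient(a, t)
    return float(np.trapezoid(j**2, t))


def sample_mjt(params: MJTParams, fs: float) -> ReferenceTrace:
    """Sample the trajectory on a uniform grid at ``fs`` Hz.

    The grid runs from ``t_s`` to ``t_f`` inclusive of both endpoints;
    a movement of duration ``d`` sampled at ``fs`` yields
    ``round(d * fs) + 1`` points (step exactly ``1/fs`` when ``d * fs`` is
    an integer, the nearest uniform step otherwise).
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got fs={fs}")
    n = int(round(params.d * fs)) + 1
    t = np.linspace(params.t_s, params.t_f, n)
    return ReferenceTrace(t, np.asarray(mjt_position(params, t)), np.asarray(mjt_velocity(params, t)))
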