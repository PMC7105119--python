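"""Fixed-step and adaptive explicit ODE integrators.

Three classic schemes: forward Euler, the 4th-order Runge–Kutta method,
and the embedded Runge–Kutta–Fehlberg 4(5) pair with adaptive step-size
control.  The right-hand side ``f(t, y)`` takes and returns array-likes.

The RKF45 controller is the standard one:
``dt_new = 0.9 * dt * (tol / err)**(1/5)`` clamped to ``[dt/4, 4*dt]``,
with the per-step error estimate required to stay below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OdeState:
    """Integration state: time, solution vector, step size, tolerance."""

    t: float
    y: np.ndarray
    dt: float = 0.01
    tol: float = 1e-6
    nfev: int = 0

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def _call(f, t, y, state):
    state.nfev += 1
    return np.asarray(f(t, y), dtype=float)


def ode_euler(f, state: OdeState, tEnd: float) -> OdeState:
    """Forward Euler with fixed step ``state.dt`` (last step shortened)."""
    if tEnd < state.t:
        raise ValueError("tEnd must be >= state.t")
    while state.t < tEnd - 1e-14:
        h = min(state.dt, tEnd - state.t)
        state.y = state.y + h * _call(f, state.t, state.y, state)
        state.t += h
    return state


def ode_rk4(f, state: OdeState, tEnd: float) -> OdeState:
    """Classic 4th-order Runge–Kutta with fixed step ``state.dt``."""
    if tEnd < state.t:
        raise ValueError("tEnd must be >= state.t")
    while state.t < tEnd - 1e-14:
        h = min(state.dt, tEnd - state.t)
        t, y = state.t, state.y
        k1 = _call(f, t, y, state)
        k2 = _call(f, t + h / 2, y + h / 2 * k1, state)
        k3 = _call(f, t + h / 2, y + h / 2 * k2, state)
        k4 = _call(f, t + h, y + h * k3, state)
        state.y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        state.t += h
    return state


# Fehlberg 4(5) tableau
_A = [
    [],
    [1 / 4],
    [3 / 32, 9 / 32],
    [1932 / 2197, -7200 / 2197, 7296 / 2197],
    [439 / 216, -8, 3680 / 513, -845 / 4104],
    [-8 / 27, 2, -3544 / 2565, 1859 / 4104, -11 / 40],
]
_C = [0, 1 / 4, 3 / 8, 12 / 13, 1, 1 / 2]
_B5 = [16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55]
_B4 = [25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0]

_SAFETY = 0.9
_DT_MIN = 1e-14


def ode_rkf45(f, state: OdeState, tEnd: float) -> OdeState:
    """Adaptive Runge–Kutta–Fehlberg 4(5) integration to ``tEnd``.

    Each step's embedded 4th/5th-order error estimate (max norm) is kept
    below ``state.tol``; rejected steps are retried with a smaller dt.
    Raises if the controller would shrink dt below ``1e-14``.
    """
    if tEnd < state.t:
        raise ValueError("tEnd must be >= state.t")
    while state.t < tEnd - 1e-14:
        h = min(state.dt, tEnd - state.t)
        t, y = state.t, state.y
        ks = []
        for stage in range(6):
            yi = y.copy()
            for j, a in enumerate(_A[stage]):
                yi = yi + h * a * ks[j]
            ks.append(_call(f, t + _C[stage] * h, yi, state))
        y5 = y + h * sum(b * k for b, k in zip(_B5, ks))
        y4 = y + h * sum(b * k for b, k in zip(_B4, ks))
        err = float(np.max(np.abs(y5 - y4)))
        if err <= state.tol or h <= _DT_MIN:
            state.t = t + h
            state.y = y5
        # controller (applied after accepted and rejected steps alike)
        if err == 0.0:
            factor = 4.0
        else:
            factor = min(4.0, max(0.25, _SAFETY * (state.tol / err) ** 0.2))
        state.dt = state.dt * factor
        if state.dt < _DT_MIN:
            raise RuntimeError("RKF45 step size underflow: tolerance unreachable")
    return state
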