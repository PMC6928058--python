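"""Kutta–Merson embedded Runge–Kutta integration.

The classical 5-stage Kutta–Merson scheme advances with a 4th-order
estimate and provides a built-in local error estimate at the cost of one
extra stage.  It is run fixed-step by default (the historical usage in
multibody packages) with an optional adaptive mode driven by the embedded
error estimate.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["kutta_merson_step", "integrate_fixed", "integrate_adaptive"]

Deriv = Callable[[float, np.ndarray], np.ndarray]


def kutta_merson_step(f: Deriv, t: float, y: np.ndarray, h: float):
    """One Kutta–Merson step of size ``h``.

    Returns ``(y_new, err)`` where ``err`` is the embedded local error
    estimate (same shape as ``y``).
    """
    k1 = f(t, y)
    k2 = f(t + h / 3, y + h * k1 / 3)
    k3 = f(t + h / 3, y + h * (k1 + k2) / 6)
    k4 = f(t + h / 2, y + h * (k1 + 3 * k3) / 8)
    k5 = f(t + h, y + h * (k1 - 3 * k3 + 4 * k4) / 2)
    y_new = y + h * (k1 + 4 * k4 + k5) / 6
    err = h * (2 * k1 - 9 * k3 + 8 * k4 - k5) / 30
    return y_new, err


def integrate_fixed(f: Deriv, t0: float, y0: np.ndarray, t1: float, h: float):
    """Integrate from t0 to t1 with fixed step h (last step shortened)."""
    t, y = t0, np.asarray(y0, dtype=float)
    while t < t1 - 1e-12:
        step = min(h, t1 - t)
        y, _ = kutta_merson_step(f, t, y, step)
        t += step
    return y


def integrate_adaptive(
    f: Deriv,
    t0: float,
    y0: np.ndarray,
    t1: float,
    h0: float,
    tol: float = 1e-8,
    h_min: float = 1e-6,
):
    """Adaptive integration using the embedded error estimate.

    Step is halved when the max-norm error estimate exceeds ``tol`` and
    doubled when it drops below ``tol/64`` (the classical Merson policy).
    """
    t, y, h = t0, np.asarray(y0, dtype=float), h0
    while t < t1 - 1e-12:
        step = min(h, t1 - t)
        y_new, err = kutta_merson_step(f, t, y, step)
        e = float(np.max(np.abs(err)))
        if e > tol and step > h_min:
            h = max(step / 2, h_min)
            continue
        t += step
        y = y_new
        if e < tol / 64:
            h = min(step * 2, h0 * 100)
    return y
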