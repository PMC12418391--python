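"""Shared brute-force oracles for the test suite (independent of the
package's adaptive integration path)."""

import math

import numpy as np

from mirpulse import ParamsM1


def rk4_reference_fr(p: ParamsM1, sigma_const: float, window: tuple, h: float = 1e-4) -> float:
    """Fold repression under constant synthesis via fixed-step RK4 + trapezoid.

    Integrates the M1 equations directly (hand-written RHS, independent of
    the package integrator) from the all-zero state, averages R over the
    window by the composite trapezoid rule on the fixed grid, and divides
    the closed-form basal average by it.
    """
    t0, t1 = window
    n = int(round(t1 / h))

    def rhs(y):
        R, r, C = y
        bind = p.kappa_on * r * R
        unbind = p.kappa_off * C
        return np.array(
            [
                1.0 - R - bind + unbind + p.gamma * p.beta * C,
                sigma_const - p.gamma * r - bind + unbind + p.alpha * C,
                bind - unbind - p.alpha * C - p.gamma * p.beta * C,
            ]
        )

    y = np.zeros(3)
    Rs = [0.0]
    for _ in range(n):
        k1 = rhs(y)
        k2 = rhs(y + h / 2 * k1)
        k3 = rhs(y + h / 2 * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        Rs.append(y[0])
    ts = np.arange(n + 1) * h
    mask = (ts >= t0) & (ts <= t1)
    repressed = np.trapezoid(np.array(Rs)[mask], ts[mask]) / (t1 - t0)
    basal = 1.0 + (0.0 - 1.0) * (math.exp(-t0) - math.exp(-t1)) / (t1 - t0)
    return basal / repressed
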