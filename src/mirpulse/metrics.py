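"""Fold repression under constant vs pulsed miRNA synthesis, and the scalar
metrics that summarize its frequency dependence.

Fold repression over an observation window is the ratio of the time-averaged
constitutive (miRNA-free) target level to its time-averaged repressed level:

    FR = <R_basal>_[t0, t1] / <R_repressed>_[t0, t1]

The window is [0, tau] by default, with tau the target's equilibration time
under the dose-equivalent constant synthesis sigma_const = sigma * d.  The
admissible frequency grid f_n = n / tau (n = 1..n_max, default n_max = 100)
contains exactly the frequencies whose pulse trains complete an integer
number of periods inside the window, which preserves dose conservation.

Scalar summaries of the FR_pulse(f) curve:

* advantage ``A``     — normalized area of the curve lying above FR_const
                        (log-frequency measure); in [0, 1].
* selectivity ``S``   — band-pass sharpness relative to a flat response over
                        the log-frequency span; in [0, 1].
* preferred frequency ``f*`` — grid frequency maximizing FR_pulse.
* differential selectivity ``DS`` — harmonic mean of two targets'
  selectivities times the log10 distance of their preferred frequencies;
  detects mutually exclusive frequency-driven repression of two targets
  sharing the miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import MirpulseError, ParameterError
from .forcing import ForcingSpec, constant_equivalent
from .models import (
    MODEL_COMPONENTS,
    ParamsM1,
    ParamsM2,
    SolverSettings,
    Trajectory,
    default_initial_state,
    equilibration_time,
    integrate,
)

__all__ = [
    "FrequencyResponse",
    "MetricSet",
    "time_average",
    "basal_average",
    "fold_repression",
    "frequency_response",
    "frequency_response_pair",
    "advantage",
    "selectivity",
    "preferred_frequency",
    "metric_set",
    "differential_selectivity",
    "dimensional_frequency",
    "dimensionless_frequency",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FrequencyResponse:
    """FR_pulse(f) on the admissible grid plus the constant-forcing reference."""

    tau: float
    frequencies: np.ndarray
    fr_pulse: np.ndarray
    fr_const: float
    target_id: str
    window_start: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if len(f) < 1 or np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be strictly increasing")
        if len(self.fr_pulse) != len(f):
            raise ParameterError("fr_pulse length must match frequencies")
        if self.fr_const <= 0 or np.any(np.asarray(self.fr_pulse) <= 0):
            raise ParameterError("fold repression values must be strictly positive")

    @property
    def n_max(self) -> int:
        return len(self.frequencies)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": np.arange(1, self.n_max + 1),
                "frequency": self.frequencies,
                "fr_pulse": self.fr_pulse,
            }
        )


@dataclass(frozen=True)
class MetricSet:
    advantage: float
    selectivity: float
    preferred_frequency: float

    def to_dict(self) -> dict:
        return {
            "advantage": self.advantage,
            "selectivity": self.selectivity,
            "preferred_frequency": self.preferred_frequency,
        }


def time_average(trajectory: Trajectory, component: str, window: tuple) -> float:
    """Trapezoidal time average of a component over [t0, t1].

    Window endpoints are linearly interpolated onto the dense output grid, so
    the window need not coincide with sample times (it must lie inside the
    trajectory span).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ParameterError(f"window must satisfy t1 > t0, got {window}")
    ts = trajectory.times
    if t0 < ts[0] - 1e-12 or t1 > ts[-1] + 1e-12:
        raise ParameterError(f"window {window} outside trajectory span [{ts[0]}, {ts[-1]}]")
    ys = trajectory.component(component)
    inside = (ts > t0) & (ts < t1)
    tt = np.concatenate([[t0], ts[inside], [t1]])
    yy = np.concatenate([[np.interp(t0, ts, ys)], ys[inside], [np.interp(t1, ts, ys)]])
    return float(np.trapezoid(yy, tt) / (t1 - t0))


def _basal_rates(model_id: str, params, target: str) -> tuple:
    """(synthesis, decay) of the target's miRNA-free linear dynamics."""
    if model_id == "M1":
        if target != "R":
            raise ParameterError(f"model M1 has a single target 'R', got {target!r}")
        return 1.0, 1.0
    if model_id == "M2":
        if target == "R1":
            return 1.0, 1.0
        if target == "R2":
            return params.delta, params.epsilon
        raise ParameterError(f"model M2 targets are 'R1'/'R2', got {target!r}")
    raise ParameterError(f"unknown model_id {model_id!r}")


def basal_average(
    model_id: str, params, target: str, initial_value: float, window: tuple
) -> float:
    """Exact window average of the constitutive (miRNA-free) target level.

    The basal dynamics dR/dt = s - k*R (s = 1, k = 1 for R/R1; s = delta,
    k = epsilon for R2) is linear, so the trajectory
    R_b(t) = s/k + (R0 - s/k) * exp(-k t) and its window average are closed
    form; this is the exact solution of the basal ODE started from the same
    target initial value as the repressed run.
    """
    s, k = _basal_rates(model_id, params, target)
    t0, t1 = window
    if not t1 > t0:
        raise ParameterError(f"window must satisfy t1 > t0, got {window}")
    rinf = s / k
    mean = rinf + (initial_value - rinf) * (math.exp(-k * t0) - math.exp(-k * t1)) / (
        k * (t1 - t0)
    )
    return float(mean)


def _target_index(model_id: str, target: str) -> int:
    return MODEL_COMPONENTS[model_id].index(target)


def _basal_mean_on_grid(
    model_id: str, params, target: str, initial_value: float, window: tuple, ts: np.ndarray
) -> float:
    """Window average of the closed-form basal solution sampled on a run's
    output grid, using the same trapezoid rule as the repressed average.

    Evaluating both numerator and denominator of FR with the same quadrature
    on the same grid cancels the discretization bias of the ratio (an
    identical basal and repressed run then gives FR = 1 to solver precision).
    """
    s, k = _basal_rates(model_id, params, target)
    t0, t1 = window
    rinf = s / k
    inside = (ts > t0) & (ts < t1)
    tt = np.concatenate([[t0], ts[inside], [t1]])
    yy = rinf + (initial_value - rinf) * np.exp(-k * tt)
    return float(np.trapezoid(yy, tt) / (t1 - t0))


def fold_repression(
    model_id: str,
    params,
    forcing: ForcingSpec,
    initial_state: np.ndarray | None = None,
    window: tuple = (0.0, 1.0),
    target: str | None = None,
    solver: SolverSettings = SolverSettings(),
) -> float:
    """FR = <basal>/<repressed> for one forcing over one window.

    The basal reference starts from the same target initial value as the
    repressed run, so constant, pulsed and basal trajectories are compared
    on equal footing.
    """
    if target is None:
        target = "R" if model_id == "M1" else "R1"
    if initial_state is None:
        initial_state = default_initial_state(model_id)
    idx = _target_index(model_id, target)
    traj = integrate(model_id, params, forcing, initial_state, t_end=window[1], solver=solver)
    repressed = time_average(traj, target, window)
    basal = _basal_mean_on_grid(
        model_id, params, target, float(initial_state[idx]), window, traj.times
    )
    if repressed == 0:
        raise MirpulseError("average repressed level is zero; fold repression undefined")
    if basal == 0:
        raise MirpulseError("basal target level is zero; fold repression undefined")
    return basal / repressed


def _fr_curves(
    model_id: str,
    params,
    duty: float,
    initial_state: np.ndarray,
    tau: float,
    n_max: int,
    window_start: float,
    solver: SolverSettings,
    targets: tuple,
) -> tuple:
    """FR_const and FR_pulse(f_n) per target, sharing one integration per forcing."""
    sigma = params.sigma
    sigma_const = constant_equivalent(sigma, duty)
    window = (window_start, window_start + tau)
    t_end = window[1]
    idxs = {tg: _target_index(model_id, tg) for tg in targets}

    const_traj = integrate(
        model_id,
        params,
        ForcingSpec(kind="constant", sigma=sigma_const),
        initial_state,
        t_end=t_end,
        solver=solver,
    )
    fr_const = {
        tg: _basal_mean_on_grid(
            model_id, params, tg, float(initial_state[i]), window, const_traj.times
        )
        / time_average(const_traj, tg, window)
        for tg, i in idxs.items()
    }

    freqs = np.arange(1, n_max + 1) / tau
    fr_pulse = {tg: np.empty(n_max) for tg in targets}
    for i, n in enumerate(range(1, n_max + 1)):
        spec = ForcingSpec(kind="square", sigma=sigma, duty=duty, period=tau / n)
        traj = integrate(model_id, params, spec, initial_state, t_end=t_end, solver=solver)
        for tg, j in idxs.items():
            basal = _basal_mean_on_grid(
                model_id, params, tg, float(initial_state[j]), window, traj.times
            )
            fr_pulse[tg][i] = basal / time_average(traj, tg, window)
    return freqs, fr_const, fr_pulse


def frequency_response(
    model_id: str,
    params,
    duty: float = 0.5,
    initial_state: np.ndarray | None = None,
    tau: float | None = None,
    n_max: int = 100,
    window_start: float = 0.0,
    rel_tol: float = 0.01,
    target: str | None = None,
    solver: SolverSettings = SolverSettings(),
) -> FrequencyResponse:
    """Compute FR_const and the FR_pulse(f) curve on the admissible grid.

    ``tau`` defaults to the target's equilibration time under the
    dose-equivalent constant synthesis ``params.sigma * duty`` started from
    the same initial state; the grid is f_n = n/tau for n = 1..n_max so every
    run fits an integer number of pulse periods into the window.
    """
    if n_max < 2:
        raise ParameterError(f"n_max must be >= 2, got {n_max}")
    if window_start < 0:
        raise ParameterError(f"window_start must be >= 0, got {window_start}")
    if target is None:
        target = "R" if model_id == "M1" else "R1"
    if initial_state is None:
        initial_state = default_initial_state(model_id)
    initial_state = np.asarray(initial_state, dtype=float)
    if tau is None:
        sigma_const = constant_equivalent(params.sigma, duty)
        tau = equilibration_time(
            model_id, params, sigma_const, initial_state, rel_tol=rel_tol, solver=solver
        )
    freqs, fr_const, fr_pulse = _fr_curves(
        model_id, params, duty, initial_state, tau, n_max, window_start, solver, (target,)
    )
    return FrequencyResponse(
        tau=tau,
        frequencies=freqs,
        fr_pulse=fr_pulse[target],
        fr_const=fr_const[target],
        target_id=target,
        window_start=window_start,
    )


def frequency_response_pair(
    params: ParamsM2,
    duty: float = 0.5,
    initial_state: np.ndarray | None = None,
    tau: float | None = None,
    n_max: int = 100,
    window_start: float = 0.0,
    rel_tol: float = 0.01,
    solver: SolverSettings = SolverSettings(),
) -> tuple:
    """FR responses of both M2 targets over the same window [0, tau].

    The window is set by the *first* target's equilibration time, so both
    species are probed on the time interval characteristic of R1's
    repression; each forcing is integrated once and averaged for both.
    """
    if initial_state is None:
        initial_state = default_initial_state("M2")
    initial_state = np.asarray(initial_state, dtype=float)
    if tau is None:
        sigma_const = constant_equivalent(params.sigma, duty)
        tau = equilibration_time(
            "M2", params, sigma_const, initial_state, rel_tol=rel_tol, solver=solver
        )
    freqs, fr_const, fr_pulse = _fr_curves(
        "M2", params, duty, initial_state, tau, n_max, window_start, solver, ("R1", "R2")
    )
    return tuple(
        FrequencyResponse(
            tau=tau,
            frequencies=freqs,
            fr_pulse=fr_pulse[tg],
            fr_const=fr_const[tg],
            target_id=tg,
            window_start=window_start,
        )
        for tg in ("R1", "R2")
    )


def _log_grid(resp: FrequencyResponse) -> np.ndarray:
    if resp.n_max < 2:
        raise ParameterError("metric undefined on a single-point frequency grid")
    return np.log(resp.frequencies)


def advantage(resp: FrequencyResponse) -> float:
    """Repressive advantage A of periodic over constant synthesis, in [0, 1].

    A is the area of FR_pulse(f) lying above FR_const, normalized by the
    total area under FR_pulse, both integrated against the log-frequency
    measure (trapezoid on the grid). Only the positive part of
    FR_pulse - FR_const contributes, so A >= 0 by construction.
    """
    x = _log_grid(resp)
    above = np.clip(resp.fr_pulse - resp.fr_const, 0.0, None)
    denom = np.trapezoid(resp.fr_pulse, x)
    return float(np.trapezoid(above, x) / denom)


def selectivity(resp: FrequencyResponse) -> float:
    """Band-pass selectivity S of the FR_pulse curve, in [0, 1].

    S = 1 - [integral of FR_pulse d(log f)] / [(log f_max - log f_min) * max FR_pulse]:
    a flat curve gives S = 0; a narrow peak approaches S = 1.
    """
    x = _log_grid(resp)
    peak = float(np.max(resp.fr_pulse))
    if peak <= 0:
        raise ParameterError("selectivity undefined: non-positive FR curve")
    return float(1.0 - np.trapezoid(resp.fr_pulse, x) / ((x[-1] - x[0]) * peak))


def preferred_frequency(resp: FrequencyResponse) -> float:
    """Grid frequency maximizing FR_pulse; ties break toward the lowest frequency."""
    return float(resp.frequencies[int(np.argmax(resp.fr_pulse))])


def metric_set(resp: FrequencyResponse) -> MetricSet:
    return MetricSet(
        advantage=advantage(resp),
        selectivity=selectivity(resp),
        preferred_frequency=preferred_frequency(resp),
    )


def differential_selectivity(resp1: FrequencyResponse, resp2: FrequencyResponse) -> float:
    """DS = harmonic_mean(S1, S2) * (log10 f*_2 - log10 f*_1).

    Positive (negative) when the second target prefers higher (lower)
    frequencies than the first and both are selective; the harmonic mean is
    taken as 0 when either selectivity is 0, so DS vanishes unless both
    targets are genuinely band-passed.
    """
    if not math.isclose(resp1.tau, resp2.tau) or not math.isclose(
        resp1.window_start, resp2.window_start
    ):
        raise ParameterError("responses must share the same observation window")
    if not np.allclose(resp1.frequencies, resp2.frequencies):
        raise ParameterError("responses must share the same frequency grid")
    s1, s2 = selectivity(resp1), selectivity(resp2)
    if s1 <= 0 or s2 <= 0:
        return 0.0
    hm = 2.0 / (1.0 / s1 + 1.0 / s2)
    return float(hm * (math.log10(preferred_frequency(resp2)) - math.log10(preferred_frequency(resp1))))


def dimensional_frequency(f: float, t_half: float) -> float:
    """Map a dimensionless frequency to 1/hours for a target of given half-life.

    Time is scaled by the target's degradation rate constant, so one
    dimensionless time unit equals 1/ln(2) target half-lives and
    f_hat = (ln 2 / t_half) * f.
    """
    if t_half <= 0:
        raise ParameterError(f"t_half must be > 0, got {t_half}")
    return LN2 / t_half * f


def dimensionless_frequency(f_hat: float, t_half: float) -> float:
    """Inverse of :func:`dimensional_frequency`."""
    if t_half <= 0:
        raise ParameterError(f"t_half must be > 0, got {t_half}")
    return f_hat * t_half / LN2
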