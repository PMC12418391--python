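"""Dimensionless mass-action models of miRNA-target interaction.

Model M1 couples one target RNA (R), the miRNA (r) and their complex (C):

    dR/dt = 1 - R - kappa_on * r * R + kappa_off * C + gamma * beta * C
    dr/dt = sigma(t) - gamma * r - kappa_on * r * R + kappa_off * C + alpha * C
    dC/dt = kappa_on * r * R - kappa_off * C - alpha * C - gamma * beta * C

Time and concentrations are nondimensionalized by the target's degradation
and synthesis rate constants, so target synthesis and decay are both scaled
to 1 and one time unit corresponds to ~1/ln(2) ~= 1.44 target half-lives.
``sigma`` is the miRNA synthesis rate relative to the target's, ``gamma``
its relative decay rate, ``kappa_on``/``kappa_off`` the scaled binding and
unbinding rates, and ``alpha``/``beta`` the in-complex decay rates of RNA
and miRNA relative to their unbound forms (degradation of one species in
complex recycles the other back into the free pool).

Model M2 adds a second, competing target RNA (R2, complex C2) sharing the
same miRNA pool, with synthesis rate ``delta`` and decay rate ``epsilon``
relative to the first target — the minimal competing-endogenous-RNA setting.
Silencing the competitor (kappa_on_2 = kappa_off_2 = delta = 0 from an empty
competitor state) reduces M2 exactly to M1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp
from scipy.optimize import brentq

from .errors import (
    DegenerateEquilibrationError,
    IntegrationError,
    ParameterError,
    SteadyStateError,
)
from .forcing import ForcingSpec, as_callable, switch_times

__all__ = [
    "ParamsM1",
    "ParamsM2",
    "SolverSettings",
    "Trajectory",
    "MODEL_COMPONENTS",
    "reaction_channels",
    "rhs_m1",
    "rhs_m2",
    "steady_state_m1",
    "steady_state_m2",
    "integrate",
    "equilibration_time",
]

MODEL_COMPONENTS = {
    "M1": ("R", "r", "C"),
    "M2": ("R1", "R2", "r", "C1", "C2"),
    "M1-basal": ("R",),
    "M2-basal": ("R1",),
}


def _check_nonneg(name: str, value: float, strict: bool = False) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"parameter {name} is not finite: {value}")
    if strict:
        if value <= 0:
            raise ParameterError(f"parameter {name} must be > 0, got {value}")
    elif value < 0:
        raise ParameterError(f"parameter {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class ParamsM1:
    """Dimensionless kinetic parameters of model M1.

    ``sigma`` here is the nominal miRNA synthesis amplitude; pulsed runs
    replace it with a time-dependent signal of that amplitude.
    """

    sigma: float
    kappa_on: float
    kappa_off: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for f_ in fields(self):
            _check_nonneg(f_.name, getattr(self, f_.name), strict=(f_.name == "gamma"))

    @property
    def K(self) -> float:
        """Dimensionless dissociation constant kappa_off / kappa_on."""
        if self.kappa_on == 0:
            raise ParameterError("K undefined for kappa_on = 0")
        return self.kappa_off / self.kappa_on

    def to_dict(self) -> dict:
        return {f_.name: getattr(self, f_.name) for f_ in fields(self)}


@dataclass(frozen=True)
class ParamsM2:
    """Dimensionless kinetic parameters of model M2 (miRNA + two targets)."""

    sigma: float
    gamma: float
    kappa_on_1: float
    kappa_off_1: float
    alpha_1: float
    beta_1: float
    kappa_on_2: float
    kappa_off_2: float
    alpha_2: float
    beta_2: float
    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        for f_ in fields(self):
            strict = f_.name in ("gamma", "epsilon")
            _check_nonneg(f_.name, getattr(self, f_.name), strict=strict)

    def m1_view(self) -> ParamsM1:
        """The miRNA/R1 subsystem as ParamsM1 (exact when the competitor is silenced)."""
        return ParamsM1(
            sigma=self.sigma,
            kappa_on=self.kappa_on_1,
            kappa_off=self.kappa_off_1,
            alpha=self.alpha_1,
            beta=self.beta_1,
            gamma=self.gamma,
        )

    def to_dict(self) -> dict:
        return {f_.name: getattr(self, f_.name) for f_ in fields(self)}


def reaction_channels(model_id: str) -> tuple:
    """Enumerate the elementary reaction channels of the mass-action scheme.

    M1 comprises eight channels: synthesis of each species, free degradation
    of each species, binding, unbinding, and the two in-complex degradations
    (each of which recycles the partner species).
    """
    if model_id == "M1":
        return (
            "synthesis: 0 -> R",
            "synthesis: 0 -> r",
            "degradation: R -> 0",
            "degradation: r -> 0",
            "binding: R + r -> C",
            "unbinding: C -> R + r",
            "complex RNA decay (miRNA recycled): C -> r",
            "complex miRNA decay (RNA recycled): C -> R",
        )
    if model_id == "M2":
        return (
            "synthesis: 0 -> R1",
            "synthesis: 0 -> R2",
            "synthesis: 0 -> r",
            "degradation: R1 -> 0",
            "degradation: R2 -> 0",
            "degradation: r -> 0",
            "binding: R1 + r -> C1",
            "binding: R2 + r -> C2",
            "unbinding: C1 -> R1 + r",
            "unbinding: C2 -> R2 + r",
            "complex RNA decay (miRNA recycled): C1 -> r",
            "complex RNA decay (miRNA recycled): C2 -> r",
            "complex miRNA decay (RNA recycled): C1 -> R1",
            "complex miRNA decay (RNA recycled): C2 -> R2",
        )
    raise ParameterError(f"unknown model_id {model_id!r}")


# ---------------------------------------------------------------------------
# Right-hand sides


def _validate_state(state: np.ndarray, names: Sequence[str]) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (len(names),):
        raise ParameterError(f"state must have {len(names)} components {names}, got shape {state.shape}")
    for name, value in zip(names, state):
        if not math.isfinite(value):
            raise ParameterError(f"state component {name} is not finite: {value}")
    return state


def rhs_m1(
    state: np.ndarray,
    t: float,
    params: ParamsM1,
    sigma_of_t: Callable[[float], float] | None = None,
) -> np.ndarray:
    """Time derivative of (R, r, C) under model M1.

    ``sigma_of_t`` replaces the constant miRNA synthesis rate ``params.sigma``
    when given (pulsed synthesis).
    """
    R, r, C = _validate_state(state, MODEL_COMPONENTS["M1"])
    sigma = params.sigma if sigma_of_t is None else float(sigma_of_t(t))
    if not math.isfinite(sigma):
        raise ParameterError(f"sigma(t) is not finite at t={t}: {sigma}")
    bind = params.kappa_on * r * R
    unbind = params.kappa_off * C
    dR = 1.0 - R - bind + unbind + params.gamma * params.beta * C
    dr = sigma - params.gamma * r - bind + unbind + params.alpha * C
    dC = bind - unbind - params.alpha * C - params.gamma * params.beta * C
    return np.array([dR, dr, dC])


def rhs_m2(
    state: np.ndarray,
    t: float,
    params: ParamsM2,
    sigma_of_t: Callable[[float], float] | None = None,
) -> np.ndarray:
    """Time derivative of (R1, R2, r, C1, C2) under model M2."""
    R1, R2, r, C1, C2 = _validate_state(state, MODEL_COMPONENTS["M2"])
    sigma = params.sigma if sigma_of_t is None else float(sigma_of_t(t))
    if not math.isfinite(sigma):
        raise ParameterError(f"sigma(t) is not finite at t={t}: {sigma}")
    p = params
    bind1 = p.kappa_on_1 * r * R1
    bind2 = p.kappa_on_2 * r * R2
    unbind1 = p.kappa_off_1 * C1
    unbind2 = p.kappa_off_2 * C2
    dR1 = 1.0 - R1 - bind1 + unbind1 + p.gamma * p.beta_1 * C1
    dR2 = p.delta - p.epsilon * R2 - bind2 + unbind2 + p.gamma * p.beta_2 * C2
    dr = (
        sigma
        - p.gamma * r
        - bind1
        + unbind1
        + p.alpha_1 * C1
        - bind2
        + unbind2
        + p.alpha_2 * C2
    )
    dC1 = bind1 - unbind1 - p.alpha_1 * C1 - p.gamma * p.beta_1 * C1
    dC2 = bind2 - unbind2 - p.alpha_2 * C2 - p.gamma * p.beta_2 * C2
    return np.array([dR1, dR2, dr, dC1, dC2])


# ---------------------------------------------------------------------------
# Steady states


def steady_state_m1(params: ParamsM1, sigma_const: float) -> np.ndarray:
    """Unique non-negative steady state of M1 under constant synthesis.

    At equilibrium the complex balance gives C = kappa_on*r*R / D with
    D = kappa_off + alpha + gamma*beta; substituting into the R and r
    balances reduces the system to a single quadratic in r whose root
    product is <= 0, so exactly one root is admissible (the model's unique
    positive steady state). A residual check at 1e-10 guards the result.
    """
    _check_nonneg("sigma_const", sigma_const)
    if params.kappa_on == 0:
        return np.array([1.0, sigma_const / params.gamma, 0.0])
    D = params.kappa_off + params.alpha + params.gamma * params.beta
    if D == 0:
        raise SteadyStateError(
            "complex has no dissipation channel (kappa_off = alpha = gamma*beta = 0): no steady state"
        )
    u = params.kappa_on * params.alpha / D
    v = params.kappa_on * params.gamma * params.beta / D
    g = params.gamma
    # quadratic g*u*r^2 + (g + v - sigma*u)*r - sigma = 0
    a = g * u
    b = g + v - sigma_const * u
    c = -sigma_const
    if a == 0:
        r = sigma_const / (g + v)
        n_admissible = 1
    else:
        disc = b * b - 4.0 * a * c
        sq = math.sqrt(disc)
        roots = ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a))
        admissible = [x for x in roots if x >= -1e-14]
        # root product c/a <= 0 guarantees at most one positive root; treat a
        # double root at 0 (sigma_const = 0) as the single admissible root
        admissible = sorted(set(max(x, 0.0) for x in admissible))
        n_admissible = len(admissible)
        if n_admissible != 1:
            raise SteadyStateError(
                f"expected exactly one admissible steady-state root, found {n_admissible}: {roots}"
            )
        r = admissible[0]
    R = 1.0 / (1.0 + u * r)
    C = params.kappa_on * r * R / D
    state = np.array([R, r, C])
    resid = rhs_m1(state, 0.0, params, lambda t: sigma_const)
    scale = max(1.0, sigma_const)
    if np.max(np.abs(resid)) > 1e-10 * scale:
        raise SteadyStateError(f"steady-state residual too large: {resid}")
    return state


def steady_state_m2(params: ParamsM2, sigma_const: float) -> np.ndarray:
    """Non-negative fixed point of M2 under constant synthesis.

    The complex and target balances reduce the fixed-point equations to a
    single monotone scalar equation for the free miRNA r:

        g(r) = gamma*r + v1*r/(1 + u1*r) + v2*delta*r/(epsilon + u2*r) = sigma_const

    with u_i = kappa_on_i*alpha_i/D_i and v_i = kappa_on_i*gamma*beta_i/D_i.
    g is strictly increasing, g(0) = 0 and g(sigma/gamma) >= sigma, so the
    root is bracketed on [0, sigma/gamma]; it is found by brentq and polished
    by Newton steps to a residual <= 1e-10.
    """
    _check_nonneg("sigma_const", sigma_const)
    p = params
    coeffs = []
    for kon, koff, al, be in (
        (p.kappa_on_1, p.kappa_off_1, p.alpha_1, p.beta_1),
        (p.kappa_on_2, p.kappa_off_2, p.alpha_2, p.beta_2),
    ):
        if kon == 0:
            coeffs.append((0.0, 0.0, 1.0))
            continue
        D = koff + al + p.gamma * be
        if D == 0:
            raise SteadyStateError("complex has no dissipation channel: no steady state")
        coeffs.append((kon * al / D, kon * p.gamma * be / D, D))
    (u1, v1, _), (u2, v2, _) = coeffs

    def g(r: float) -> float:
        return (
            p.gamma * r
            + v1 * r / (1.0 + u1 * r)
            + v2 * p.delta * r / (p.epsilon + u2 * r)
        )

    def gprime(r: float) -> float:
        return (
            p.gamma
            + v1 / (1.0 + u1 * r) ** 2
            + v2 * p.delta * p.epsilon / (p.epsilon + u2 * r) ** 2
        )

    if sigma_const == 0:
        r = 0.0
    else:
        hi = sigma_const / p.gamma
        r = brentq(lambda x: g(x) - sigma_const, 0.0, hi, xtol=1e-300, rtol=8.9e-16)
        for _ in range(3):  # Newton polish toward machine-precision residual
            step = (g(r) - sigma_const) / gprime(r)
            r = max(0.0, r - step)

    R1 = 1.0 / (1.0 + u1 * r)
    R2 = p.delta / (p.epsilon + u2 * r)
    D1 = p.kappa_off_1 + p.alpha_1 + p.gamma * p.beta_1
    D2 = p.kappa_off_2 + p.alpha_2 + p.gamma * p.beta_2
    C1 = p.kappa_on_1 * r * R1 / D1 if p.kappa_on_1 > 0 else 0.0
    C2 = p.kappa_on_2 * r * R2 / D2 if p.kappa_on_2 > 0 else 0.0
    state = np.array([R1, R2, r, C1, C2])
    resid = rhs_m2(state, 0.0, params, lambda t: sigma_const)
    scale = max(1.0, sigma_const, p.delta)
    if np.max(np.abs(resid)) > 1e-10 * scale:
        raise SteadyStateError(f"M2 steady-state residual too large: {resid}")
    return state


# ---------------------------------------------------------------------------
# Integration


@dataclass(frozen=True)
class SolverSettings:
    """Numerical integration settings.

    A stiff-capable method is required because ``kappa_on`` (and hence the
    binding relaxation rate kappa_on*r) can exceed the unit target turnover
    by orders of magnitude. ``points_per_period`` controls the dense output
    used for time-averaging (per forcing period, or per unit time for
    constant forcing). Components undershooting below ``-undershoot_tol``
    abort the run; smaller undershoot is clamped to 0 as solver noise.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    points_per_period: int = 200
    undershoot_tol: float = 1e-9

    def to_dict(self) -> dict:
        return {
            "rtol": self.rtol,
            "atol": self.atol,
            "method": self.method,
            "points_per_period": self.points_per_period,
            "undershoot_tol": self.undershoot_tol,
        }


#: faster profile for large parameter sweeps (documented package default for
#: sampling studies; metrics are ratios of window averages and are robust to
#: the looser tolerance)
FAST_SOLVER = SolverSettings(rtol=1e-6, atol=1e-9, points_per_period=60, undershoot_tol=1e-8)


@dataclass(frozen=True)
class Trajectory:
    """Dense ODE solution on a strictly increasing time grid starting at 0."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_components)
    model_id: str
    forcing: ForcingSpec | None = None

    def __post_init__(self) -> None:
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ParameterError("trajectory times must start at 0 and increase strictly")
        names = MODEL_COMPONENTS.get(self.model_id)
        if names is None:
            raise ParameterError(f"unknown model_id {self.model_id!r}")
        if self.states.shape != (len(self.times), len(names)):
            raise ParameterError(
                f"states shape {self.states.shape} does not match model {self.model_id}"
            )

    @property
    def components(self) -> tuple:
        return MODEL_COMPONENTS[self.model_id]

    def component(self, name: str) -> np.ndarray:
        try:
            idx = self.components.index(name)
        except ValueError:
            raise ParameterError(f"model {self.model_id} has no component {name!r}") from None
        return self.states[:, idx]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for i, name in enumerate(self.components):
            data[name] = self.states[:, i]
        return pd.DataFrame(data)


def _make_rhs(model_id: str, params) -> Callable:
    """Unchecked fast RHS f(t, y, sigma) used inside the integrator."""
    if model_id == "M1":
        kon, koff, al, be, g = (
            params.kappa_on,
            params.kappa_off,
            params.alpha,
            params.beta,
            params.gamma,
        )
        gb = g * be

        def f(t, y, sigma):
            R, r, C = y
            bind = kon * r * R
            unbind = koff * C
            return (
                1.0 - R - bind + unbind + gb * C,
                sigma - g * r - bind + unbind + al * C,
                bind - unbind - al * C - gb * C,
            )

        return f
    if model_id == "M2":
        p = params
        gb1 = p.gamma * p.beta_1
        gb2 = p.gamma * p.beta_2

        def f(t, y, sigma):
            R1, R2, r, C1, C2 = y
            bind1 = p.kappa_on_1 * r * R1
            bind2 = p.kappa_on_2 * r * R2
            unbind1 = p.kappa_off_1 * C1
            unbind2 = p.kappa_off_2 * C2
            return (
                1.0 - R1 - bind1 + unbind1 + gb1 * C1,
                p.delta - p.epsilon * R2 - bind2 + unbind2 + gb2 * C2,
                sigma - p.gamma * r - bind1 + unbind1 + p.alpha_1 * C1 - bind2 + unbind2 + p.alpha_2 * C2,
                bind1 - unbind1 - p.alpha_1 * C1 - gb1 * C1,
                bind2 - unbind2 - p.alpha_2 * C2 - gb2 * C2,
            )

        return f
    if model_id == "M1-basal":

        def f(t, y, sigma):
            return (1.0 - y[0],)

        return f
    if model_id == "M2-basal":

        def f(t, y, sigma):
            return (1.0 - y[0],)

        return f
    raise ParameterError(f"unknown model_id {model_id!r}")


def _make_jac(model_id: str, params) -> Callable:
    """Analytic Jacobian of the RHS (sigma-independent).

    Supplying it matters: free miRNA can exceed free target by many orders
    of magnitude, which wrecks finite-difference Jacobians and makes the
    stiff solver thrash on strongly bound states.
    """
    if model_id == "M1":
        kon, koff, al, g = params.kappa_on, params.kappa_off, params.alpha, params.gamma
        gb = g * params.beta

        def jac(t, y):
            R, r, C = y
            return np.array(
                [
                    [-1.0 - kon * r, -kon * R, koff + gb],
                    [-kon * r, -g - kon * R, koff + al],
                    [kon * r, kon * R, -koff - al - gb],
                ]
            )

        return jac
    if model_id == "M2":
        p = params
        gb1 = p.gamma * p.beta_1
        gb2 = p.gamma * p.beta_2
        k1, k2 = p.kappa_on_1, p.kappa_on_2

        def jac(t, y):
            R1, R2, r, C1, C2 = y
            return np.array(
                [
                    [-1.0 - k1 * r, 0.0, -k1 * R1, p.kappa_off_1 + gb1, 0.0],
                    [0.0, -p.epsilon - k2 * r, -k2 * R2, 0.0, p.kappa_off_2 + gb2],
                    [
                        -k1 * r,
                        -k2 * r,
                        -p.gamma - k1 * R1 - k2 * R2,
                        p.kappa_off_1 + p.alpha_1,
                        p.kappa_off_2 + p.alpha_2,
                    ],
                    [k1 * r, 0.0, k1 * R1, -(p.kappa_off_1 + p.alpha_1 + gb1), 0.0],
                    [0.0, k2 * r, k2 * R2, 0.0, -(p.kappa_off_2 + p.alpha_2 + gb2)],
                ]
            )

        return jac

    def jac(t, y):
        return np.array([[-1.0]])

    return jac


def default_initial_state(model_id: str) -> np.ndarray:
    """All species unexpressed (the declared, configurable default)."""
    return np.zeros(len(MODEL_COMPONENTS[model_id]))


def integrate(
    model_id: str,
    params,
    forcing: ForcingSpec,
    initial_state: np.ndarray | None = None,
    t_end: float = 10.0,
    solver: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate a model under the given forcing on [0, t_end].

    For square-wave forcing, integration is restarted at every ON/OFF switch
    time so the discontinuity never falls inside a solver step (piecewise
    integration over smooth segments, each with a constant synthesis rate);
    this makes the result robust to solver tolerances. Dense output is
    produced at ``points_per_period`` points per forcing period (per unit
    time for constant forcing).
    """
    if not t_end > 0:
        raise ParameterError(f"t_end must be > 0, got {t_end}")
    names = MODEL_COMPONENTS.get(model_id)
    if names is None:
        raise ParameterError(f"unknown model_id {model_id!r}")
    if initial_state is None:
        initial_state = default_initial_state(model_id)
    y0 = _validate_state(initial_state, names)
    if np.any(y0 < 0):
        raise ParameterError("initial state must be non-negative")

    f = _make_rhs(model_id, params)
    jac = _make_jac(model_id, params)

    # segment boundaries and the constant/ callable sigma on each segment
    if forcing.kind == "square" and not model_id.endswith("basal"):
        sw = switch_times(forcing, t_end)
        # drop switches within rounding distance of 0, t_end or each other:
        # they would create (near-)zero-length segments the solver rejects
        eps = 1e-12 * max(1.0, t_end)
        sw = sw[(sw > eps) & (sw < t_end - eps)]
        if len(sw) > 1:
            sw = sw[np.concatenate([[True], np.diff(sw) > eps])]
        bounds = np.concatenate([[0.0], sw, [t_end]])
        wave = as_callable(forcing)
        # sigma is piecewise constant: evaluate at segment midpoints
        seg_sigma = [float(wave(0.5 * (a + b))) for a, b in zip(bounds[:-1], bounds[1:])]
        seg_fun = [(lambda t, y, s=s: f(t, y, s)) for s in seg_sigma]
        pts_per_time = solver.points_per_period / forcing.period
    elif model_id.endswith("basal"):
        bounds = np.array([0.0, t_end])
        seg_fun = [lambda t, y: f(t, y, 0.0)]
        pts_per_time = solver.points_per_period / (
            forcing.period if forcing.kind != "constant" and forcing.period else 1.0
        )
    elif forcing.kind == "constant":
        bounds = np.array([0.0, t_end])
        sigma0 = forcing.sigma
        seg_fun = [lambda t, y: f(t, y, sigma0)]
        pts_per_time = float(solver.points_per_period)
    else:  # sinusoid: smooth, single segment
        bounds = np.array([0.0, t_end])
        wave = as_callable(forcing)
        seg_fun = [lambda t, y: f(t, y, float(wave(t)))]
        pts_per_time = solver.points_per_period / forcing.period

    all_t = [np.array([0.0])]
    all_y = [y0.reshape(1, -1)]
    y = y0
    for (a, b), fun in zip(zip(bounds[:-1], bounds[1:]), seg_fun):
        npts = max(2, int(math.ceil((b - a) * pts_per_time)) + 1)
        t_eval = np.linspace(a, b, npts)
        if solver.method == "LSODA":
            # the light Fortran LSODA wrapper: same algorithm as
            # solve_ivp(method="LSODA") at a fraction of the per-call overhead,
            # which matters because square-wave runs restart at every switch
            import warnings

            from scipy.integrate import ODEintWarning

            with warnings.catch_warnings():
                # failures are detected from info["message"] below
                warnings.simplefilter("ignore", ODEintWarning)
                ys, info = odeint(
                    fun,
                    y,
                    t_eval,
                    Dfun=jac,
                    rtol=solver.rtol,
                    atol=solver.atol,
                    tfirst=True,
                    full_output=True,
                    printmessg=False,
                    mxstep=100000,
                )
            if info["message"] != "Integration successful.":
                # LSODA's error control can destabilize at loose tolerances on
                # strongly bound states; retry the segment with stiff BDF
                sol = solve_ivp(
                    fun,
                    (a, b),
                    y,
                    method="BDF",
                    jac=jac,
                    t_eval=t_eval,
                    rtol=solver.rtol,
                    atol=solver.atol,
                )
                if not sol.success:
                    raise IntegrationError(
                        f"solver failed near t={sol.t[-1] if len(sol.t) else a}: {sol.message}"
                    )
                ys = sol.y.T
            y = ys[-1]
            all_t.append(t_eval[1:])
            all_y.append(ys[1:])
        else:
            sol = solve_ivp(
                fun,
                (a, b),
                y,
                method=solver.method,
                t_eval=t_eval,
                rtol=solver.rtol,
                atol=solver.atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"solver failed near t={sol.t[-1] if len(sol.t) else a}: {sol.message}"
                )
            y = sol.y[:, -1]
            all_t.append(sol.t[1:])
            all_y.append(sol.y.T[1:])

    times = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=0)

    low = states.min()
    if low < -solver.undershoot_tol:
        comp = names[int(np.argwhere(states == low)[0][1])]
        raise IntegrationError(
            f"component {comp} undershot to {low}, beyond the numerical tolerance "
            f"{-solver.undershoot_tol}: positivity violated"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=times, states=states, model_id=model_id, forcing=forcing)


def equilibration_time(
    model_id: str,
    params,
    sigma_const: float,
    initial_state: np.ndarray | None = None,
    rel_tol: float = 0.01,
    solver: SolverSettings = SolverSettings(),
    _grid_points: int = 4001,
) -> float:
    """Time for the (first) target to settle at its constant-synthesis steady state.

    Returns the first dense-output time after which the monitored component
    (R for M1, R1 for M2) stays within ``rel_tol`` relative deviation of its
    steady-state value for all later sampled times. This equilibration time
    tau defines the fold-repression observation window and the admissible
    frequency grid f_n = n/tau.
    """
    if not (0 < rel_tol <= 0.1):
        raise ParameterError(f"rel_tol must lie in (0, 0.1], got {rel_tol}")
    if model_id == "M1":
        target_star = steady_state_m1(params, sigma_const)[0]
        idx = 0
    elif model_id == "M2":
        target_star = steady_state_m2(params, sigma_const)[0]
        idx = 0
    else:
        raise ParameterError(f"equilibration_time supports M1/M2, got {model_id!r}")
    if initial_state is None:
        initial_state = default_initial_state(model_id)
    y0 = np.asarray(initial_state, dtype=float)

    f = _make_rhs(model_id, params)
    fun = lambda t, y: f(t, y, sigma_const)
    jac = _make_jac(model_id, params)

    # coarse relaxation scale: unit target turnover plus the miRNA's 1/gamma
    T = 10.0 * max(1.0, 1.0 / params.gamma)
    if model_id == "M2":
        T = max(T, 10.0 / params.epsilon)
    for _ in range(16):
        method = solver.method
        sol = solve_ivp(
            fun,
            (0.0, T),
            y0,
            method=method,
            jac=jac if method in ("LSODA", "BDF", "Radau") else None,
            dense_output=True,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success and method == "LSODA":
            sol = solve_ivp(
                fun, (0.0, T), y0, method="BDF", jac=jac,
                dense_output=True, rtol=solver.rtol, atol=solver.atol,
            )
        if not sol.success:
            raise IntegrationError(f"solver failed near t={sol.t[-1]}: {sol.message}")
        ts = np.linspace(0.0, T, _grid_points)
        traj = sol.sol(ts)[idx]
        dev = np.abs(traj - target_star) / target_star
        outside = dev > rel_tol
        if not outside.any():
            raise DegenerateEquilibrationError(
                "target starts within tolerance of its steady state: equilibration time undefined"
            )
        last = int(np.nonzero(outside)[0][-1])
        if last < _grid_points - 1:
            return float(ts[last + 1])
        T *= 2.0  # not yet converged inside the window
    raise IntegrationError("equilibration time not found within the maximum horizon")
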