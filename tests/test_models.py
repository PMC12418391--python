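"""Mass-action models: right-hand sides, steady states, integration, equilibration."""

import math

import numpy as np
import pytest

from mirpulse import (
    DegenerateEquilibrationError,
    ForcingSpec,
    ParameterError,
    ParamsM1,
    ParamsM2,
    SolverSettings,
    equilibration_time,
    integrate,
    reaction_channels,
    rhs_m1,
    rhs_m2,
    steady_state_m1,
    steady_state_m2,
)
from conftest import random_params_m1


def m1_terms_oracle(state, sigma, p):
    """Independent term-by-term evaluation of the M1 mass-action balance.

    Each kinetic process contributes its term separately (synthesis, free
    decay, binding, unbinding, in-complex decays), and the derivative of
    each species is assembled as the signed sum of the processes that
    produce or consume it.
    """
    R, r, C = state
    synth_R = 1.0
    synth_r = sigma
    decay_R = R
    decay_r = p.gamma * r
    binding = p.kappa_on * r * R
    unbinding = p.kappa_off * C
    complex_rna_decay = p.alpha * C        # C -> r (miRNA recycled)
    complex_mirna_decay = p.gamma * p.beta * C  # C -> R (RNA recycled)
    dR = synth_R - decay_R - binding + unbinding + complex_mirna_decay
    dr = synth_r - decay_r - binding + unbinding + complex_rna_decay
    dC = binding - unbinding - complex_rna_decay - complex_mirna_decay
    return np.array([dR, dr, dC])


def m2_terms_oracle(state, sigma, p):
    R1, R2, r, C1, C2 = state
    b1 = p.kappa_on_1 * r * R1
    b2 = p.kappa_on_2 * r * R2
    u1 = p.kappa_off_1 * C1
    u2 = p.kappa_off_2 * C2
    rna1 = p.alpha_1 * C1
    rna2 = p.alpha_2 * C2
    mir1 = p.gamma * p.beta_1 * C1
    mir2 = p.gamma * p.beta_2 * C2
    return np.array(
        [
            1.0 - R1 - b1 + u1 + mir1,
            p.delta - p.epsilon * R2 - b2 + u2 + mir2,
            sigma - p.gamma * r - b1 + u1 + rna1 - b2 + u2 + rna2,
            b1 - u1 - rna1 - mir1,
            b2 - u2 - rna2 - mir2,
        ]
    )


class TestRhs:
    def test_decoupled_steady_state_has_zero_derivative(self):
        p = ParamsM1(sigma=2.0, kappa_on=0.0, kappa_off=1.0, alpha=1.0, beta=1.0, gamma=0.5)
        np.testing.assert_allclose(
            rhs_m1(np.array([1.0, 2.0 / 0.5, 0.0]), 0.0, p), np.zeros(3), atol=1e-14
        )

    def test_empty_state_only_synthesis(self):
        p = ParamsM1(sigma=0.0, kappa_on=3.0, kappa_off=1.0, alpha=1.0, beta=1.0, gamma=1.0)
        np.testing.assert_allclose(rhs_m1(np.zeros(3), 0.0, p), [1.0, 0.0, 0.0])
        p2 = ParamsM2(
            sigma=0.0, gamma=1.0, kappa_on_1=1.0, kappa_off_1=1.0, alpha_1=1.0, beta_1=1.0,
            kappa_on_2=2.0, kappa_off_2=1.0, alpha_2=1.0, beta_2=1.0, delta=0.7, epsilon=2.0,
        )
        np.testing.assert_allclose(rhs_m2(np.zeros(5), 0.0, p2), [1.0, 0.7, 0.0, 0.0, 0.0])

    def test_generic_matches_term_oracle(self, rng):
        for _ in range(25):
            p = random_params_m1(rng)
            state = rng.uniform(0, 3, size=3)
            expected = m1_terms_oracle(state, p.sigma, p)
            np.testing.assert_allclose(rhs_m1(state, 0.0, p), expected, atol=1e-12)

    def test_m2_generic_matches_term_oracle(self, rng):
        for _ in range(25):
            vals = 10 ** rng.uniform(-1, 1, size=12)
            p = ParamsM2(*vals)
            state = rng.uniform(0, 3, size=5)
            expected = m2_terms_oracle(state, p.sigma, p)
            np.testing.assert_allclose(rhs_m2(state, 0.0, p), expected, atol=1e-12)

    def test_m2_reduces_to_m1(self, rng):
        for _ in range(10):
            m1 = random_params_m1(rng)
            p2 = ParamsM2(
                sigma=m1.sigma, gamma=m1.gamma,
                kappa_on_1=m1.kappa_on, kappa_off_1=m1.kappa_off,
                alpha_1=m1.alpha, beta_1=m1.beta,
                kappa_on_2=0.0, kappa_off_2=0.0, alpha_2=0.0, beta_2=0.0,
                delta=0.0, epsilon=1.0,
            )
            R1, r, C1 = rng.uniform(0, 2, size=3)
            d2 = rhs_m2(np.array([R1, 0.0, r, C1, 0.0]), 0.0, p2)
            d1 = rhs_m1(np.array([R1, r, C1]), 0.0, m1)
            np.testing.assert_allclose([d2[0], d2[2], d2[3]], d1, atol=1e-14)
            assert d2[1] == 0.0 and d2[4] == 0.0

    def test_mass_bookkeeping_identities(self, rng):
        """Binding/unbinding cancels in d(R+C)/dt and d(r+C)/dt."""
        for _ in range(20):
            p = random_params_m1(rng)
            R, r, C = rng.uniform(0, 3, size=3)
            dR, dr, dC = rhs_m1(np.array([R, r, C]), 0.0, p)
            assert dR + dC == pytest.approx(1.0 - R - p.alpha * C, abs=1e-12)
            assert dr + dC == pytest.approx(p.sigma - p.gamma * r - p.gamma * p.beta * C, abs=1e-12)

    def test_nonfinite_state_rejected_with_field_name(self):
        p = ParamsM1(sigma=1, kappa_on=1, kappa_off=1, alpha=1, beta=1, gamma=1)
        with pytest.raises(ParameterError, match="component r"):
            rhs_m1(np.array([1.0, np.nan, 0.0]), 0.0, p)

    def test_invalid_params_rejected_with_field_name(self):
        with pytest.raises(ParameterError, match="gamma"):
            ParamsM1(sigma=1, kappa_on=1, kappa_off=1, alpha=1, beta=1, gamma=0.0)
        with pytest.raises(ParameterError, match="kappa_on"):
            ParamsM1(sigma=1, kappa_on=-1, kappa_off=1, alpha=1, beta=1, gamma=1)


class TestReactionCensus:
    def test_m1_has_eight_channels(self):
        channels = reaction_channels("M1")
        assert len(channels) == 8

    def test_m2_channel_structure(self):
        channels = reaction_channels("M2")
        assert len(channels) == 14
        assert sum("synthesis" in c for c in channels) == 3


class TestSteadyState:
    def test_decoupled(self):
        p = ParamsM1(sigma=1, kappa_on=0, kappa_off=0, alpha=1, beta=1, gamma=2.0)
        np.testing.assert_allclose(steady_state_m1(p, 3.0), [1.0, 1.5, 0.0])

    def test_no_mirna(self):
        p = ParamsM1(sigma=0, kappa_on=5, kappa_off=1, alpha=1, beta=1, gamma=1)
        np.testing.assert_allclose(steady_state_m1(p, 0.0), [1.0, 0.0, 0.0])

    def test_matches_long_time_integration(self, rng):
        for _ in range(10):
            p = random_params_m1(rng)
            ss = steady_state_m1(p, p.sigma)
            t_end = 60.0 * max(1.0, 1.0 / p.gamma)
            traj = integrate(
                "M1", p, ForcingSpec(kind="constant", sigma=p.sigma),
                initial_state=None, t_end=t_end,
                solver=SolverSettings(points_per_period=2),
            )
            final = traj.states[-1]
            np.testing.assert_allclose(final, ss, rtol=1e-6, atol=1e-8)

    def test_uniqueness_over_many_draws(self, rng):
        # steady_state_m1 raises if the admissible-root count differs from 1
        for _ in range(1000):
            p = random_params_m1(rng)
            ss = steady_state_m1(p, p.sigma)
            assert np.all(ss >= 0)

    def test_m2_decoupled(self):
        p = ParamsM2(
            sigma=1, gamma=2.0, kappa_on_1=0, kappa_off_1=0, alpha_1=1, beta_1=1,
            kappa_on_2=0, kappa_off_2=0, alpha_2=1, beta_2=1, delta=0.5, epsilon=0.25,
        )
        np.testing.assert_allclose(steady_state_m2(p, 3.0), [1.0, 2.0, 1.5, 0.0, 0.0])

    def test_m2_unsynthesized_competitor_vanishes(self):
        p = ParamsM2(
            sigma=1, gamma=1.0, kappa_on_1=4, kappa_off_1=1, alpha_1=2, beta_1=0.5,
            kappa_on_2=7, kappa_off_2=1, alpha_2=2, beta_2=0.5, delta=0.0, epsilon=1.0,
        )
        ss2 = steady_state_m2(p, 1.0)
        assert ss2[1] == pytest.approx(0.0, abs=1e-12)
        assert ss2[4] == pytest.approx(0.0, abs=1e-12)
        ss1 = steady_state_m1(p.m1_view(), 1.0)
        np.testing.assert_allclose([ss2[0], ss2[2], ss2[3]], ss1, rtol=1e-10)

    def test_m2_matches_long_time_integration(self, rng):
        for _ in range(5):
            vals = 10 ** rng.uniform(-1, 1, size=12)
            p = ParamsM2(*vals)
            ss = steady_state_m2(p, p.sigma)
            t_end = 60.0 * max(1.0, 1.0 / p.gamma, 1.0 / p.epsilon)
            traj = integrate(
                "M2", p, ForcingSpec(kind="constant", sigma=p.sigma),
                t_end=t_end, solver=SolverSettings(points_per_period=2),
            )
            np.testing.assert_allclose(traj.states[-1], ss, rtol=1e-6, atol=1e-8)


def rk4_fixed_step(model_rhs, y0, t_end, h, wave):
    """Brute-force fixed-step RK4 with the forcing evaluated at substep times."""
    n = int(round(t_end / h))
    y = np.asarray(y0, dtype=float)
    out = [y.copy()]
    for i in range(n):
        t = i * h  # index-based time avoids accumulation drift
        # steps are aligned with the square wave's segments, so the step
        # midpoint identifies the segment and its constant sigma exactly
        sigma = float(wave(t + h / 2))
        k1 = model_rhs(t, y, sigma)
        k2 = model_rhs(t + h / 2, y + h / 2 * np.asarray(k1), sigma)
        k3 = model_rhs(t + h / 2, y + h / 2 * np.asarray(k2), sigma)
        k4 = model_rhs(t + h, y + h * np.asarray(k3), sigma)
        y = y + h / 6 * (np.asarray(k1) + 2 * np.asarray(k2) + 2 * np.asarray(k3) + np.asarray(k4))
        out.append(y.copy())
    return np.array(out)


class TestIntegrate:
    def test_basal_closed_form(self):
        p = ParamsM1(sigma=0, kappa_on=0, kappa_off=0, alpha=1, beta=1, gamma=1)
        traj = integrate("M1", p, ForcingSpec(kind="constant", sigma=0.0), t_end=5.0)
        expected = 1.0 - np.exp(-traj.times)
        np.testing.assert_allclose(traj.component("R"), expected, atol=1e-8)

    def test_fixed_point_is_invariant(self, median_params_m1):
        ss = steady_state_m1(median_params_m1, 1.0)
        traj = integrate(
            "M1", median_params_m1, ForcingSpec(kind="constant", sigma=1.0),
            initial_state=ss, t_end=5.0,
        )
        np.testing.assert_allclose(traj.states, np.tile(ss, (len(traj.times), 1)), atol=1e-8)

    def test_square_wave_matches_fixed_step_rk4(self, rng):
        """Adaptive piecewise integration vs a brute-force RK4 at h = 1e-4."""
        from mirpulse.models import _make_rhs
        from mirpulse.forcing import square_wave

        h = 1e-4
        for _ in range(20):
            p = random_params_m1(rng, moderate=True)
            T = float(rng.choice([0.5, 1.0, 2.0]))  # switches land on multiples of h
            spec = ForcingSpec(kind="square", sigma=p.sigma, duty=0.5, period=T)
            t_end = 2.0
            traj = integrate("M1", p, spec, t_end=t_end)
            f = _make_rhs("M1", p)
            wave = square_wave(spec)
            ref = rk4_fixed_step(f, np.zeros(3), t_end, h, wave)
            ref_times = np.arange(len(ref)) * h
            for i, comp in enumerate(("R", "r", "C")):
                interp = np.interp(traj.times, ref_times, ref[:, i])
                assert np.max(np.abs(traj.component(comp) - interp)) <= 1e-5

    def test_positivity_under_random_forcing(self, rng):
        for _ in range(10):
            p = random_params_m1(rng)
            kind = rng.choice(["square", "sinusoid", "constant"])
            spec = (
                ForcingSpec(kind="constant", sigma=p.sigma * 0.5)
                if kind == "constant"
                else ForcingSpec(kind=str(kind), sigma=p.sigma, duty=0.5, period=1.0)
            )
            traj = integrate("M1", p, spec, t_end=5.0, solver=SolverSettings(rtol=1e-6, atol=1e-9, undershoot_tol=1e-8))
            assert traj.states.min() >= 0.0  # undershoot clamped, larger raises

    def test_m2_silenced_competitor_reproduces_m1(self, median_params_m1):
        m1 = median_params_m1
        p2 = ParamsM2(
            sigma=m1.sigma, gamma=m1.gamma,
            kappa_on_1=m1.kappa_on, kappa_off_1=m1.kappa_off,
            alpha_1=m1.alpha, beta_1=m1.beta,
            kappa_on_2=0.0, kappa_off_2=0.0, alpha_2=0.0, beta_2=0.0,
            delta=0.0, epsilon=1.0,
        )
        spec = ForcingSpec(kind="square", sigma=m1.sigma, duty=0.5, period=1.0)
        t1 = integrate("M1", m1, spec, t_end=4.0)
        t2 = integrate("M2", p2, spec, t_end=4.0)
        np.testing.assert_allclose(t2.component("R1"), t1.component("R"), atol=1e-8)
        np.testing.assert_allclose(t2.component("r"), t1.component("r"), atol=1e-8)
        np.testing.assert_allclose(t2.component("C1"), t1.component("C"), atol=1e-8)

    def test_high_frequency_approaches_constant(self, median_params_m1):
        """Closely spaced pulses mimic the dose-equivalent constant synthesis."""
        p = median_params_m1
        tau = equilibration_time("M1", p, p.sigma * 0.5)
        spec = ForcingSpec(kind="square", sigma=p.sigma, duty=0.5, period=tau / 100)
        pulsed = integrate("M1", p, spec, t_end=tau)
        const = integrate("M1", p, ForcingSpec(kind="constant", sigma=p.sigma * 0.5), t_end=tau)
        Rp = np.interp(const.times, pulsed.times, pulsed.component("R"))
        mask = const.times > tau / 10  # skip the earliest transient
        rel = np.abs(Rp[mask] - const.component("R")[mask]) / const.component("R")[mask]
        assert np.max(rel) <= 0.05


class TestEquilibrationTime:
    def test_analytic_linear_relaxation(self):
        p = ParamsM1(sigma=1, kappa_on=0, kappa_off=0, alpha=1, beta=1, gamma=1)
        tau = equilibration_time("M1", p, 1.0, rel_tol=0.01)
        assert tau == pytest.approx(-math.log(0.01), abs=0.01)
        tau5 = equilibration_time("M1", p, 1.0, rel_tol=0.05)
        assert tau5 == pytest.approx(-math.log(0.05), abs=0.01)

    def test_definitional_post_check(self, rng):
        p = random_params_m1(rng)
        sigma_const = p.sigma * 0.5
        tau = equilibration_time("M1", p, sigma_const, rel_tol=0.01)
        ss = steady_state_m1(p, sigma_const)[0]
        traj = integrate(
            "M1", p, ForcingSpec(kind="constant", sigma=sigma_const), t_end=2 * tau
        )
        after = traj.times >= tau
        dev = np.abs(traj.component("R")[after] - ss) / ss
        assert np.max(dev) <= 0.011  # within tolerance for all later samples

    def test_degenerate_start_rejected(self, median_params_m1):
        ss = steady_state_m1(median_params_m1, 1.0)
        with pytest.raises(DegenerateEquilibrationError):
            equilibration_time("M1", median_params_m1, 1.0, initial_state=ss)

    def test_bad_rel_tol(self, median_params_m1):
        with pytest.raises(ParameterError):
            equilibration_time("M1", median_params_m1, 1.0, rel_tol=0.5)
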