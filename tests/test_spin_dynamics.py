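"""Forward-model tests: generator structure, propagation, R1ρ extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from wclike import (
    DecayCurve,
    ExchangeModel,
    SpinLockCondition,
    build_bm_matrix,
    fast_exchange_rex,
    fit_monoexponential,
    initial_magnetization,
    r1rho_profile,
    r2eff_transform,
    simulate_decay,
    simulate_r1rho,
)
from wclike.exceptions import (
    ConfigurationError,
    DataError,
    DomainError,
    ValidationError,
)
from wclike.spin_dynamics import alignment_axis, exchange_generator


def random_model(rng, n_states):
    """Random valid exchange model for property tests."""
    pops = rng.dirichlet(np.r_[50.0, np.full(n_states - 1, 1.0)])
    states = ("GS", "ES1", "ES2")[:n_states]
    kex = {}
    for i in range(n_states):
        for j in range(i + 1, n_states):
            kex[(states[i], states[j])] = float(rng.uniform(100, 3e4))
    dw = {"N": {s: float(rng.uniform(-60, 60)) for s in states[1:]}}
    return ExchangeModel(states=states, populations=tuple(pops), kex=kex,
                         delta_omega=dw, r1=2.0, r2=16.0)


class TestExchangeModel:
    def test_population_and_rate_validation(self):
        with pytest.raises(ValidationError):
            ExchangeModel(states=("GS", "ES1"), populations=(0.9, 0.2))
        with pytest.raises(ValidationError):
            ExchangeModel(states=("GS", "ES1"), populations=(0.999, 0.001),
                          kex={("GS", "ES1"): -5.0})
        with pytest.raises(ValidationError):
            ExchangeModel(states=("GS", "ES1"), populations=(0.999, 0.001),
                          delta_omega={"N": {"GS": 3.0}})

    def test_two_state_subrates_match_printed_parameters(self, two_state_model):
        """k_f = p_ES·k_ex ≈ 5.98 1/s and k_b = p_GS·k_ex ≈ 7194 1/s."""
        kf = two_state_model.rate("GS", "ES1")
        kb = two_state_model.rate("ES1", "GS")
        assert kf == pytest.approx(0.00083 * 7200.0, rel=1e-12)
        assert kb == pytest.approx((1 - 0.00083) * 7200.0, rel=1e-12)
        assert kf + kb == pytest.approx(7200.0, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 3))
    def test_detailed_balance_by_construction(self, seed, n_states):
        m = random_model(np.random.default_rng(seed), n_states)
        for i, si in enumerate(m.states):
            for sj in m.states[i + 1:]:
                lhs = m.population(si) * m.rate(si, sj)
                rhs = m.population(sj) * m.rate(sj, si)
                assert lhs == pytest.approx(rhs, abs=1e-12 * max(lhs, 1.0))

    def test_missing_delta_omega_is_configuration_error(self, two_state_model, cond):
        with pytest.raises(ConfigurationError):
            build_bm_matrix(two_state_model, cond, "C-H6")


class TestGenerator:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 3))
    def test_exchange_conserves_magnetization_per_axis(self, seed, n_states):
        """Pure-exchange column sums vanish on each x/y/z sub-block."""
        m = random_model(np.random.default_rng(seed), n_states)
        L = exchange_generator(m)
        assert np.allclose(L.sum(axis=0), 0.0, atol=1e-9)
        cond = SpinLockCondition(1000.0, 500.0)
        A = build_bm_matrix(m, cond, "N")
        relax_free = A - build_bm_matrix(
            ExchangeModel(states=m.states, populations=m.populations,
                          delta_omega=m.delta_omega, r1=m.r1, r2=m.r2),
            cond, "N")
        n = m.n_states
        # per-axis blocks: exchange couples identical components across states
        for axis in range(3):
            block = np.array([[relax_free[3 * i + axis, 3 * j + axis]
                               for j in range(n)] for i in range(n)])
            assert np.allclose(block.sum(axis=0), 0.0, atol=1e-9)

    def test_no_exchange_reduces_to_single_state_r1rho(self, cond):
        """All Δω = 0 collapses to R1ρ = R1·cos²θ + R2·sin²θ."""
        m = ExchangeModel(states=("GS", "ES1"), populations=(0.999, 0.001),
                          kex={("GS", "ES1"): 5000.0},
                          delta_omega={"N": {"ES1": 0.0}}, r1=2.0, r2=16.0)
        expected = 2.0 * math.cos(cond.theta) ** 2 + 16.0 * math.sin(cond.theta) ** 2
        assert simulate_r1rho(m, cond, "N") == pytest.approx(expected, rel=1e-4)

    def test_tilt_angle_in_open_interval(self):
        for off in (-5000.0, 0.0, 5000.0):
            c = SpinLockCondition(400.0, off)
            assert 0.0 < c.theta < math.pi


class TestInitialMagnetization:
    def test_single_state_unit_vector(self, cond):
        m = ExchangeModel(states=("GS",), populations=(1.0,), r1=2.0, r2=16.0)
        v = initial_magnetization(m, cond, "N")
        th = cond.theta
        assert np.allclose(v, [math.sin(th), 0.0, math.cos(th)], atol=1e-12)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_gs_component_carries_population_fraction(self, two_state_model, cond):
        v = initial_magnetization(two_state_model, cond, "G-N1")
        gs_mag = np.linalg.norm(v[:3])
        assert gs_mag == pytest.approx(1 - 0.00083, rel=1e-9)

    def test_fast_exchange_aligns_with_average_field(self):
        """k_ex/|Δω| → large flips the alignment to the population average."""
        p = 0.05
        mk = lambda kex: ExchangeModel(
            states=("GS", "ES1"), populations=(1 - p, p),
            kex={("GS", "ES1"): kex}, delta_omega={"N": {"ES1": 4.0}},
            r1=2.0, r2=16.0)
        cond = SpinLockCondition(1000.0, 300.0)
        dw_rad = 4.0 * 2 * math.pi * cond.larmor_mhz
        slow = alignment_axis(mk(0.1 * dw_rad), cond, "N")
        fast = alignment_axis(mk(100 * dw_rad), cond, "N")
        th_gs = math.atan2(cond.omega1, cond.omega_gs)
        th_avg = math.atan2(cond.omega1, cond.omega_gs + p * dw_rad)
        assert slow[0] == pytest.approx(math.sin(th_gs), abs=1e-12)
        assert fast[0] == pytest.approx(math.sin(th_avg), abs=1e-12)
        assert not np.allclose(slow, fast)


class TestPropagation:
    def test_initial_intensity_is_total_magnitude(self, two_state_model, cond):
        curve = simulate_decay(two_state_model, cond, "G-N1")
        assert curve.delays[0] == 0.0
        assert curve.intensities[0] == pytest.approx(1.0, rel=1e-12)

    def test_no_exchange_closed_form_decay(self, cond):
        m = ExchangeModel(states=("GS",), populations=(1.0,), r1=2.0, r2=16.0)
        curve = simulate_decay(m, cond, "N")
        rate = 2.0 * math.cos(cond.theta) ** 2 + 16.0 * math.sin(cond.theta) ** 2
        # exact up to the small non-secular R1/R2 mixing
        assert np.allclose(curve.intensities,
                           np.exp(-rate * curve.delays), rtol=5e-4)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 3))
    def test_matrix_exponential_matches_integration_oracle(self, seed, n_states):
        """expm propagation ≡ adaptive-step ODE integration to 1e-8 relative."""
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_states)
        cond = SpinLockCondition(float(rng.uniform(400, 2000)),
                                 float(rng.uniform(-3000, 3000)),
                                 delays=(0.0, 0.03, 0.09))
        curve = simulate_decay(m, cond, "N")
        A = build_bm_matrix(m, cond, "N")
        m0 = initial_magnetization(m, cond, "N")
        proj = np.tile(alignment_axis(m, cond, "N"), m.n_states)
        sol = solve_ivp(lambda t, y: A @ y, (0.0, max(cond.delays)), m0,
                        t_eval=cond.delays, rtol=1e-11, atol=1e-13)
        oracle = proj @ sol.y
        assert np.allclose(curve.intensities, oracle, rtol=1e-8, atol=1e-10)

    def test_profile_matches_scalar_simulation(self, two_state_model):
        conds = [SpinLockCondition(pw, off)
                 for pw in (400.0, 1200.0) for off in (-900.0, 0.0, 1500.0)]
        vec = r1rho_profile(two_state_model, conds, "G-N1")
        scal = [simulate_r1rho(two_state_model, c, "G-N1") for c in conds]
        assert np.allclose(vec, scal, rtol=1e-10)


class TestMonoexponentialFit:
    def test_exact_noiseless_rate(self):
        t = np.array([0.0, 0.04, 0.08, 0.12])
        curve = DecayCurve(t, 10.0 * np.exp(-25.0 * t), noise_sd=0.0)
        rate, sd = fit_monoexponential(curve)
        assert rate == pytest.approx(25.0, rel=1e-10)
        assert sd <= 1e-8

    def test_two_points_give_inverse_delay(self):
        t = 0.05
        curve = DecayCurve([0.0, t], [3.0, 3.0 / math.e], noise_sd=0.0)
        rate, _ = fit_monoexponential(curve)
        assert rate == pytest.approx(1.0 / t, rel=1e-10)

    def test_monte_carlo_sd_scales_with_noise(self, rng):
        t = np.array([0.0, 0.04, 0.08, 0.12])
        I = np.exp(-20.0 * t)
        sds = []
        for noise in (0.01, 0.02):
            curve = DecayCurve(t, I, noise_sd=noise)
            _, sd = fit_monoexponential(curve, mc_iterations=2000, rng=rng)
            sds.append(sd)
        assert sds[1] == pytest.approx(2 * sds[0], rel=0.15)

    def test_rejects_bad_input(self):
        with pytest.raises(DataError):
            fit_monoexponential(DecayCurve([0.0, 0.0], [1.0, 1.0]))
        with pytest.raises(DataError):
            fit_monoexponential(DecayCurve([0.0, 0.1], [1.0, -0.5]))


class TestR2effTransform:
    def test_on_resonance_identity(self):
        assert r2eff_transform(20.0, 2.0, math.pi / 2) == pytest.approx(20.0)

    def test_arithmetic_example(self):
        assert r2eff_transform(20.0, 2.0, math.pi / 3) == pytest.approx(26.0)

    def test_error_propagation_linear_map(self):
        v, sd = r2eff_transform(20.0, 2.0, math.pi / 3, r1rho_sd=0.3)
        assert sd == pytest.approx(0.3 / math.sin(math.pi / 3) ** 2)

    def test_domain_error_on_z_axis(self):
        with pytest.raises(DomainError):
            r2eff_transform(20.0, 2.0, 0.0)

    def test_no_exchange_profile_is_flat(self):
        """End-to-end: zero Δω gives R2+Rex = R2 at every offset."""
        m = ExchangeModel(states=("GS", "ES1"), populations=(0.999, 0.001),
                          kex={("GS", "ES1"): 5000.0},
                          delta_omega={"N": {"ES1": 0.0}}, r1=2.0, r2=16.0)
        for off in (-2800.0, -700.0, 0.0, 1400.0):
            c = SpinLockCondition(800.0, off)
            r = simulate_r1rho(m, c, "N")
            assert r2eff_transform(r, 2.0, c.theta) == pytest.approx(16.0, rel=2e-3)


class TestDispersionShape:
    def test_r2eff_decreases_with_spin_lock_power_on_resonance(self, two_state_model):
        vals = []
        for pw in (400.0, 800.0, 1200.0, 1600.0, 2000.0):
            c = SpinLockCondition(pw, 0.0)
            r = simulate_r1rho(two_state_model, c, "G-N1")
            vals.append(r2eff_transform(r, two_state_model.r1, c.theta))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_slow_exchange_peak_sits_at_minus_delta_omega(self, two_state_model):
        """k_ex ≪ |Δω|: the dispersion maximum is at a carrier offset ≈ −Δω."""
        c0 = SpinLockCondition(400.0, 0.0)
        offs = np.linspace(-3.5 * 1000, 3.5 * 1000, 281)
        conds = [SpinLockCondition(1000.0, float(o)) for o in offs]
        prof = r1rho_profile(two_state_model, conds, "G-N1")
        r2eff = [r2eff_transform(r, two_state_model.r1, c.theta)
                 for r, c in zip(prof, conds)]
        peak = offs[int(np.argmax(r2eff))]
        expected = -34.9 * c0.larmor_mhz  # ppm -> Hz
        assert peak == pytest.approx(expected, abs=100.0)

    def test_fast_exchange_closed_form_within_5_percent(self):
        """BM simulation at k_ex/|Δω| = 20 matches the Lorentzian Rex form.

        The closed form carries no relaxation asymmetry, so the oracle model
        uses R1 = R2 to isolate the exchange term it does describe; the
        genuine (R2−R1) off-resonance cross-term is checked separately below.
        """
        pes, dw_ppm = 0.002, 8.0
        dw_rad = dw_ppm * 2 * math.pi * 70.95
        kex = 20.0 * dw_rad
        m = ExchangeModel(states=("GS", "ES1"), populations=(1 - pes, pes),
                          kex={("GS", "ES1"): kex},
                          delta_omega={"N": {"ES1": dw_ppm}}, r1=10.0, r2=10.0)
        for pw in (800.0, 1500.0):
            for off in np.linspace(-1.5 * pw, 1.5 * pw, 7):
                c = SpinLockCondition(pw, float(off))
                rex_num = r2eff_transform(simulate_r1rho(m, c, "N"), 10.0, c.theta) - 10.0
                omega_avg = c.omega_gs + pes * dw_rad
                omega_eff = math.hypot(c.omega1, omega_avg)
                rex_cf = fast_exchange_rex(1 - pes, pes, dw_rad, kex, omega_eff)
                assert rex_num == pytest.approx(rex_cf, rel=0.05)

    def test_fast_exchange_closed_form_on_resonance_realistic_relaxation(self):
        """With R1 ≠ R2 the on-resonance agreement still holds (odd term vanishes)."""
        pes, dw_ppm = 0.002, 8.0
        dw_rad = dw_ppm * 2 * math.pi * 70.95
        kex = 20.0 * dw_rad
        m = ExchangeModel(states=("GS", "ES1"), populations=(1 - pes, pes),
                          kex={("GS", "ES1"): kex},
                          delta_omega={"N": {"ES1": dw_ppm}}, r1=2.0, r2=16.0)
        for pw in (800.0, 1500.0):
            c = SpinLockCondition(pw, 0.0)
            rex_num = r2eff_transform(simulate_r1rho(m, c, "N"), 2.0, c.theta) - 16.0
            omega_eff = math.hypot(c.omega1, c.omega_gs + pes * dw_rad)
            rex_cf = fast_exchange_rex(1 - pes, pes, dw_rad, kex, omega_eff)
            assert rex_num == pytest.approx(rex_cf, rel=0.05)

    def test_fast_exchange_rex_vanishes_without_contrast(self):
        assert fast_exchange_rex(0.999, 0.001, 0.0, 1e4, 5e3) == 0.0
        assert fast_exchange_rex(1.0, 0.0, 900.0, 1e4, 5e3) == 0.0
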