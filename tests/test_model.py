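"""ODE right-hand side, closed form, volume mapping and constraints."""

import numpy as np
import pytest

from csclineage import (
    CELLS_PER_MM3,
    PopulationState,
    RateConstants,
    asymptotic_fractions,
    check_constraints,
    closed_form,
    closed_form_series,
    derivatives,
    growth_exponents,
    phi_to_rates,
    REPORTED_PHI,
    volume_mm3,
)

from conftest import random_rates, random_state, rk_oracle


def ledger_derivatives(state, k):
    """Independent oracle: assemble each derivative reaction-by-reaction as
    production - consumption by division - death, instead of using the
    simplified coefficients."""
    csc, p, d = state.csc, state.p, state.d
    # CSC ledger: R1 produces 2, consumes 1; R2 produces 1, consumes 1; R3 consumes 1
    dcsc = (2 * k.k1 * csc + k.k2 * csc) - (k.k1 * csc + k.k2 * csc + k.k3 * csc) - k.k6 * csc
    # P ledger: R2 produces 1; R3 produces 2; R4 produces 2, consumes 1; R5 consumes 1
    dp = (k.k2 * csc + 2 * k.k3 * csc + 2 * k.k4 * p) - (k.k4 * p + k.k5 * p) - k.k7 * p
    # D ledger: R5 produces 2; death by R8
    dd = 2 * k.k5 * p - k.k8 * d
    return dcsc, dp, dd


class TestDerivatives:
    def test_pure_csc_inoculum(self, reported_k):
        got = derivatives(PopulationState(0, 100, 0, 0), reported_k)
        assert got == pytest.approx((98.0, 102.0, 0.0))

    def test_empty_tumor_is_fixed_point(self, reported_k):
        assert derivatives(PopulationState(0, 0, 0, 0), reported_k) == (0, 0, 0)

    def test_progenitor_driven_state(self, reported_k):
        got = derivatives(PopulationState(0, 0, 50, 10), reported_k)
        assert got == pytest.approx((0.0, 48.5, 418.0))

    def test_matches_reaction_ledger_on_random_states(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = random_rates(rng)
            state = random_state(rng)
            assert derivatives(state, k) == pytest.approx(
                ledger_derivatives(state, k), rel=1e-12
            )


class TestClosedForm:
    def test_decoupled_compartments_are_pure_exponentials(self):
        k = RateConstants(k1=0.5, k2=0, k3=0, k4=1.2, k5=0, k6=0.1, k7=0.3, k8=0.7)
        init = PopulationState(0, 100, 200, 300)
        a, b, c = growth_exponents(k)
        out = closed_form(k, init, 2.0)
        assert out.csc == pytest.approx(100 * np.exp(2 * a), rel=1e-12)
        assert out.p == pytest.approx(200 * np.exp(2 * b), rel=1e-12)
        assert out.d == pytest.approx(300 * np.exp(2 * c), rel=1e-12)

    def test_matches_runge_kutta_oracle_on_reported_parameters(self, reported_k):
        init = PopulationState(0, 100, 0, 0)
        expected = rk_oracle(reported_k, init, 1.0)
        got = closed_form(reported_k, init, 1.0).as_array()
        assert got == pytest.approx(expected, rel=1e-8)

    def test_matches_oracle_on_random_parameter_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = random_rates(rng)
            init = random_state(rng)
            horizon = 20.0 / k.k1
            expected = rk_oracle(k, init, horizon)
            got = closed_form(k, init, horizon).as_array()
            scale = max(expected.sum(), 1.0)
            assert np.all(np.abs(got - expected) / scale <= 1e-8)

    def test_confluent_exponents_finite(self):
        # a == b exactly: k1 - k3 - k6 = k4 - k5 - k7 = 0.5
        k = RateConstants(k1=0.7, k2=1.0, k3=0.1, k4=2.0, k5=1.2, k6=0.1, k7=0.3, k8=0.4)
        a, b, _ = growth_exponents(k)
        assert a == pytest.approx(b)
        init = PopulationState(0, 50, 10, 5)
        out = closed_form(k, init, 3.0).as_array()
        assert np.all(np.isfinite(out))
        assert out == pytest.approx(rk_oracle(k, init, 3.0), rel=1e-8)

    def test_triple_confluence_finite(self):
        # a == b == c: all exponents equal -0.2
        k = RateConstants(k1=0.1, k2=0.5, k3=0.1, k4=1.0, k5=0.8, k6=0.2, k7=0.4, k8=0.2)
        a, b, c = growth_exponents(k)
        assert a == pytest.approx(b) and b == pytest.approx(c)
        init = PopulationState(0, 50, 10, 5)
        out = closed_form(k, init, 5.0).as_array()
        assert np.all(np.isfinite(out))
        assert out == pytest.approx(rk_oracle(k, init, 5.0), rel=1e-8)

    def test_long_horizon_log_slope_is_dominant_exponent(self, reported_k):
        init = PopulationState(0, 100, 0, 0)
        times = np.array([500.0, 501.0])
        csc, p, d = closed_form_series(reported_k, init, times)
        n = csc + p + d
        slope = np.log(n[1] / n[0])
        assert slope == pytest.approx(0.98, rel=1e-4)


class TestVolume:
    def test_density_definition(self):
        assert volume_mm3(3.2e5) == 1.0
        assert volume_mm3(0.0) == 0.0

    def test_ten_doublings_give_1024_mm3(self):
        assert volume_mm3(3.2e5 * 2**10) == 1024.0

    def test_linearity_and_custom_density(self):
        rng = np.random.default_rng(3)
        n = rng.uniform(0, 1e9)
        alpha = rng.uniform(0.1, 7.0)
        assert volume_mm3(alpha * n) == pytest.approx(alpha * volume_mm3(n))
        assert volume_mm3(2e5, density=1e5) == pytest.approx(2.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            volume_mm3(-1.0)


class TestAsymptoticFractions:
    def test_reported_parameters(self, reported_k):
        mode = asymptotic_fractions(reported_k)
        assert mode.dominant == "csc"
        # dominant-eigenvector values: P/CSC = 1.02/0.01, D/P = 8.56/1.98
        assert mode.f_csc == pytest.approx(0.0018383, rel=1e-3)
        assert mode.f_p == pytest.approx(0.18751, rel=1e-3)
        assert mode.f_d == pytest.approx(0.81065, rel=1e-3)

    def test_disconnected_lineage_is_pure_csc(self):
        k = RateConstants(k1=1.0, k2=0, k3=0, k4=0.5, k5=0.2, k6=0.05, k7=0.1, k8=0.3)
        mode = asymptotic_fractions(k)
        assert mode.f_csc == 1.0

    def test_fractions_sum_to_one_and_rescale_invariant(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            k = random_rates(rng)
            mode = asymptotic_fractions(k)
            assert mode.f_csc + mode.f_p + mode.f_d == pytest.approx(1.0, abs=1e-12)
            scaled = asymptotic_fractions(k.scaled(rng.uniform(0.1, 10.0)))
            assert scaled.as_array() == pytest.approx(mode.as_array(), rel=1e-12)
            assert scaled.dominant == mode.dominant

    def test_progenitor_dominant_regime_flagged(self):
        # fast progenitor renewal outpaces the CSC mode: CSC fraction -> 0
        k = phi_to_rates(REPORTED_PHI.replace(phi_5_4=0.1), 1.0)
        mode = asymptotic_fractions(k)
        assert mode.dominant == "p"
        assert mode.f_csc == 0.0


class TestConstraints:
    def test_reported_parameters_pass_all_five(self, reported_k):
        report = check_constraints(reported_k)
        assert report.passed
        assert report.stationarity_residual <= 1e-12

    def test_death_rate_boundary_is_strict(self, reported_k):
        report = check_constraints(reported_k.replace(k6=reported_k.k7))
        assert not report.death_csc_below_p
        assert not report.passed

    def test_weak_differentiation_fails_bulk_constraints(self):
        report = check_constraints(phi_to_rates(REPORTED_PHI.replace(phi_5_4=0.1), 1.0))
        assert not report.differentiated_fraction_bounded
        assert not report.progenitor_fraction_bounded
        assert not report.passed
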