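"""Treatment-schedule integration engine."""

import numpy as np
import pytest

from csclineage import (
    KillEvent,
    PopulationState,
    RateModifier,
    Trajectory,
    TreatmentSchedule,
    apply_kill,
    closed_form_series,
    growth_delay,
    integrate_to_equilibrium,
    asymptotic_fractions,
    relapse_time,
    simulate,
    phi_to_rates,
    REPORTED_PHI,
)

from conftest import random_rates, random_state


class TestScheduleTypes:
    def test_modifier_validation(self):
        with pytest.raises(ValueError):
            RateModifier("k9", 0, 10, factor=2.0)
        with pytest.raises(ValueError):
            RateModifier("k6", 10, 10, factor=2.0)
        with pytest.raises(ValueError):
            RateModifier("k6", 0, 10)  # neither factor nor replace
        with pytest.raises(ValueError):
            RateModifier("k6", 0, 10, factor=2.0, replace=1.0)

    def test_window_is_half_open(self, reported_k):
        sched = TreatmentSchedule(modifiers=(RateModifier("k6", 5.0, 10.0, factor=100.0),))
        assert sched.rates_at(5.0, reported_k).k6 == 1.0
        assert sched.rates_at(9.999, reported_k).k6 == 1.0
        assert sched.rates_at(10.0, reported_k).k6 == 0.01
        assert sched.rates_at(4.999, reported_k).k6 == 0.01

    def test_overlapping_factors_compose_multiplicatively(self, reported_k):
        sched = TreatmentSchedule(
            modifiers=(
                RateModifier("k6", 0.0, 10.0, factor=100.0),
                RateModifier("k6", 5.0, 15.0, factor=2.0),
            )
        )
        assert sched.rates_at(7.0, reported_k).k6 == pytest.approx(0.01 * 200)
        assert sched.rates_at(2.0, reported_k).k6 == pytest.approx(1.0)
        assert sched.rates_at(12.0, reported_k).k6 == pytest.approx(0.02)

    def test_replacement_semantics(self, reported_k):
        sched = TreatmentSchedule(modifiers=(RateModifier("k1", 0.0, 5.0, replace=0.0),))
        assert sched.rates_at(1.0, reported_k).k1 == 0.0

    def test_duplicate_event_times_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSchedule(events=(KillEvent(5, 0.5, 0.5, 0.5), KillEvent(5, 0.1, 0, 0)))


class TestApplyKill:
    def test_bulk_99_percent(self):
        out = apply_kill(PopulationState(0, 100, 200, 700), (0.99, 0.99, 0.99))
        assert (out.csc, out.p, out.d) == pytest.approx((1.0, 2.0, 7.0))

    def test_identity(self):
        s = PopulationState(0, 10, 20, 30)
        out = apply_kill(s, (0, 0, 0))
        assert (out.csc, out.p, out.d) == (s.csc, s.p, s.d)

    def test_sparing_cscs(self):
        out = apply_kill(PopulationState(0, 100, 200, 700), (0.0, 0.99, 0.99))
        assert (out.csc, out.p, out.d) == pytest.approx((100.0, 2.0, 7.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_kill(PopulationState(0, 1, 1, 1), (1.5, 0, 0))


class TestSimulate:
    def test_empty_schedule_matches_closed_form(self, reported_k):
        init = PopulationState(0, 600, 1000, 5000)
        traj = simulate(reported_k, init, t_end=15.0)
        csc, p, d = closed_form_series(reported_k, init, traj.times)
        n_ref = csc + p + d
        assert np.max(np.abs(traj.n - n_ref) / n_ref) <= 1e-8

    def test_empty_schedule_matches_closed_form_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = random_rates(rng)
            init = random_state(rng)
            traj = simulate(k, init, t_end=10.0 / k.k1)
            csc, p, d = closed_form_series(k, init, traj.times)
            scale = np.maximum(csc + p + d, 1e-12)
            assert np.max(np.abs(traj.n - (csc + p + d)) / scale) <= 1e-8

    def test_kill_event_drops_volume_and_preserves_fractions(self, reported_k):
        k = phi_to_rates(REPORTED_PHI, 0.1)
        init = PopulationState(0, 100, 10200, 44000)
        sched = TreatmentSchedule(events=(KillEvent(20.0, 0.99, 0.99, 0.99),))
        traj = simulate(k, init, sched, t_end=40.0)
        i = np.searchsorted(traj.times, 20.0)
        csc, p, d = closed_form_series(k, init, np.array([20.0]))
        pre = np.array([csc[0], p[0], d[0]])
        assert traj.n[i] == pytest.approx(0.01 * pre.sum(), rel=1e-6)
        assert traj.frac_csc[i] == pytest.approx(pre[0] / pre.sum(), rel=1e-6)
        assert traj.frac_p[i] == pytest.approx(pre[1] / pre.sum(), rel=1e-6)

    def test_kill_commutes_with_integration_restart(self, reported_k):
        init = PopulationState(0, 500, 2000, 9000)
        sched = TreatmentSchedule(events=(KillEvent(5.0, 0.9, 0.5, 0.2),))
        combined = simulate(reported_k, init, sched, t_end=10.0)
        first = simulate(reported_k, init, t_end=5.0)
        mid = apply_kill(first.state_at(-1), (0.9, 0.5, 0.2))
        second = simulate(reported_k, mid, t_end=10.0)
        i = np.searchsorted(combined.times, 5.0)
        np.testing.assert_allclose(combined.csc[i:], second.csc, rtol=1e-9)
        np.testing.assert_allclose(combined.d[i:], second.d, rtol=1e-9)

    def test_modifier_changes_only_window(self, reported_k):
        init = PopulationState(0, 1000, 0, 0)
        sched = TreatmentSchedule(modifiers=(RateModifier("k6", 2.0, 4.0, factor=100.0),))
        traj = simulate(reported_k, init, sched, t_end=6.0)
        ref = simulate(reported_k, init, t_end=6.0)
        i2 = np.searchsorted(traj.times, 2.0)
        np.testing.assert_allclose(traj.csc[: i2 + 1], ref.csc[: i2 + 1], rtol=1e-8)
        assert traj.csc[-1] < ref.csc[-1]

    def test_extinction_threshold_zeroes_residual_cells(self):
        k = phi_to_rates(REPORTED_PHI, 0.07)
        init = PopulationState(0, 1e4, 0, 0)
        sched = TreatmentSchedule(modifiers=(RateModifier("k6", 10.0, 200.0, factor=2000.0),))
        traj = simulate(k, init, sched, t_end=250.0, extinction_threshold=1.0)
        assert traj.csc[-1] == 0.0
        ref = simulate(k, init, sched, t_end=250.0)
        assert ref.csc[-1] > 0.0

    def test_trajectory_invariants(self, reported_k):
        traj = simulate(reported_k, PopulationState(0, 100, 200, 700), t_end=8.0)
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.csc >= 0) and np.all(traj.p >= 0) and np.all(traj.d >= 0)
        ok = traj.n > 0
        assert np.all((traj.frac_csc[ok] >= 0) & (traj.frac_csc[ok] <= 1))

    def test_trajectory_csv_round_trip(self, reported_k, tmp_path):
        traj = simulate(reported_k, PopulationState(0, 100, 200, 700), t_end=5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.read_csv(path)
        np.testing.assert_allclose(back.n, traj.n, rtol=1e-12)
        np.testing.assert_allclose(back.volume, traj.volume, rtol=1e-12)


class TestRelapseAndDelay:
    def test_untreated_trajectory_returns_none_with_warning(self, reported_k):
        traj = simulate(reported_k, PopulationState(0, 100, 0, 0), t_end=10.0)
        with pytest.warns(UserWarning):
            assert relapse_time(traj) is None

    def test_regrowth_crossing_matches_closed_form_time(self):
        # 99% bulk kill of a pure exponential: volume regains its reference
        # after log(100)/a days
        k = phi_to_rates(REPORTED_PHI, 0.1)
        mode = asymptotic_fractions(k)
        n0 = 1e7
        init = PopulationState(0, n0 * mode.f_csc, n0 * mode.f_p, n0 * mode.f_d)
        sched = TreatmentSchedule(events=(KillEvent(30.0, 0.99, 0.99, 0.99),))
        traj = simulate(k, init, sched, t_end=150.0, grid_step=0.1)
        expected = 30.0 + np.log(100.0) / 0.098
        got = relapse_time(traj)
        assert got == pytest.approx(expected, abs=0.2)

    def test_eradication_returns_none(self):
        k = phi_to_rates(REPORTED_PHI, 0.1)
        init = PopulationState(0, 100, 2000, 10000)
        sched = TreatmentSchedule(events=(KillEvent(10.0, 1.0, 1.0, 0.5),))
        traj = simulate(k, init, sched, t_end=100.0)
        assert relapse_time(traj) is None

    def test_growth_delay_identity_and_shift(self, reported_k):
        init = PopulationState(0, 100, 0, 0)
        traj = simulate(reported_k, init, t_end=12.0)
        assert growth_delay(traj, traj, traj.volume[5]) == 0.0
        shifted = Trajectory(
            times=traj.times + 3.0, csc=traj.csc, p=traj.p, d=traj.d,
        )
        delay = growth_delay(shifted, traj, float(traj.volume[len(traj.times) // 2]))
        assert delay == pytest.approx(3.0, abs=1e-6)

    def test_delay_monotone_in_kill_fraction(self, colon_base):
        k, init, control = colon_base
        vref = float(np.interp(120.0, control.times, control.volume))
        delays = []
        for f in (0.95, 0.99, 0.999, 0.9999):
            sched = TreatmentSchedule(events=(KillEvent(120.0, f, f, f),))
            traj = simulate(k, init, sched, t_end=420.0)
            delays.append(growth_delay(traj, control, vref))
        assert all(d is not None for d in delays)
        assert np.all(np.diff(delays) > 0)

    def test_never_crossing_returns_none(self, reported_k):
        init = PopulationState(0, 100, 0, 0)
        traj = simulate(reported_k, init, t_end=5.0)
        assert growth_delay(traj, traj, 1e12) is None


class TestEquilibriumIntegration:
    def test_matches_analytic_dominant_mode(self, reported_k):
        f = integrate_to_equilibrium(reported_k)
        mode = asymptotic_fractions(reported_k)
        assert np.asarray(f) == pytest.approx(mode.as_array(), abs=1e-9)

    def test_permanent_combo_therapy_extinguishes_tumor(self):
        # CSC renewal cut 1000-fold and P death raised 100-fold, held
        # forever: both proliferative exponents turn negative and the
        # tumor volume decays toward zero
        k = phi_to_rates(REPORTED_PHI, 0.1)
        treated = k.replace(k1=k.k1 / 1000.0, k7=k.k7 * 100.0)
        a = treated.k1 - treated.k3 - treated.k6
        b = treated.k4 - treated.k5 - treated.k7
        assert a < 0 and b < 0
        # CSC decay is slow (|a| ~ 0.002/day) so the horizon is long
        init = PopulationState(0, 1e4, 1e6, 4e6)
        traj = simulate(treated, init, t_end=1500.0, grid_step=2.0)
        assert traj.volume[-1] < 1e-3 * traj.volume[0]
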