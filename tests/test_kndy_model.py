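"""Unit and property tests for the KNDy relaxation-oscillator core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepdsim.kndy_model import (
    ArcInput,
    KndyParams,
    KndyState,
    PULSATILE,
    QUIESCENT_HIGH,
    SILENT,
    Trajectory,
    find_fixed_point,
    kndy_derivatives,
    pulse_times_from_activity,
    scan_input,
    simulate,
)


def measured_period(traj: Trajectory, settle: float = 120.0) -> float:
    mask = traj.times >= settle
    sub = Trajectory(times=traj.times[mask], states=traj.states[mask],
                     columns=traj.columns)
    events = pulse_times_from_activity(sub)
    assert len(events) >= 3, "need several cycles to measure a period"
    return float(np.diff(events.times).mean())


class TestDerivatives:
    def test_all_sources_off_origin_is_stationary(self):
        p = KndyParams(k_D=0.0, k_N=0.0, k_N0=0.0, I0=0.0)
        d = kndy_derivatives(KndyState(0, 0, 0), p, ArcInput(0, 0))
        assert d.as_array() == pytest.approx(np.zeros(3), abs=0.0)

    def test_vanishes_at_independently_located_fixed_point(self, kndy_params):
        # silent fixed point under strong inhibition, found by root finding
        inp = ArcInput(I_exc=0.0, I_inh=0.8)
        fp = find_fixed_point(kndy_params, inp)
        assert fp is not None
        d = kndy_derivatives(fp, kndy_params, inp).as_array()
        assert np.max(np.abs(d)) < 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        D=st.floats(0, 1.5), N=st.floats(0, 1.5), v=st.floats(0, 1),
        a=st.floats(0, 1), b=st.floats(0, 1), delta=st.floats(1e-6, 1),
    )
    def test_dv_dt_monotone_in_input_channels(self, D, N, v, a, b, delta):
        p = KndyParams()
        s = KndyState(D, N, v)
        base = kndy_derivatives(s, p, ArcInput(a, b)).v
        assert kndy_derivatives(s, p, ArcInput(a + delta, b)).v >= base
        assert kndy_derivatives(s, p, ArcInput(a, b + delta)).v <= base

    def test_rejects_non_finite_state(self):
        with pytest.raises(ValueError, match="D"):
            KndyState(float("nan"), 0.0, 0.0)
        with pytest.raises(ValueError, match="tau_D"):
            KndyParams(tau_D=float("inf"))


class TestSimulate:
    def test_deterministic_and_grid_covers_span(self, kndy_params):
        t1 = simulate(kndy_params, ArcInput(), (0, 50), dt_out=0.1)
        t2 = simulate(kndy_params, ArcInput(), (0, 50), dt_out=0.1)
        assert np.array_equal(t1.states, t2.states)
        assert t1.times[0] == 0.0 and t1.times[-1] == pytest.approx(50.0)
        assert np.allclose(np.diff(t1.times), 0.1)

    def test_strong_inhibition_silences_firing(self, kndy_params):
        traj = simulate(kndy_params, ArcInput(I_inh=2.0), (0, 200))
        assert traj.v[traj.times > 100].max() < 0.01
        assert len(pulse_times_from_activity(traj, 0.5)) == 0

    def test_period_matches_long_run_oracle(self, kndy_params):
        # oracle: peak-interval measurement on a 10x longer, finer run
        short = simulate(kndy_params, ArcInput(), (0, 300), dt_out=0.1)
        long = simulate(kndy_params, ArcInput(), (0, 3000), dt_out=0.01,
                        tol=1e-8)
        p_short = measured_period(short)
        p_long = measured_period(long, settle=300.0)
        assert p_short == pytest.approx(p_long, rel=0.02)

    def test_default_params_oscillate_at_zero_input_in_ultradian_range(
            self, kndy_params):
        traj = simulate(kndy_params, ArcInput(), (0, 400), dt_out=0.1)
        period = measured_period(traj)
        assert 15.0 <= period <= 35.0

    def test_tolerance_convergence(self, kndy_params):
        y0 = KndyState(0.2, 0.1, 0.1)
        a = simulate(kndy_params, ArcInput(), (0, 150), tol=1e-8, y0=y0)
        b = simulate(kndy_params, ArcInput(), (0, 150), tol=5e-9, y0=y0)
        assert np.max(np.abs(a.v - b.v)) / kndy_params.v_max < 1e-4

    def test_period_converges_with_tolerance(self, kndy_params):
        a = simulate(kndy_params, ArcInput(), (0, 500), tol=1e-6)
        b = simulate(kndy_params, ArcInput(), (0, 500), tol=5e-7)
        assert measured_period(a) == pytest.approx(measured_period(b),
                                                   rel=0.005)

    def test_finite_difference_matches_derivatives(self, kndy_params):
        # trajectory points from a tight-tolerance solve; centred secants
        # at scattered times must converge to the analytic vector field
        traj = simulate(kndy_params, ArcInput(), (0, 200), dt_out=0.001,
                        tol=1e-10)
        rng = np.random.default_rng(7)
        idx = rng.integers(1000, len(traj.times) - 1000, size=100)
        errors = {}
        for h_steps in (100, 10):  # h = 0.1 and 0.01 min
            errs = []
            for i in idx:
                fd = (traj.states[i + h_steps] - traj.states[i - h_steps]) \
                    / (2 * h_steps * 0.001)
                d = kndy_derivatives(
                    KndyState.from_array(traj.states[i]), kndy_params,
                    ArcInput()).as_array()
                errs.append(np.max(np.abs(fd - d)))
            errors[h_steps] = np.median(errs)
        assert errors[10] < errors[100]
        assert errors[10] < 1e-3

    def test_invalid_span_rejected(self, kndy_params):
        with pytest.raises(ValueError, match="ordered"):
            simulate(kndy_params, ArcInput(), (10, 10))


class TestPulseTimes:
    def test_constant_trajectory_has_no_events(self):
        traj = Trajectory(times=np.arange(100.0),
                          states=np.full((100, 3), 0.5))
        assert len(pulse_times_from_activity(traj)) == 0

    def test_synthetic_oscillation_with_known_period(self):
        t = np.arange(0, 100.01, 0.1)
        v = 0.5 + 0.5 * np.sin(2 * np.pi * (t - 5.0) / 25.0)
        states = np.column_stack([np.zeros_like(t), np.zeros_like(t), v])
        events = pulse_times_from_activity(
            Trajectory(times=t, states=states), 0.5)
        assert len(events) == 4  # upward crossings at 5, 30, 55, 80
        assert np.allclose(np.diff(events.times), 25.0, atol=0.2)

    def test_event_count_matches_cycle_count(self, kndy_params):
        traj = simulate(kndy_params, ArcInput(), (0, 400), dt_out=0.1)
        period = measured_period(traj)
        mask = traj.times >= 120
        sub = Trajectory(times=traj.times[mask], states=traj.states[mask])
        n = len(pulse_times_from_activity(sub))
        expected = (sub.times[-1] - sub.times[0]) / period
        assert abs(n - expected) <= 1

    def test_short_trajectory_rejected(self):
        traj = Trajectory(times=np.array([0.0]), states=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="2 samples"):
            pulse_times_from_activity(traj)

    def test_threshold_range_validated(self, control_trajectory):
        with pytest.raises(ValueError):
            pulse_times_from_activity(control_trajectory, 1.5)


class TestScanInput:
    def test_three_contiguous_bands(self, scan):
        labels = list(scan.regime)
        boundaries = sum(a != b for a, b in zip(labels, labels[1:]))
        assert boundaries == 2
        assert labels[0] == SILENT
        assert PULSATILE in labels
        assert labels[-1] == QUIESCENT_HIGH

    def test_frequency_non_decreasing_on_pulsatile_band(self, scan):
        f = scan.frequency[np.array([r == PULSATILE for r in scan.regime])]
        assert len(f) >= 5
        assert np.all(np.diff(f) >= -1e-9)

    def test_fixed_points_confirmed_by_root_finding(self, kndy_params, scan):
        # steady regimes must correspond to true equilibria of the flow
        from mepdsim.kndy_model import _rhs

        for ie, regime in zip(scan.I_exc, scan.regime):
            if regime == PULSATILE:
                continue
            inp = ArcInput(I_exc=float(ie), I_inh=0.5)
            guess = (KndyState(0, 0, 0) if regime == SILENT
                     else KndyState(0.6, 0.05, 0.4))
            fp = find_fixed_point(kndy_params, inp, guess=guess)
            if fp is None:  # oscillatory shoulder: no stable equilibrium
                continue
            res = _rhs(fp.as_array(), kndy_params, inp.I_exc, inp.I_inh)
            assert np.max(np.abs(res)) < 1e-8

    def test_everything_silent_under_dominant_inhibition(self, kndy_params):
        scan = scan_input(kndy_params, np.linspace(0, 0.3, 4), I_inh=2.0,
                          t_settle=60.0, t_window=60.0)
        assert all(r == SILENT for r in scan.regime)

    def test_small_grid_rejected(self, kndy_params):
        with pytest.raises(ValueError, match="2 points"):
            scan_input(kndy_params, [0.5])
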