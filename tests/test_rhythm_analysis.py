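"""Rhythm analysis validated against closed forms and brute-force
dense-sampling oracles on analytic signals."""

import numpy as np
import pytest

from compactclock.rhythm_analysis import (
    ARRHYTHMIC,
    DAMPED,
    RHYTHMIC,
    demultiplication_test,
    dusk_sensitivity,
    entrained_phases,
    estimate_period,
    find_peaks,
    find_troughs,
)
from compactclock.light_protocols import ld_cycle

from conftest import synthetic_trajectory


def cosine_traj(period=24.0, t_end=240.0, dt=1.0, phase=0.0, decay=None):
    t = np.arange(0.0, t_end + 1e-9, dt)
    x = np.cos(2 * np.pi * (t - phase) / period)
    if decay is not None:
        x = x * np.exp(-t * np.log(2) / decay)
    return synthetic_trajectory(t, x)


class TestFindPeaks:
    def test_cosine_peaks_at_multiples_of_period(self):
        peaks = find_peaks(cosine_traj(dt=1.0), "x")
        times = np.array([p[0] for p in peaks])
        expected = np.arange(24.0, 240.0, 24.0)
        assert times.size == expected.size
        assert np.max(np.abs(times - expected)) < 0.05

    def test_constant_series_has_no_peaks(self):
        t = np.arange(0, 100.0, 1.0)
        assert find_peaks(synthetic_trajectory(t, np.ones_like(t)), "x") == []

    def test_monotone_series_has_no_peaks(self):
        t = np.arange(0, 100.0, 1.0)
        assert find_peaks(synthetic_trajectory(t, t * 0.1), "x") == []

    def test_troughs_mirror_peaks(self):
        traj = cosine_traj()
        troughs = find_troughs(traj, "x")
        assert np.all([abs(v + 1.0) < 1e-3 for _, v in troughs])

    def test_two_tone_count_matches_dense_oracle(self):
        """Peak count of an incommensurate two-tone signal equals the
        brute-force count on dt=0.001 sampling."""
        f = lambda t: np.sin(2 * np.pi * t / 24.0) + 0.4 * np.sin(2 * np.pi * t / 7.3)
        t_coarse = np.arange(0.0, 120.0, 0.25)
        peaks = find_peaks(synthetic_trajectory(t_coarse, f(t_coarse)), "x")
        t_dense = np.arange(0.0, 120.0, 0.001)
        x = f(t_dense)
        dense_count = int(np.sum((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))
        assert len(peaks) == dense_count


class TestEstimatePeriod:
    @pytest.mark.parametrize("period", [20.0, 24.0, 25.7])
    def test_sine_period_recovered(self, period):
        est = estimate_period(cosine_traj(period=period, dt=0.5), "x")
        assert est.rhythmic == RHYTHMIC
        assert est.period == pytest.approx(period, abs=0.01)

    def test_period_error_vs_dense_oracle(self):
        """Estimator error < 0.02 h against dt=0.001 brute-force peaks."""
        period = 23.4
        est = estimate_period(cosine_traj(period=period, dt=0.5), "x")
        t = np.arange(0.0, 240.0, 0.001)
        x = np.cos(2 * np.pi * t / period)
        idx = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1
        oracle = float(np.mean(np.diff(t[idx])))
        assert abs(est.period - oracle) < 0.02

    def test_damped_sine_not_called_rhythmic(self):
        # half-life 30 h: amplitude after 240 h is ~0.4% of the start
        est = estimate_period(cosine_traj(decay=30.0, dt=0.5), "x")
        assert est.rhythmic in (DAMPED, ARRHYTHMIC)

    def test_flat_series_arrhythmic(self):
        t = np.arange(0, 200.0, 0.5)
        est = estimate_period(synthetic_trajectory(t, np.full_like(t, 2.0)), "x")
        assert est.rhythmic == ARRHYTHMIC
        assert est.n_peaks == 0

    def test_window_longer_than_span_rejected(self):
        with pytest.raises(ValueError):
            estimate_period(cosine_traj(t_end=48.0), "x", window=100.0)


class TestEntrainedPhases:
    def test_peak_at_lights_on_reports_zt0(self):
        t = np.arange(0.0, 96.0 + 1e-9, 0.25)
        x = np.cos(2 * np.pi * t / 24.0)  # peaks exactly at ZT0
        peak, trough = entrained_phases(synthetic_trajectory(t, x),
                                        ld_cycle(12), "x")
        assert min(peak, 24 - peak) < 0.05
        assert trough == pytest.approx(12.0, abs=0.05)

    def test_shift_equivariance(self):
        t = np.arange(0.0, 96.0 + 1e-9, 0.25)
        for shift in (3.0, 7.5):
            x = np.cos(2 * np.pi * (t - shift) / 24.0)
            peak, _ = entrained_phases(synthetic_trajectory(t, x),
                                       ld_cycle(12), "x")
            assert peak == pytest.approx(shift, abs=0.05)


class TestDuskSensitivity:
    @staticmethod
    def table(phases, pps=(3, 6, 9, 12, 15, 18, 21)):
        import pandas as pd
        return pd.DataFrame([
            {"photoperiod": pp, "component": "x", "peak_zt": ph,
             "trough_zt": 0.0}
            for pp, ph in zip(pps, phases)])

    def test_constant_phase_slope_zero(self):
        tab = self.table([2.0] * 7)
        assert dusk_sensitivity(tab, "x") == pytest.approx(0.0, abs=1e-12)

    def test_dusk_locked_slope_one(self):
        tab = self.table([3, 6, 9, 12, 15, 18, 21])
        assert dusk_sensitivity(tab, "x") == pytest.approx(1.0)

    def test_half_sensitive_with_noise(self):
        rng = np.random.default_rng(0)
        pps = np.array([3, 6, 9, 12, 15, 18, 21], dtype=float)
        tab = self.table(0.5 * pps + rng.normal(0, 0.1, 7), pps)
        assert dusk_sensitivity(tab, "x") == pytest.approx(0.5, abs=0.05)

    def test_wraparound_phases_unwrapped(self):
        # dawn-tracking gene whose phase jitters across the ZT0/ZT24 seam
        tab = self.table([23.8, 0.1, 23.9, 0.2, 0.0, 23.7, 0.1])
        assert abs(dusk_sensitivity(tab, "x")) < 0.05


class TestDemultiplication:
    def test_relaxation_toy_follows_short_cycle(self, ref_params):
        """A single-well relaxation system (no endogenous oscillator) must
        simply follow a 6L:6D drive with a 12 h dominant period."""
        from compactclock.simulate import Trajectory
        proto = ld_cycle(6, 12)
        # brute-force integration of dx/dt = L - x (1-variable linear toy)
        dt = 0.001
        t = np.arange(0.0, 480.0, dt)
        x = np.empty_like(t)
        x[0] = 0.0
        for i in range(1, t.size):
            L = proto(t[i - 1])
            x[i] = x[i - 1] + dt * (L - x[i - 1])
        keep = t >= 384.0
        traj = synthetic_trajectory(t[keep] - 384.0, x[keep])
        est = estimate_period(traj, "x")
        assert est.period == pytest.approx(12.0, abs=0.05)
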