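import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spopulse.ssa import EnsembleResult
from spopulse.twostate import (OnFractionSeries, fit_rates, fraction_on, pon,
                               threshold_robustness)


def _ensemble_from_counts(tap_rows):
    tap = np.asarray(tap_rows, dtype=np.int64)
    times = np.arange(tap.shape[1]) * 0.1
    return EnsembleResult(times, tap, seed_base=0, initially_on=False)


def _telegraph_ensemble(k_on, k_off, n_cells, t_grid, p0, rng):
    """Exact simulation of independent two-state chains (the oracle)."""
    fon = np.zeros((n_cells, t_grid.size), dtype=bool)
    for c in range(n_cells):
        state = rng.random() < p0
        t, i = 0.0, 0
        while i < t_grid.size:
            rate = k_off if state else k_on
            dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            t_next = t + dwell
            while i < t_grid.size and t_grid[i] < t_next:
                fon[c, i] = state
                i += 1
            state = not state
            t = t_next
    return fon


class TestPon:
    def test_initial_value(self):
        assert pon(0.0, 0.3, 0.7, 0.25) == pytest.approx(0.25)

    def test_long_time_limit(self):
        assert pon(1e6, 0.3, 0.7, 0.0) == pytest.approx(0.3)
        assert pon(1e6, 0.3, 0.7, 1.0) == pytest.approx(0.3)

    def test_worked_value(self):
        # kON = kOFF = 0.5, p0 = 0, t = 1: 0.5 (1 - e^-1)
        assert pon(1.0, 0.5, 0.5, 0.0) == pytest.approx(
            0.5 * (1 - math.exp(-1)), abs=1e-6)

    def test_frozen_chain(self):
        assert pon(5.0, 0.0, 0.0, 0.4) == pytest.approx(0.4)

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0),
           st.floats(0.0, 1.0), st.floats(0.01, 20.0))
    @settings(derandomize=True, deadline=None)
    def test_satisfies_generating_ode(self, k_on, k_off, p0, t):
        # dP/dt = kON (1-P) - kOFF P, checked by central difference
        h = 1e-5
        dp = (pon(t + h, k_on, k_off, p0) - pon(t - h, k_on, k_off, p0)) / (2 * h)
        p = pon(t, k_on, k_off, p0)
        assert dp == pytest.approx(k_on * (1 - p) - k_off * p, abs=1e-6)

    def test_initial_conditions_converge(self):
        k_on, k_off = 0.4, 0.6
        t = 25.0 / (k_on + k_off)
        assert abs(pon(t, k_on, k_off, 0.0) - pon(t, k_on, k_off, 1.0)) < 1e-6


class TestFractionOn:
    def test_all_above_threshold(self):
        ens = _ensemble_from_counts([[300, 400], [250, 201]])
        s = fraction_on(ens)
        assert np.all(s.fon == 1.0)

    def test_partial_fraction(self):
        ens = _ensemble_from_counts([[300]] + [[100]] * 3)
        assert fraction_on(ens).fon[0] == pytest.approx(0.25)

    def test_threshold_is_inclusive(self):
        ens = _ensemble_from_counts([[200], [199]])
        assert fraction_on(ens, 200).fon[0] == pytest.approx(0.5)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            OnFractionSeries(np.array([0.0]), np.array([1.2]), 10)


class TestFitRates:
    def test_noiseless_self_consistency(self):
        t = np.arange(0, 40.05, 0.1)
        k_on, k_off = 0.02, 0.20
        s_off = OnFractionSeries(t, pon(t, k_on, k_off, 0.0), 1000)
        s_on = OnFractionSeries(t, pon(t, k_on, k_off, 1.0), 1000)
        fit = fit_rates(s_off, s_on)
        assert fit.k_on == pytest.approx(k_on, rel=1e-2)
        assert fit.k_off == pytest.approx(k_off, rel=1e-2)
        assert fit.mse < 1e-10
        assert fit.pon_inf == pytest.approx(k_on / (k_on + k_off), rel=1e-2)

    def test_recovery_from_simulated_telegraph_ensembles(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 40.05, 0.1)
        k_on, k_off = 0.05, 0.15
        f_off = _telegraph_ensemble(k_on, k_off, 2000, t, 0.0, rng)
        f_on = _telegraph_ensemble(k_on, k_off, 2000, t, 1.0, rng)
        fit = fit_rates(
            OnFractionSeries(t, f_off.mean(axis=0), 2000),
            OnFractionSeries(t, f_on.mean(axis=0), 2000))
        assert fit.k_on == pytest.approx(k_on, rel=0.10)
        assert fit.k_off == pytest.approx(k_off, rel=0.10)

    @pytest.mark.parametrize("k_on", [0.01, 0.05, 0.2])
    @pytest.mark.parametrize("k_off", [0.01, 0.05, 0.2])
    def test_recovery_grid(self, k_on, k_off):
        # median error over seeds within 15% for each rate combination
        t = np.arange(0, 60.05, 0.1)
        errs_on, errs_off = [], []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            f_off = _telegraph_ensemble(k_on, k_off, 600, t, 0.0, rng)
            f_on = _telegraph_ensemble(k_on, k_off, 600, t, 1.0, rng)
            fit = fit_rates(OnFractionSeries(t, f_off.mean(axis=0), 600),
                            OnFractionSeries(t, f_on.mean(axis=0), 600))
            errs_on.append(abs(fit.k_on - k_on) / k_on)
            errs_off.append(abs(fit.k_off - k_off) / k_off)
        assert np.median(errs_on) < 0.15
        assert np.median(errs_off) < 0.15

    def test_mismatched_grids_rejected(self):
        a = OnFractionSeries(np.arange(5) * 0.1, np.zeros(5), 10)
        b = OnFractionSeries(np.arange(6) * 0.1, np.zeros(6), 10)
        with pytest.raises(ValueError):
            fit_rates(a, b)


class TestThresholdRobustness:
    def _pair(self, rng):
        n, t = 60, 81
        base_off = rng.integers(0, 150, size=(n, t))
        base_on = rng.integers(260, 600, size=(n, t))
        flip = rng.random((n, t)) < 0.1
        base_on[flip] = 50
        times = np.arange(t) * 0.5
        return (EnsembleResult(times, base_off, 0, False),
                EnsembleResult(times, base_on, 0, True))

    def test_reproducible_under_fixed_seed(self):
        e_off, e_on = self._pair(np.random.default_rng(3))
        r1 = threshold_robustness(e_off, e_on, n_draws=5, seed=11)
        r2 = threshold_robustness(e_off, e_on, n_draws=5, seed=11)
        np.testing.assert_array_equal(r1[4], r2[4])

    def test_collapsed_range_zero_spread(self):
        e_off, e_on = self._pair(np.random.default_rng(4))
        _, sd_on, _, sd_off, _ = threshold_robustness(
            e_off, e_on, n_draws=4, rel_range=(1.0, 1.0), seed=0)
        assert sd_on == pytest.approx(0.0, abs=1e-12)
        assert sd_off == pytest.approx(0.0, abs=1e-12)
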