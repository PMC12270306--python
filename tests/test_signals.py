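import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spopulse.signals import (CosineSpec, Signal, SquarePulseSpec,
                              cosine_signal, natural_pulse_signal,
                              per_cycle_constant, square_signal)


class TestSignalContainer:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            Signal(np.array([0.0, 0.1, 0.3]), np.zeros(3))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            Signal(np.arange(3) * 0.1, np.array([0.0, -1.0, 0.0]))

    def test_csv_roundtrip(self, tmp_path):
        sig = cosine_signal(CosineSpec(0.5, 2.0), duration=4.0, dt=0.01)
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        back = Signal.from_csv(path)
        assert back.units == sig.units
        np.testing.assert_allclose(back.values, sig.values, atol=1e-9)


class TestCosine:
    def test_angular_frequency(self):
        assert CosineSpec(1.0, 1.0).freq == pytest.approx(2 * math.pi)

    def test_extremes_and_zero_minimum(self):
        sig = cosine_signal(CosineSpec(0.7, 2.0), duration=4.0, dt=0.01)
        assert sig.values[0] == pytest.approx(1.4)
        assert sig.interpolator()(1.0) == pytest.approx(0.0, abs=1e-9)
        assert sig.values.min() >= 0.0

    @pytest.mark.parametrize("k", [1, 3])
    def test_mean_over_full_periods_equals_amplitude(self, k):
        amp, T = 0.45, 1.5
        sig = cosine_signal(CosineSpec(amp, T), duration=k * T, dt=T / 300)
        assert sig.mean() == pytest.approx(amp, rel=1e-4)

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            cosine_signal(CosineSpec(1.0, 1.0), duration=2.0, dt=0.1)


class TestSquare:
    def test_growing_off_time_schedule(self):
        spec = SquarePulseSpec(1.0, 0.0, (1.0, 1.0, 1.0), (1.0, 2.0, 3.0))
        sig = square_signal(spec, dt=0.01)
        assert sig.duration == pytest.approx(9.0)
        f = sig.interpolator()
        assert f(0.5) == 1.0 and f(1.5) == 0.0       # first cycle 1 ON, 1 OFF
        assert f(2.5) == 1.0 and f(4.0) == 0.0       # second cycle 1 ON, 2 OFF

    def test_degenerate_equal_levels(self):
        spec = SquarePulseSpec(0.3, 0.3, (1.0,), (2.0,))
        sig = square_signal(spec)
        assert np.all(sig.values == 0.3)

    def test_duty_cycle_time_average(self):
        high, low, on, off = 2.0, 0.5, 1.2, 0.8
        spec = SquarePulseSpec(high, low, (on,) * 5, (off,) * 5)
        sig = square_signal(spec, dt=0.001)
        d = on / (on + off)
        assert sig.mean() == pytest.approx(low + d * (high - low), rel=2e-3)


class TestPerCycleConstant:
    def test_constant_input_idempotent(self):
        sig = Signal(np.arange(0, 6.0, 0.01), np.full(600, 0.8))
        for mode in ("mean", "max", "min"):
            out = per_cycle_constant(sig, [0.0, 2.0, 4.0], mode)
            assert np.allclose(out.values, 0.8)

    def test_cosine_cycle_mean_is_offset(self):
        sig = cosine_signal(CosineSpec(0.6, 2.0), duration=4.0, dt=0.002)
        out = per_cycle_constant(sig, [0.0, 2.0, 4.0], "mean")
        assert out.values[100] == pytest.approx(0.6, rel=1e-3)

    def test_triangular_pulse_statistics(self):
        # 0 -> 2 -> 0 triangle over one cycle: mean 1, max 2, min 0
        t = np.arange(0, 2.0001, 0.001)
        vals = 2.0 - 2.0 * np.abs(t - 1.0)
        sig = Signal(t, vals)
        assert per_cycle_constant(sig, [0, 2], "mean").values[0] == \
            pytest.approx(1.0, rel=1e-3)
        assert per_cycle_constant(sig, [0, 2], "max").values[0] == \
            pytest.approx(2.0)
        assert per_cycle_constant(sig, [0, 2], "min").values[0] == \
            pytest.approx(0.0)

    def test_mean_mode_preserves_cycle_integrals(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 9.0, 0.005)
        vals = np.abs(np.sin(t) + 0.3 * rng.standard_normal(t.size)).cumsum()
        vals /= vals.max()
        sig = Signal(t, vals)
        edges = [0.0, 3.0, 6.0, 8.995]
        out = per_cycle_constant(sig, edges, "mean")
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (sig.times >= lo) & (sig.times <= hi)
            orig = np.trapezoid(sig.values[m], sig.times[m])
            flat = np.trapezoid(out.values[m], sig.times[m])
            assert flat == pytest.approx(orig, rel=2e-2)

    def test_empty_cycle_rejected(self):
        sig = Signal(np.arange(0, 1.0, 0.01), np.ones(100))
        with pytest.raises(ValueError):
            per_cycle_constant(sig, [0.5, 0.5], "mean")


class TestNaturalPulse:
    def test_nonnegative_and_periodic(self, phos_params):
        sig = natural_pulse_signal(g=0.2, n_cycles=8, params=phos_params)
        assert np.all(sig.values >= 0)
        tau = math.log(2) / 0.2
        n = int(round(tau / sig.dt))
        c1, c2 = sig.values[:n], sig.values[n:2 * n]
        corr = np.corrcoef(c1, c2)[0, 1]
        assert corr > 0.99

    def test_amplitude_grows_as_growth_slows(self, pulse_cache):
        slow, fast = pulse_cache(0.15), pulse_cache(0.6)
        assert slow.values.max() > 2 * fast.values.max()
        assert slow.mean() > fast.mean()

    def test_no_phosphorylation_source_gives_flat_zero(self, phos_params):
        import dataclasses
        dead = dataclasses.replace(phos_params, ka=0.0)
        sig = natural_pulse_signal(g=0.2, n_cycles=5, params=dead)
        assert np.all(sig.values < 1e-9)
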