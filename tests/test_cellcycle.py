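import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spopulse.cellcycle import (CycleTiming, GenePosition,
                                OverlappingReplicationError, SizeFactorParams,
                                average_copy_number, discrete_copy_number,
                                size_factor, timing_from_growth)


class TestTimingFromGrowth:
    @pytest.mark.parametrize("g, tau_rep, tau_cyc", [
        (0.2, 1.53, 3.4657),          # slow growth reference point
        (math.log(2), 0.9964, 1.0),   # one-hour cycle by definition
        (0.15, 1.78, 4.6210),
    ])
    def test_reference_values(self, g, tau_rep, tau_cyc):
        t = timing_from_growth(g)
        assert t.tau_rep == pytest.approx(tau_rep, abs=5e-4)
        assert t.tau_cyc == pytest.approx(tau_cyc, abs=5e-4)
        assert t.tau_post == pytest.approx(t.tau_cyc - t.tau_rep, abs=1e-12)

    def test_printed_precision_triple(self):
        t = timing_from_growth(0.2)
        assert (round(t.tau_rep, 2), round(t.tau_post, 2),
                round(t.tau_cyc, 2)) == (1.53, 1.94, 3.47)

    @pytest.mark.parametrize("g", [0.0, -0.1, float("nan")])
    def test_invalid_growth_rate(self, g):
        with pytest.raises(ValueError):
            timing_from_growth(g)

    def test_overlapping_replication_rejected_then_allowed(self):
        with pytest.raises(OverlappingReplicationError):
            timing_from_growth(0.7)
        t = timing_from_growth(0.7, allow_overlap=True)
        assert t.tau_rep >= t.tau_cyc

    def test_overrides_adjust_cycle_length(self):
        t = timing_from_growth(0.2)
        t2 = t.with_overrides(tau_rep=t.tau_rep + 0.3)
        assert t2.tau_post == pytest.approx(t.tau_post)
        assert t2.tau_cyc == pytest.approx(t.tau_cyc + 0.3)


class TestSizeFactor:
    @pytest.mark.parametrize("g, expected", [
        (0.0, 7.2),            # a + c at zero growth
        (1.0, 3.5 / 2 + 3.7),  # b = -ln2 halves the exponential per unit g
    ])
    def test_values(self, g, expected):
        assert size_factor(g) == pytest.approx(expected)

    def test_degenerate_constant(self):
        p = SizeFactorParams(a=0.0, b=-1.0, c=3.7)
        assert size_factor(0.1, p) == size_factor(2.0, p) == 3.7

    @given(st.floats(0.01, 1.5), st.floats(0.01, 1.5))
    @settings(derandomize=True, deadline=None)
    def test_strictly_decreasing(self, g1, g2):
        lo, hi = sorted([g1, g2])
        if hi - lo > 1e-9:
            assert size_factor(hi) < size_factor(lo)


class TestCopyNumbers:
    def test_terminus_gene_doubles_at_replication_end(self):
        t = timing_from_growth(0.2)
        kinA = GenePosition(1.0)
        assert discrete_copy_number(t.tau_rep - 0.01, kinA, t) == 1
        assert discrete_copy_number(t.tau_rep, kinA, t) == 2
        assert discrete_copy_number(t.tau_cyc - 0.01, kinA, t) == 2

    def test_oriC_gene_always_duplicated(self):
        t = timing_from_growth(0.2)
        spo0F = GenePosition(0.0)
        for x in np.linspace(0.0, t.tau_cyc * 0.999, 7):
            assert discrete_copy_number(x, spo0F, t) == 2

    def test_dosage_ratio_during_replication(self):
        # kinA:spo0F is 1:2 while replication is ongoing
        t = timing_from_growth(0.2)
        mid_rep = 0.5 * t.tau_rep
        assert (discrete_copy_number(mid_rep, GenePosition(1.0), t),
                discrete_copy_number(mid_rep, GenePosition(0.0), t)) == (1, 2)

    def test_out_of_cycle_time_rejected(self):
        t = timing_from_growth(0.2)
        with pytest.raises(ValueError):
            discrete_copy_number(t.tau_cyc, GenePosition(0.5), t)

    @pytest.mark.parametrize("p, expected", [
        (0.0, 2.0),
        (0.5, 2 ** (1 - 1.53 * 0.5 / (math.log(2) / 0.2))),  # ~1.716
    ])
    def test_average_copy_number(self, p, expected):
        t = timing_from_growth(0.2)
        assert average_copy_number(GenePosition(p), t) == pytest.approx(
            expected, rel=1e-3)

    def test_average_is_one_when_replication_fills_cycle(self):
        t = CycleTiming(0.6, 1.0, 1.0, allow_overlap=True)
        assert average_copy_number(GenePosition(1.0), t) == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(derandomize=True, deadline=None)
    def test_average_monotone_decreasing_in_position(self, p1, p2):
        t = timing_from_growth(0.2)
        lo, hi = sorted([p1, p2])
        n_lo = average_copy_number(GenePosition(lo), t)
        n_hi = average_copy_number(GenePosition(hi), t)
        assert 1.0 <= n_hi <= n_lo <= 2.0

    def test_cycle_average_of_discrete_copies_orders_with_position(self):
        # time-averaged discrete copies lie in [1, 2] and decrease with p
        t = timing_from_growth(0.2)
        xs = np.linspace(0, t.tau_cyc * 0.9999, 4000)
        means = []
        for p in (0.0, 0.3, 0.7, 1.0):
            vals = [discrete_copy_number(x, GenePosition(p), t) for x in xs]
            means.append(np.mean(vals))
        assert all(1.0 <= m <= 2.0 for m in means)
        assert all(a >= b for a, b in zip(means, means[1:]))
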