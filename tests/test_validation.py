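"""Validation statistics: worked arithmetic examples and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiralquant.validation import (AreaTriplet, ReplicateSet,
                                    absolute_recovery, accuracy,
                                    average_recovery, interday_repeatability,
                                    intraday_precision, method_accuracy,
                                    method_limits, method_precision,
                                    relative_recovery, relative_retention,
                                    signal_suppression)

finite = st.floats(allow_nan=False, allow_infinity=False)


class TestAccuracyAndPrecision:
    @pytest.mark.parametrize("nominal,measured,expected", [
        (10.0, (10.0, 10.0, 10.0), 100.0),
        (10.0, (12.0, 12.5, 13.0), 80.0),
        (5.0, (10.0, 10.0, 10.0), 50.0),
    ])
    def test_accuracy(self, nominal, measured, expected):
        assert accuracy(ReplicateSet(nominal, measured)) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("measured,expected", [
        ((10.0, 10.0, 10.0), 0.0),
        ((8.0, 10.0, 12.0), 20.0),
        ((1.0, 3.0), 70.7106781),
    ])
    def test_intraday_precision(self, measured, expected):
        assert intraday_precision(ReplicateSet(1.0, measured)) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("day_rsds,expected", [
        ([(5.0, 5.0, 5.0), (7.0, 7.0, 7.0)], 0.0),       # both days 0% RSD
    ])
    def test_interday_zero(self, day_rsds, expected):
        days = [ReplicateSet(1.0, m, day_label=str(i))
                for i, m in enumerate(day_rsds)]
        assert interday_repeatability(days) == pytest.approx(expected)

    def test_interday_is_mean_of_day_rsds(self):
        # day RSDs of 10% and 20% -> 15%; 5/5/20 -> 10%
        d10 = ReplicateSet(1.0, (0.9, 1.0, 1.1))    # RSD 10.0%
        d20 = ReplicateSet(1.0, (0.8, 1.0, 1.2))    # RSD 20.0%
        assert interday_repeatability([d10, d20]) == pytest.approx(15.0)
        d5 = ReplicateSet(1.0, (0.95, 1.0, 1.05))   # RSD 5.0%
        assert interday_repeatability([d5, d5, d20]) == pytest.approx(10.0)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            interday_repeatability([ReplicateSet(1.0, (1.0, 1.0))])

    @settings(max_examples=100, derandomize=True)
    @given(nominal=st.floats(0.01, 1e4),
           measured=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8))
    def test_accuracy_identity(self, nominal, measured):
        # accuracy x mean(measurements) == nominal x 100 by construction
        rep = ReplicateSet(nominal, tuple(measured))
        assert accuracy(rep) * rep.mean == pytest.approx(nominal * 100.0,
                                                         rel=1e-9)


class TestRelativeRetention:
    @pytest.mark.parametrize("ta,ti,expected", [
        (3.0, 3.0, 1.0), (2.0, 4.0, 0.5), (4.5, 3.0, 1.5)])
    def test_ratio(self, ta, ti, expected):
        assert relative_retention(ta, ti) == pytest.approx(expected)

    def test_nonpositive_istd_rejected(self):
        with pytest.raises(ValueError):
            relative_retention(1.0, 0.0)


class TestSuppressionAndRecovery:
    @pytest.mark.parametrize("spiked,blank,qc,expected_ss", [
        (100.0, 0.0, 100.0, 0.0),
        (50.0, 0.0, 100.0, 50.0),
        (250.0, 50.0, 100.0, -100.0),   # enhancement
    ])
    def test_signal_suppression(self, spiked, blank, qc, expected_ss):
        assert signal_suppression(AreaTriplet(spiked, blank, qc)) == \
            pytest.approx(expected_ss)

    @pytest.mark.parametrize("spiked,blank,qc,expected", [
        (130.0, 30.0, 100.0, 100.0),
        (80.0, 30.0, 100.0, 50.0),
        (30.0, 30.0, 100.0, 0.0),
    ])
    def test_absolute_recovery(self, spiked, blank, qc, expected):
        assert absolute_recovery(AreaTriplet(spiked, blank, qc)) == \
            pytest.approx(expected)

    def test_zero_qc_area_rejected(self):
        with pytest.raises(ValueError):
            AreaTriplet(1.0, 0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(spiked=st.floats(0, 1e6), frac=st.floats(0, 1),
           qc=st.floats(1e-3, 1e6))
    def test_suppression_plus_recovery_is_exactly_100(self, spiked, frac, qc):
        # spiking analyte into an extract cannot reduce its area below the
        # matched blank, so the blank-corrected ratio is non-negative; in
        # that regime the complement identity is exact in floating point
        triplet = AreaTriplet(spiked, frac * spiked, qc)
        assert signal_suppression(triplet) + absolute_recovery(triplet) == 100.0

    def test_identity_holds_to_one_ulp_below_blank(self):
        # pathological spiked-below-blank triplets: identity to 1 ulp
        triplet = AreaTriplet(10.0, 10.3, 3.0)
        total = signal_suppression(triplet) + absolute_recovery(triplet)
        assert total == pytest.approx(100.0, abs=1e-12)

    @pytest.mark.parametrize("measured,blank,spike,expected", [
        (0.6, 0.1, 0.5, 100.0),
        (0.35, 0.1, 0.5, 50.0),
    ])
    def test_relative_recovery(self, measured, blank, spike, expected):
        assert relative_recovery(measured, blank, spike) == \
            pytest.approx(expected)

    def test_relative_recovery_below_blank_is_negative(self):
        assert relative_recovery(0.05, 0.1, 0.5) < 0

    def test_average_recovery_across_levels(self):
        mean, sd = average_recovery([58.0, 60.0, 56.0])
        assert mean == pytest.approx(58.0)
        assert sd == pytest.approx(2.0)


class TestMethodAccuracyPrecision:
    @pytest.mark.parametrize("x,blank,measured,expected", [
        (0.5, 0.0, (0.5, 0.5, 0.5), 100.0),
        (0.5, 0.1, (0.6, 0.6, 0.6), 100.0),
        (0.5, 0.1, (1.1, 1.1, 1.1), 50.0),
    ])
    def test_method_accuracy(self, x, blank, measured, expected):
        assert method_accuracy(ReplicateSet(x, measured), blank) == \
            pytest.approx(expected)

    def test_nonpositive_corrected_mean_is_undefined(self):
        out = method_accuracy(ReplicateSet(0.5, (0.05, 0.05, 0.05)), 0.1)
        assert math.isnan(out)

    def test_method_precision_worked_example(self):
        # blank 0.1, measurements (0.5, 0.7, 0.9): SD 0.2 over mean 0.6
        out = method_precision(ReplicateSet(0.5, (0.5, 0.7, 0.9)), 0.1)
        assert out == pytest.approx(100.0 / 3.0, rel=1e-9)

    def test_identical_measurements_zero_rsd(self):
        assert method_precision(ReplicateSet(0.5, (0.6, 0.6, 0.6)), 0.1) == 0.0

    def test_blank_subtraction_changes_rsd_not_sd(self):
        measured = (0.5, 0.7, 0.9)
        raw = intraday_precision(ReplicateSet(0.7, measured))
        subtracted = method_precision(ReplicateSet(0.5, measured), 0.1)
        # same SD, smaller mean after subtraction -> larger %RSD
        assert subtracted > raw
        assert np.std(np.array(measured) - 0.1, ddof=1) == \
            pytest.approx(np.std(measured, ddof=1))


class TestMethodLimits:
    def test_forward_formula(self):
        lim = method_limits(1.0, 2.0, 100.0, 100.0)
        assert lim.mlod == pytest.approx(0.01)
        assert lim.mloq == pytest.approx(0.02)

    def test_halved_recovery_doubles_limits(self):
        full = method_limits(1.0, 2.0, 100.0, 100.0)
        half = method_limits(1.0, 2.0, 50.0, 100.0)
        assert half.mlod == pytest.approx(2 * full.mlod)

    def test_printed_river_water_style_value(self):
        # iLOD 0.5 ug/L, 58% recovery, CF 100 -> 0.0086, printing as 0.009
        lim = method_limits(0.5, 1.0, 58.0, 100.0)
        assert lim.mlod == pytest.approx(0.00862069, rel=1e-6)
        assert round(lim.mlod, 3) == 0.009

    def test_nonpositive_recovery_rejected(self):
        with pytest.raises(ValueError):
            method_limits(1.0, 2.0, 0.0, 100.0)

    @settings(max_examples=100, derandomize=True)
    @given(ilod=st.floats(1e-4, 10), k=st.floats(0.1, 10),
           rec=st.floats(1.0, 160.0), cf=st.floats(1.0, 1000.0))
    def test_homogeneity_in_ilod_and_cf(self, ilod, k, rec, cf):
        base = method_limits(ilod, 2 * ilod, rec, cf)
        scaled_ilod = method_limits(k * ilod, 2 * k * ilod, rec, cf)
        scaled_cf = method_limits(ilod, 2 * ilod, rec, k * cf)
        assert scaled_ilod.mlod == pytest.approx(k * base.mlod, rel=1e-9)
        assert scaled_cf.mlod == pytest.approx(base.mlod / k, rel=1e-9)
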