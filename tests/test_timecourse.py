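"""Ratio spectra, normalization, AUC, confluency gating and statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ecistools import (
    CONFLUENT_BARRIER,
    DEFAULT_ELECTRODE,
    FrequencyGrid,
    NormalizedTrace,
    RatioSpectrum,
    area_under_curve,
    compare_groups,
    confluency_gate,
    normalize_trace,
    ratio_spectrum,
    select_frequency,
    star_annotation,
    well_impedance,
)

GRID = FrequencyGrid()
FREQS = GRID.as_array()


def records_frame(wells: dict[str, object], at_time=0.0) -> pd.DataFrame:
    """Tidy records at one timepoint; wells maps id -> barrier (None = free)."""
    rows = []
    for well, barrier in wells.items():
        z = well_impedance(FREQS, DEFAULT_ELECTRODE, barrier)
        rows.append(pd.DataFrame({
            "time_h": at_time, "well": well,
            "group": "cellfree" if barrier is None else "cells",
            "frequency_hz": FREQS,
            "z_real_ohm": z.real, "z_imag_ohm": z.imag,
        }))
    return pd.concat(rows, ignore_index=True)


class TestRatioSpectrum:
    def test_identical_groups_give_unit_ratios(self):
        df = records_frame({"a": None, "b": None})
        spec = ratio_spectrum(df, ["a"], ["b"], "impedance_magnitude", 0.0)
        np.testing.assert_allclose(spec.ratios, 1.0)

    def test_confluent_monolayer_peaks_at_interior_frequency(self):
        df = records_frame({"a": CONFLUENT_BARRIER, "b": None})
        spec = ratio_spectrum(df, ["a"], ["b"], "impedance_magnitude", 0.0)
        peak = int(np.argmax(spec.ratios))
        assert 0 < peak < len(GRID) - 1

    def test_capacitance_ratio_below_one_at_high_frequency(self):
        df = records_frame({"a": CONFLUENT_BARRIER, "b": None})
        spec = ratio_spectrum(df, ["a"], ["b"], "capacitance", 0.0)
        assert spec.ratios[-1] < 1.0

    def test_missing_frequency_omitted_with_warning(self):
        df = records_frame({"a": CONFLUENT_BARRIER, "b": None})
        df = df[~((df.well == "b") & (df.frequency_hz == 500.0))]
        with pytest.warns(UserWarning, match="omitted"):
            spec = ratio_spectrum(df, ["a"], ["b"], "resistance", 0.0)
        assert 500.0 not in spec.grid.frequencies_hz
        assert len(spec.grid) == 8


class TestSelectFrequency:
    def test_monotone_ratios_select_extremes(self):
        spec = RatioSpectrum(grid=GRID, quantity="impedance_magnitude",
                             ratios=tuple(np.linspace(1.1, 2.0, 9)))
        assert select_frequency(spec, "maximize") == 64000.0
        assert select_frequency(spec, "minimize") == 250.0

    def test_ties_break_toward_lower_frequency(self):
        ratios = np.ones(9); ratios[[3, 5]] = 2.0
        spec = RatioSpectrum(grid=GRID, quantity="resistance",
                             ratios=tuple(ratios))
        assert select_frequency(spec, "maximize") == GRID.frequencies_hz[3]

    def test_permutation_invariant_to_well_ordering(self):
        df = records_frame({"a": CONFLUENT_BARRIER, "b": CONFLUENT_BARRIER,
                            "c": None, "d": None})
        s1 = ratio_spectrum(df, ["a", "b"], ["c", "d"], "resistance", 0.0)
        s2 = ratio_spectrum(df, ["b", "a"], ["d", "c"], "resistance", 0.0)
        assert select_frequency(s1, "maximize") == select_frequency(s2, "maximize")
        np.testing.assert_allclose(s1.ratios, s2.ratios)


class TestNormalizeTrace:
    def test_unity_at_treatment_time(self):
        t = np.arange(-2.0, 5.0, 0.5)
        v = 100 + 10 * np.sin(t)
        trace = normalize_trace(t, v, t0=0.0)
        assert trace.values[trace.times_h.index(0.0)] == 1.0
        log = normalize_trace(t, v, t0=0.0, log_scale=True)
        assert log.values[log.times_h.index(0.0)] == 0.0

    def test_constant_trace_normalizes_to_ones(self):
        trace = normalize_trace([0.0, 1.0, 2.0], [7.0, 7.0, 7.0])
        assert trace.values == (1.0, 1.0, 1.0)

    def test_idempotent(self):
        t = [0.0, 1.0, 2.0]
        trace = normalize_trace(t, [5.0, 4.0, 3.0])
        again = normalize_trace(trace.times_h, trace.values)
        assert again.values == trace.values

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace([0.0, 1.0], [0.0, 1.0])

    def test_missing_t0_rejected(self):
        with pytest.raises(ValueError, match="t0"):
            normalize_trace([1.0, 2.0], [1.0, 2.0], t0=0.0)


class TestAUC:
    def test_constant_trace(self):
        t = np.arange(0.0, 25.25, 0.25)
        trace = NormalizedTrace(times_h=tuple(t), values=tuple(np.ones_like(t)))
        assert area_under_curve(trace, 0.0, 25.0).value == pytest.approx(25.0)

    def test_linear_ramp_exact(self):
        trace = NormalizedTrace(times_h=(0.0, 0.3, 1.0),
                                values=(0.0, 0.3, 1.0))
        assert area_under_curve(trace, 0.0, 1.0).value == pytest.approx(0.5)

    @given(split=st.floats(0.1, 24.9))
    def test_additive_over_adjacent_windows(self, split):
        rng = np.random.default_rng(0)
        t = np.unique(np.concatenate([[0.0], rng.uniform(0, 25, 60), [25.0]]))
        v = rng.normal(1.0, 0.2, t.size)
        trace = NormalizedTrace(times_h=tuple(t), values=tuple(v))
        whole = area_under_curve(trace, 0.0, 25.0).value
        parts = (area_under_curve(trace, 0.0, split).value
                 + area_under_curve(trace, split, 25.0).value)
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_window_outside_support_rejected(self):
        trace = NormalizedTrace(times_h=(0.0, 1.0), values=(1.0, 1.0))
        with pytest.raises(ValueError, match="support"):
            area_under_curve(trace, 0.0, 2.0)


class TestConfluencyGate:
    def test_never_confluent(self):
        t = np.arange(0.0, 10.0, 0.25)
        assert confluency_gate(t, np.full_like(t, 30e-9)) is None

    def test_exact_threshold_does_not_qualify(self):
        t = np.arange(0.0, 10.0, 0.25)
        assert confluency_gate(t, np.full_like(t, 20e-9)) is None

    def test_first_sustained_crossing_reported(self):
        t = np.arange(0.0, 10.0, 0.25)
        c = np.where(t >= 4.0, 15e-9, 30e-9)
        assert confluency_gate(t, c) == 4.0

    def test_brief_dip_shorter_than_dwell_ignored(self):
        t = np.arange(0.0, 10.0, 0.25)
        c = np.full_like(t, 30e-9)
        c[(t >= 2.0) & (t < 2.5)] = 15e-9   # 0.5 h dip, dwell is 1 h
        c[t >= 6.0] = 15e-9
        assert confluency_gate(t, c, dwell_h=1.0) == 6.0


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0, "****"), (0.0001, "****"), (0.00011, "***"),
        (0.001, "***"), (0.0011, "**"), (0.01, "**"),
        (0.011, "*"), (0.05, "*"), (0.051, "ns"), (1.0, "ns"),
    ])
    def test_threshold_boundaries_inclusive(self, p, expected):
        assert star_annotation(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            star_annotation(1.5)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]}
        res = compare_groups(g)
        assert res.degenerate and res.p_value == 1.0
        assert all(s == "ns" for s in res.pairwise_stars.values())

    def test_textbook_anova_matches_hand_computation(self):
        # group means 3, 4, 6; SSB = 70/3 on 2 df; SSW = 30 on 12 df
        # F = (70/6) / (30/12) = 14/3
        groups = {
            "g1": [1, 2, 3, 4, 5],
            "g2": [2, 3, 4, 5, 6],
            "g3": [4, 5, 6, 7, 8],
        }
        res = compare_groups(groups)
        assert res.test == "anova"
        assert res.statistic == pytest.approx(14 / 3)
        assert set(res.pairwise_p) == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}

    def test_two_groups_fall_back_to_t_test(self):
        from scipy import stats

        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5]
        res = compare_groups({"a": a, "b": b})
        assert res.test == "t-test"
        assert res.p_value == pytest.approx(stats.ttest_ind(a, b).pvalue)

    def test_unequal_group_sizes_supported(self):
        rng = np.random.default_rng(1)
        res = compare_groups({
            "a": rng.normal(0, 1, 5),
            "b": rng.normal(0, 1, 6),
            "c": rng.normal(3, 1, 6),
        })
        stars = {tuple(sorted(k)): v for k, v in res.pairwise_stars.items()}
        assert stars[("a", "c")] != "ns"
        assert stars[("b", "c")] != "ns"

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
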