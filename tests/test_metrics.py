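"""Rates, ISI-CV classification, spike-count histograms, duty cycle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m1beta.datamodel import AnalysisWindow, SpikeTrainSet
from m1beta.metrics import (SpikeCountHistogram, duty_cycle, extract_periods,
                            firing_rates, isi_cv, spike_count_histogram)


def _hist_from_rate(rate_fn, duration=2.0, bin_s=0.002):
    edges = np.arange(0, duration + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SpikeCountHistogram(edges, rate_fn(centers))


class TestFiringRates:
    def test_rate_arithmetic(self):
        sts = SpikeTrainSet.from_trains(
            {0: np.linspace(0.05, 2.25, 23)}, AnalysisWindow(0.0, 2.3),
            population="PT5B")
        out = firing_rates(sts)
        assert out.loc[0, "mean_rate"] == pytest.approx(10.0)

    def test_silent_population_zero(self):
        sts = SpikeTrainSet.from_trains({0: [], 1: []},
                                        AnalysisWindow(0.0, 1.0))
        out = firing_rates(sts)
        assert out.loc[0, "mean_rate"] == 0.0
        assert out.loc[0, "sd_rate"] == 0.0

    def test_additive_over_disjoint_windows(self, labeled_set):
        """count(w1) + count(w2) = count(w1 ∪ w2) for adjacent windows."""
        w1, w2 = AnalysisWindow(0.0, 1.0), AnalysisWindow(1.0, 2.0)
        full = AnalysisWindow(0.0, 2.0)
        r1 = firing_rates(labeled_set, w1).set_index("population")
        r2 = firing_rates(labeled_set, w2).set_index("population")
        rf = firing_rates(labeled_set, full).set_index("population")
        for pop in rf.index:
            total = r1.loc[pop, "mean_rate"] * 1.0 + r2.loc[pop, "mean_rate"] * 1.0
            assert total == pytest.approx(rf.loc[pop, "mean_rate"] * 2.0)


class TestIsiCv:
    def test_periodic_train_is_regular(self):
        sts = SpikeTrainSet.from_trains({0: np.arange(0.1, 9.9, 0.1)},
                                        AnalysisWindow(0.0, 10.0))
        report = isi_cv(sts)
        assert report.per_neuron["cv"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert report.regular_fraction == 1.0

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(3)
        isi = rng.exponential(0.05, 4000)
        times = np.cumsum(isi)
        sts = SpikeTrainSet.from_trains({0: times},
                                        AnalysisWindow(0.0, times[-1] + 1))
        report = isi_cv(sts)
        assert report.per_neuron["cv"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert report.irregular_fraction == 1.0

    def test_short_trains_excluded_and_counted(self):
        sts = SpikeTrainSet.from_trains({0: [0.1, 0.2], 1: [0.1, 0.2, 0.3]},
                                        AnalysisWindow(0.0, 1.0))
        report = isi_cv(sts)
        assert report.n_excluded == 1
        assert len(report.per_neuron) == 1


class TestSpikeCountHistogram:
    def test_empty_set_all_zero(self):
        sts = SpikeTrainSet.from_trains({0: []}, AnalysisWindow(0.0, 0.1))
        h = spike_count_histogram(sts)
        assert h.counts.sum() == 0

    def test_conserves_total_count(self, labeled_set):
        h = spike_count_histogram(labeled_set)
        assert h.counts.sum() == labeled_set.n_spikes

    def test_matches_brute_force(self, toy_set):
        h = spike_count_histogram(toy_set, bin_s=0.002)
        brute = np.zeros(h.counts.size)
        for t in toy_set.spike_times:
            brute[min(int(t / 0.002), brute.size - 1)] += 1
        assert np.array_equal(h.counts, brute)


class TestExtractPeriods:
    def test_sinusoid_period(self):
        """20 Hz sinusoidal rate: mean period 50 +/- 2 ms."""
        h = _hist_from_rate(lambda t: 50 * (1 + np.sin(2 * np.pi * 20 * t)))
        periods = extract_periods(h)
        assert np.mean([p.period for p in periods]) == \
            pytest.approx(0.050, abs=0.002)

    def test_flat_histogram_no_periods(self):
        h = _hist_from_rate(lambda t: np.full_like(t, 7.0))
        assert extract_periods(h) == []

    def test_square_wave_exact_periods(self):
        h = _hist_from_rate(
            lambda t: np.where((t * 10) % 1.0 < 0.5, 40.0, 0.0), duration=1.0)
        periods = extract_periods(h, smoothing_bins=0)
        for p in periods:
            assert p.period == pytest.approx(0.1, abs=0.002)

    def test_additive_offset_leaves_periods_unchanged(self):
        base = _hist_from_rate(lambda t: 30 * (1 + np.sin(2 * np.pi * 15 * t)))
        shifted = SpikeCountHistogram(base.edges, base.counts + 100.0)
        p0 = extract_periods(base)
        p1 = extract_periods(shifted)
        assert len(p0) == len(p1)
        for a, b in zip(p0, p1):
            assert a.t_start == pytest.approx(b.t_start, abs=1e-9)
            assert a.above_half_duration == \
                pytest.approx(b.above_half_duration, abs=1e-9)


class TestDutyCycle:
    @pytest.mark.parametrize("phi", [0.25, 0.3, 0.5])
    def test_square_wave_duty(self, phi):
        h = _hist_from_rate(
            lambda t: np.where((t * 15) % 1.0 < phi, 40.0, 0.0))
        assert duty_cycle(extract_periods(h)) == \
            pytest.approx(100 * phi, abs=2.0)

    def test_sinusoid_duty_is_half(self):
        h = _hist_from_rate(lambda t: 30 * (1 + np.sin(2 * np.pi * 20 * t)))
        assert duty_cycle(extract_periods(h)) == pytest.approx(50.0, abs=2.0)

    def test_no_periods_raises(self):
        with pytest.raises(ValueError):
            duty_cycle([])

    @settings(deadline=None, max_examples=20)
    @given(st.floats(1.5, 40.0), st.floats(5.0, 30.0))
    def test_bounded_and_scale_invariant(self, scale, freq):
        """Duty in [0, 100]; invariant under count rescaling."""
        h = _hist_from_rate(
            lambda t: 20 * (1 + np.sin(2 * np.pi * freq * t)))
        d0 = duty_cycle(extract_periods(h))
        hs = SpikeCountHistogram(h.edges, h.counts * scale)
        d1 = duty_cycle(extract_periods(hs))
        assert 0.0 <= d0 <= 100.0
        assert d1 == pytest.approx(d0, abs=1e-6)
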