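"""Coincidence detection and the unitary-event joint-surprise statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m1beta.datamodel import AnalysisWindow, SpikeTrainSet
from m1beta.synchrony import (detect_coincidences, epoch_frequency,
                              expected_coincidences, joint_surprise,
                              sliding_ue)
from m1beta.synth import (CoincidenceInjectionSpec, OscillatoryRateSpec,
                          gen_inhomogeneous_poisson, inject_coincidences)


def brute_force(trains: dict, t_stop: float, bin_s: float = 0.001):
    """Exhaustive per-bin enumeration: (distinct neurons, spikes) per bin."""
    n_bins = max(1, int(np.ceil(t_stop / bin_s - 1e-9)))
    active = np.zeros(n_bins, dtype=int)
    spikes = np.zeros(n_bins, dtype=int)
    for _, ts in trains.items():
        seen = set()
        for t in ts:
            b = min(int(t / bin_s), n_bins - 1)
            spikes[b] += 1
            if b not in seen:
                active[b] += 1
                seen.add(b)
    return active, spikes


class TestDetectCoincidences:
    def test_single_neuron_no_coincidences(self):
        sts = SpikeTrainSet.from_trains({0: [0.001, 0.002, 0.003]},
                                        AnalysisWindow(0.0, 0.01))
        series = detect_coincidences(sts)
        assert series.proportion_spikes == 0.0
        assert not series.coincident.any()

    def test_identical_trains_all_participate(self):
        ts = [0.0015, 0.0105, 0.0203]
        sts = SpikeTrainSet.from_trains({0: ts, 1: ts},
                                        AnalysisWindow(0.0, 0.05))
        series = detect_coincidences(sts)
        assert series.proportion_spikes == 1.0

    def test_toy_set_matches_enumeration(self, toy_set):
        series = detect_coincidences(toy_set)
        active, spikes = brute_force(toy_set.trains(), 0.05)
        assert np.array_equal(series.n_active, active)
        assert np.array_equal(series.spikes_per_bin, spikes)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_random_toy_sets_match_enumeration(self, seed):
        """Exact agreement with exhaustive counting, <=5 neurons x <=50 bins."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        t_stop = float(rng.uniform(0.005, 0.05))
        trains = {i: np.sort(rng.uniform(0, t_stop, rng.integers(0, 15)))
                  for i in range(n)}
        sts = SpikeTrainSet.from_trains(trains, AnalysisWindow(0.0, t_stop))
        series = detect_coincidences(sts)
        active, spikes = brute_force(sts.trains(), t_stop)
        assert np.array_equal(series.n_active, active)
        assert np.array_equal(series.spikes_per_bin, spikes)


class TestExpectedCoincidences:
    def test_zero_rates(self):
        assert expected_coincidences(np.zeros(5), 0.001, 0.1) == 0.0

    def test_two_neuron_closed_form(self):
        """2 neurons at 10 Hz, 1 ms bins, 100 ms window: 100 * (0.01)^2."""
        n_exp = expected_coincidences(np.array([10.0, 10.0]), 0.001, 0.1)
        assert n_exp == pytest.approx(100 * 0.01 ** 2, rel=1e-9)

    def test_rate_too_high_rejected(self):
        with pytest.raises(ValueError):
            expected_coincidences(np.array([2000.0]), 0.001, 0.1)

    def test_matches_monte_carlo_heterogeneous(self):
        """Bernoulli-bin Monte-Carlo agrees within 3 sd (scaled probe; the
        full-size run lives in the acceptance suite)."""
        rates = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        n_exp = expected_coincidences(rates, 0.001, 0.1)
        rng = np.random.default_rng(17)
        m = 200_000
        hits = 0
        p = rates * 0.001
        for _ in range(10):
            x = rng.random((m // 10, 100, rates.size)) < p
            hits += int(((x.sum(axis=2) >= 2).sum()))
        mc = hits / m
        sd = np.sqrt(n_exp / m)
        assert abs(mc - n_exp) < 3 * sd


class TestJointSurprise:
    def test_zero_empirical(self):
        p, s = joint_surprise(0, 1.5)
        assert p == 1.0 and s <= -100

    def test_poisson_tail_example(self):
        """n_emp=5, n_exp=1: p = P(X>=5) ~ 0.00366, S ~ 2.43."""
        p, s = joint_surprise(5, 1.0)
        assert p == pytest.approx(0.003660, abs=2e-5)
        assert s == pytest.approx(2.435, abs=0.01)

    def test_p_monotone_in_empirical_count(self):
        ps = [joint_surprise(k, 2.0)[0] for k in range(0, 15)]
        assert all(a >= b for a, b in zip(ps[:-1], ps[1:]))

    def test_impossible_observation_floors(self):
        p, s = joint_surprise(3, 0.0)
        assert 0 < p < 1e-100 and s >= 100


class TestSlidingUE:
    def test_injection_raises_significant_fraction(self):
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=0.5, duration=10.0), 50, seed=6)
        inj = inject_coincidences(
            base, CoincidenceInjectionSpec(event_rate=5.0,
                                           participating_fraction=0.04),
            seed=7)
        assert sliding_ue(inj).total_significant_s > \
            sliding_ue(base).total_significant_s

    def test_significant_duration_monotone_in_injection_rate(self):
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=0.5, duration=10.0), 50, seed=6)
        totals = []
        for rate in (0.0, 5.0, 20.0):
            s = base if rate == 0 else inject_coincidences(
                base, CoincidenceInjectionSpec(event_rate=rate,
                                               participating_fraction=0.04),
                seed=7)
            totals.append(sliding_ue(s).total_significant_s)
        assert totals[0] <= totals[1] <= totals[2]

    def test_fdr_correction_never_adds_significance(self):
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=0.5, duration=10.0), 50, seed=6)
        inj = inject_coincidences(
            base, CoincidenceInjectionSpec(event_rate=10.0,
                                           participating_fraction=0.04),
            seed=7)
        plain = sliding_ue(inj)
        corrected = sliding_ue(inj, fdr=True)
        assert corrected.total_significant_s <= plain.total_significant_s
        assert (corrected.windows["p"] >= plain.windows["p"] - 1e-12).all()

    def test_window_shorter_than_data_required(self):
        sts = SpikeTrainSet.from_trains({0: [0.01]}, AnalysisWindow(0.0, 0.05))
        with pytest.raises(ValueError):
            sliding_ue(sts)

    def test_epochs_non_overlapping_and_bounded(self):
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=1.0, duration=8.0), 40, seed=8)
        inj = inject_coincidences(
            base, CoincidenceInjectionSpec(event_rate=10.0,
                                           participating_fraction=0.05),
            seed=9)
        res = sliding_ue(inj)
        for a, b in zip(res.epochs[:-1], res.epochs[1:]):
            assert b.t_start > a.t_stop
        assert res.total_significant_s <= res.analysis_window.duration + 1e-9


class TestEpochFrequency:
    def test_recovers_periodic_injection_frequency(self):
        """Coincidences injected at exactly 15 Hz read back at 15 +/- 0.5."""
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=0.5, duration=10.0), 50, seed=6)
        inj = inject_coincidences(
            base, CoincidenceInjectionSpec(event_rate=15.0,
                                           participating_fraction=0.04,
                                           periodic=True), seed=7)
        res = sliding_ue(inj)
        freq, _ = epoch_frequency(res.series, res.epochs)
        assert freq == pytest.approx(15.0, abs=0.5)

    def test_single_peak_epochs_excluded(self):
        base = gen_inhomogeneous_poisson(
            OscillatoryRateSpec(baseline=0.5, duration=10.0), 50, seed=10)
        res = sliding_ue(base)
        _, table = epoch_frequency(res.series, res.epochs)
        # whatever epochs arise from noise, the exclusion flag is honored
        assert (table.loc[~table["used"], "freq_hz"].isna()).all()
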