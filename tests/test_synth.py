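"""Ground-truth generators: rate fidelity, injections, phantoms."""

import numpy as np
import pytest

from m1beta.synth import (CoincidenceInjectionSpec, CurrentPhantomSpec,
                          OscillatoryRateSpec, gen_current_phantom,
                          gen_inhomogeneous_poisson, inject_coincidences)


class TestOscillatoryRateSpec:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            OscillatoryRateSpec(baseline=-1.0)

    def test_square_mean_rate_is_baseline(self):
        spec = OscillatoryRateSpec(baseline=10.0, osc_freq=20.0,
                                   duty_shape="square", on_fraction=0.25)
        t = np.linspace(0, 1, 100001)
        assert np.mean(spec.rate(t)) == pytest.approx(10.0, rel=0.01)

    def test_rate_non_negative_everywhere(self):
        spec = OscillatoryRateSpec(baseline=5.0, modulation_depth=1.0,
                                   osc_freq=15.0)
        t = np.linspace(0, 2, 50001)
        assert np.all(spec.rate(t) >= 0)


class TestInhomogeneousPoisson:
    def test_mean_count_matches_poisson(self):
        """200 neurons x 10 Hz x 10 s: population-mean count ~ 100."""
        spec = OscillatoryRateSpec(baseline=10.0, duration=10.0)
        sts = gen_inhomogeneous_poisson(spec, 200, seed=1)
        counts = np.array([len(t) for t in sts.trains().values()])
        se = 3 * np.sqrt(100) / np.sqrt(200)
        assert abs(counts.mean() - 100.0) < se

    def test_zero_baseline_gives_no_spikes(self):
        spec = OscillatoryRateSpec(baseline=0.0, duration=5.0)
        assert gen_inhomogeneous_poisson(spec, 50, seed=2).n_spikes == 0

    def test_fixed_seed_reproducible(self):
        spec = OscillatoryRateSpec(baseline=8.0, modulation_depth=0.5,
                                   osc_freq=20.0, duration=3.0)
        a = gen_inhomogeneous_poisson(spec, 30, seed=9)
        b = gen_inhomogeneous_poisson(spec, 30, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_neuron_ids, b.spike_neuron_ids)

    def test_empirical_rate_converges(self):
        """Relative error < 5% beyond ~1e4 expected spikes."""
        spec = OscillatoryRateSpec(baseline=20.0, modulation_depth=0.8,
                                   osc_freq=15.0, duration=10.0)
        sts = gen_inhomogeneous_poisson(spec, 100, seed=3)
        rate = sts.n_spikes / (100 * 10.0)
        assert rate == pytest.approx(20.0, rel=0.05)

    def test_square_duty_shape_feeds_duty_estimate(self):
        """Construction check: 30% on-fraction recovered downstream."""
        from m1beta.metrics import (duty_cycle, extract_periods,
                                    spike_count_histogram)
        spec = OscillatoryRateSpec(baseline=12.0, osc_freq=15.0,
                                   duty_shape="square", on_fraction=0.3,
                                   duration=10.0)
        sts = gen_inhomogeneous_poisson(spec, 2500, seed=4)
        periods = extract_periods(spike_count_histogram(sts))
        assert duty_cycle(periods) == pytest.approx(30.0, abs=2.0)


class TestInjectCoincidences:
    def test_zero_rate_returns_input(self, poisson_population):
        spec = CoincidenceInjectionSpec(event_rate=0.0)
        assert inject_coincidences(poisson_population, spec, seed=1) \
            is poisson_population

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            CoincidenceInjectionSpec(event_rate=1.0, jitter_ms=-1.0)

    def test_event_count_poisson_lower_bound(self, poisson_population):
        """5 Hz x 10 s events, half the population each: the number of
        >=2-neuron bins exceeds the Poisson 3-sigma lower bound."""
        from m1beta.synchrony import detect_coincidences
        spec = OscillatoryRateSpec(baseline=10.0, duration=10.0)
        base = gen_inhomogeneous_poisson(spec, 20, seed=11)
        inj = inject_coincidences(
            base, CoincidenceInjectionSpec(event_rate=5.0,
                                           participating_fraction=0.5), seed=12)
        n_coinc = int(detect_coincidences(inj).coincident.sum())
        lower = 50 - 3 * np.sqrt(50)  # injected events alone
        assert n_coinc >= lower

    def test_coincident_bins_monotone_under_injection(self, poisson_population):
        from m1beta.synchrony import detect_coincidences
        before = int(detect_coincidences(poisson_population).coincident.sum())
        inj = inject_coincidences(
            poisson_population,
            CoincidenceInjectionSpec(event_rate=3.0, participating_fraction=0.5),
            seed=5)
        after = int(detect_coincidences(inj).coincident.sum())
        assert after >= before

    def test_spikes_added_not_moved(self, poisson_population):
        inj = inject_coincidences(
            poisson_population,
            CoincidenceInjectionSpec(event_rate=2.0, participating_fraction=0.2),
            seed=6)
        orig = set(np.round(poisson_population.spike_times, 6))
        new = set(np.round(inj.spike_times, 6))
        assert orig <= new


class TestCurrentPhantom:
    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="nonzero length"):
            CurrentPhantomSpec((0, 0, 0), (0, 0, 0))

    def test_zero_current_zero_potential(self):
        spec = CurrentPhantomSpec((0, 0, 0), (0, 100, 0),
                                  current_nA=np.zeros(10))
        *_, line_pot, point_pot = gen_current_phantom(spec)
        assert np.all(line_pot(np.array([200.0, 50.0, 0.0])) == 0)
        assert np.all(point_pot(np.array([200.0, 50.0, 0.0])) == 0)

    def test_point_source_closed_form(self):
        """V = I / (4 pi sigma r) for a short segment at distance r."""
        spec = CurrentPhantomSpec((0, 0, 0), (0, 0.01, 0),
                                  current_nA=np.array([1.0]), sigma=0.3)
        *_, point_pot = gen_current_phantom(spec)
        r = 100.0
        expected = 1.0 / (4 * np.pi * 0.3 * r)
        assert point_pot(np.array([r, 0.005, 0.0]))[0] == \
            pytest.approx(expected, rel=1e-6)

    def test_line_matches_point_in_far_field(self):
        """Agreement within 0.5% at 50x the segment length."""
        spec = CurrentPhantomSpec((0, 0, 0), (0, 20, 0),
                                  current_nA=np.array([2.5]))
        *_, line_pot, point_pot = gen_current_phantom(spec)
        e = np.array([1000.0, 10.0, 0.0])  # 50 x 20 um
        assert line_pot(e)[0] == pytest.approx(point_pot(e)[0], rel=0.005)
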