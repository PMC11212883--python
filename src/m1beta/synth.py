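"""Ground-truth synthetic data: oscillating spike trains, injected
coincidences, and line-current phantoms.

Every downstream analysis stage (duty cycle, burst detection, unitary-event
synchrony, LFP forward model) is tested against data produced here, where the
oscillation frequency, modulation depth, duty-cycle on-fraction, coincidence
rate and extracellular potential are all known by construction.

Spike trains are inhomogeneous Poisson processes generated by thinning
against the rate maximum, which is exact for any bounded rate function.
Injected coincidences are *added* spikes (never displaced ones), so the
marginal rate of each train stays analytically known up to the small
additive term.  All generators take an integer seed; sub-streams are derived
by splitting a :class:`numpy.random.SeedSequence`, so a fixed seed gives
byte-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .datamodel import AnalysisWindow, SpikeTrainSet, TIME_RESOLUTION

__all__ = [
    "OscillatoryRateSpec",
    "CoincidenceInjectionSpec",
    "CurrentPhantomSpec",
    "gen_inhomogeneous_poisson",
    "inject_coincidences",
    "gen_current_phantom",
]

DutyShape = Literal["sinusoid", "rectified", "square"]


@dataclass(frozen=True)
class OscillatoryRateSpec:
    """Rate function ``r(t)`` for an oscillating population.

    ``sinusoid``: ``baseline * (1 + m * sin(2π f t))``.
    ``rectified``: sinusoid thresholded at ``theta`` (sub-threshold part set
    to the threshold level), giving sharper peaks.
    ``square``: rate ``baseline/on_fraction`` during the first
    ``on_fraction`` of each cycle and 0 otherwise, so the *mean* rate stays
    ``baseline`` and the duty cycle equals ``on_fraction`` by construction.
    """

    baseline: float  # Hz; time-averaged rate
    modulation_depth: float = 0.0  # in [0, 1]
    osc_freq: float = 0.0  # Hz
    duty_shape: DutyShape = "sinusoid"
    on_fraction: float = 0.5  # square shape only
    threshold: float = 0.0  # rectified shape only, as a fraction of baseline
    duration: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline rate must be >= 0")
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.osc_freq < 0 or self.duration <= 0:
            raise ValueError("osc_freq >= 0 and duration > 0 required")
        if self.duty_shape == "square" and not 0 < self.on_fraction <= 1:
            raise ValueError("on_fraction must lie in (0, 1]")

    def rate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the (non-negative) rate function at times ``t``."""
        t = np.asarray(t, dtype=float)
        if self.osc_freq == 0 or self.modulation_depth == 0 and self.duty_shape != "square":
            return np.full_like(t, self.baseline)
        if self.duty_shape == "sinusoid":
            return self.baseline * (1 + self.modulation_depth *
                                    np.sin(2 * np.pi * self.osc_freq * t))
        if self.duty_shape == "rectified":
            raw = np.sin(2 * np.pi * self.osc_freq * t)
            raw = np.maximum(raw, self.threshold)
            return self.baseline * (1 + self.modulation_depth * raw)
        # square: on during the first on_fraction of each cycle
        phase = (t * self.osc_freq) % 1.0
        on = phase < self.on_fraction
        return np.where(on, self.baseline / self.on_fraction, 0.0)

    @property
    def rate_max(self) -> float:
        if self.duty_shape == "square" and self.osc_freq > 0:
            return self.baseline / self.on_fraction
        return self.baseline * (1 + self.modulation_depth)


def gen_inhomogeneous_poisson(
    spec: OscillatoryRateSpec,
    n_neurons: int,
    seed: int,
    population: str = "synthetic",
) -> SpikeTrainSet:
    """Independent inhomogeneous-Poisson spike trains by thinning.

    Candidate spikes are drawn homogeneously at ``spec.rate_max`` and kept
    with probability ``rate(t) / rate_max``; per-neuron counts are Poisson
    with mean equal to the time-integral of the rate.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    window = AnalysisWindow(0.0, spec.duration)
    streams = np.random.SeedSequence(seed).spawn(n_neurons)
    rmax = spec.rate_max
    trains: dict[int, np.ndarray] = {}
    for nid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if rmax <= 0:
            trains[nid] = np.empty(0)
            continue
        n_cand = rng.poisson(rmax * spec.duration)
        cand = np.sort(rng.uniform(0.0, spec.duration, n_cand))
        keep = rng.uniform(0.0, rmax, n_cand) < spec.rate(cand)
        trains[nid] = _dedupe(cand[keep])
    return SpikeTrainSet.from_trains(trains, window, population=population)


def _dedupe(times: np.ndarray) -> np.ndarray:
    """Drop spikes closer than the storage resolution to their predecessor."""
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) >= TIME_RESOLUTION])
    return times[keep]


@dataclass(frozen=True)
class CoincidenceInjectionSpec:
    """Above-chance population coincidences to superimpose on spike trains.

    At each event time a random subset of ``ceil(participating_fraction * n)``
    neurons receives one extra spike within ``±jitter_ms``.  Event times are
    Poisson with rate ``event_rate`` by default, or an exact periodic comb
    when ``periodic`` is set (useful when the downstream test must recover
    the injection frequency).
    """

    event_rate: float  # Hz
    participating_fraction: float = 0.5
    jitter_ms: float = 0.0
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if not 0 < self.participating_fraction <= 1:
            raise ValueError("participating_fraction must lie in (0, 1]")
        if self.jitter_ms < 0:
            raise ValueError("jitter must be >= 0")


def inject_coincidences(
    sts: SpikeTrainSet,
    spec: CoincidenceInjectionSpec,
    seed: int,
) -> SpikeTrainSet:
    """Return a copy of ``sts`` with injected population coincidences.

    Spikes are added, never moved; with ``event_rate == 0`` the input is
    returned unchanged.
    """
    if spec.event_rate == 0:
        return sts
    n = sts.n_neurons
    k = int(np.ceil(spec.participating_fraction * n))
    if k < 2:
        raise ValueError("participating_fraction x n_neurons must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = sts.window
    if spec.periodic:
        period = 1.0 / spec.event_rate
        events = np.arange(w.t_start + period / 2, w.t_stop, period)
    else:
        n_ev = rng.poisson(spec.event_rate * w.duration)
        events = np.sort(rng.uniform(w.t_start, w.t_stop, n_ev))
    neuron_ids = sts.neurons["neuron_id"].to_numpy()
    add_ids, add_times = [], []
    half = spec.jitter_ms * 1e-3
    for t in events:
        members = rng.choice(neuron_ids, size=k, replace=False)
        if half > 0:
            ts = t + rng.uniform(-half, half, k)
        else:
            ts = np.full(k, t)
        ts = np.clip(ts, w.t_start, w.t_stop - TIME_RESOLUTION)
        add_ids.append(members)
        add_times.append(ts)
    ids = np.concatenate([sts.spike_neuron_ids] + add_ids)
    times = np.concatenate([sts.spike_times] + add_times)
    # collapse storage-resolution duplicates per neuron introduced by injection
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    dup = (np.diff(ids) == 0) & (np.diff(times) < TIME_RESOLUTION)
    keep = np.concatenate([[True], ~dup])
    return SpikeTrainSet(sts.neurons.copy(), ids[keep], times[keep], w)


# ---------------------------------------------------------------------------
# line-current phantoms for the LFP forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentPhantomSpec:
    """A single uniform line-current source with a known waveform.

    ``start_um``/``end_um`` are the segment endpoints (µm); ``current_nA``
    is the waveform sampled at ``fs`` Hz; ``sigma`` is the extracellular
    conductivity (mS/mm; numerically equal to S/m).
    """

    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    current_nA: np.ndarray = field(default_factory=lambda: np.ones(1))
    fs: float = 1000.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        a = np.asarray(self.start_um, float)
        b = np.asarray(self.end_um, float)
        if not np.isfinite(a).all() or not np.isfinite(b).all():
            raise ValueError("segment endpoints must be finite")
        if np.linalg.norm(b - a) == 0:
            raise ValueError("segment must have nonzero length")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(
            np.asarray(self.end_um, float) - np.asarray(self.start_um, float)))


def gen_current_phantom(spec: CurrentPhantomSpec) -> tuple[
    np.ndarray, np.ndarray, Callable[[np.ndarray], np.ndarray],
    Callable[[np.ndarray], np.ndarray],
]:
    """Phantom bundle: segment geometry, currents, and exact potentials.

    Returns ``(segments, currents, line_potential, point_potential)`` where
    ``segments`` is ``(1, 2, 3)`` µm endpoints, ``currents`` is
    ``(1, n_samples)`` nA, and the two callables map an electrode position
    (µm) to the exact potential time series in mV for (a) the uniform line
    source (log closed form) and (b) an equivalent point source at the
    segment midpoint, ``V = I / (4 π σ r)``.
    """
    a = np.asarray(spec.start_um, float)
    b = np.asarray(spec.end_um, float)
    current = np.atleast_1d(np.asarray(spec.current_nA, float))
    segments = np.stack([a, b])[None, :, :]
    currents = current[None, :]
    # unit conversion: nA / (S/m * um) -> mV  is a factor of 1.0
    #   V = I[A] / (4 pi sigma[S/m] d[m]) = 1e-9 I[nA] / (4 pi sigma * 1e-6 d[um])
    #     = 1e-3 * I[nA] / (4 pi sigma d[um])  volts  = I[nA]/(4 pi sigma d[um]) mV
    def point_potential(electrode_um: np.ndarray) -> np.ndarray:
        e = np.asarray(electrode_um, float)
        mid = 0.5 * (a + b)
        r = float(np.linalg.norm(e - mid))
        return current / (4 * np.pi * spec.sigma * r)

    def line_potential(electrode_um: np.ndarray) -> np.ndarray:
        e = np.asarray(electrode_um, float)
        axis = b - a
        length = float(np.linalg.norm(axis))
        u = axis / length
        # h: axial coordinate of electrode relative to segment end b
        # (Holt & Koch closed form for a uniform line source)
        s = float(np.dot(e - a, u))
        r = float(np.linalg.norm((e - a) - s * u))
        h = s - length  # position past the far end
        l_ = s
        num = np.hypot(h, r) - h
        den = np.hypot(l_, r) - l_
        factor = np.log(num / den) / length
        return current * factor / (4 * np.pi * spec.sigma)

    return segments, currents, line_potential, point_potential
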