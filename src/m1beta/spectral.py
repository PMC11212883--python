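"""Time-frequency analysis of LFP: Morlet spectrograms, band power, and
beta-burst statistics.

The spectrogram is a complex Morlet wavelet transform (MNE backend) with a
fixed number of cycles per frequency (default 6), evaluated on a
log-spaced 1–80 Hz grid.  Power units are arbitrary but consistent across
recordings analysed with the same settings, which is what the
between-condition comparisons need.

Bursts in a band-power time series are maximal supra-threshold intervals
of at least ``min_duration`` (default 50 ms).  The default threshold is
the 75th percentile of the series, a scale-free rule that transfers across
conditions with very different absolute power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import LFPRecording

__all__ = [
    "SpectrogramResult",
    "BurstEvent",
    "BurstStatistics",
    "spectrogram",
    "band_power",
    "detect_bursts",
    "BETA_BAND",
]

BETA_BAND = (13.0, 30.0)
DEFAULT_MIN_BURST_S = 0.050
DEFAULT_THRESHOLD_PERCENTILE = 75.0


@dataclass
class SpectrogramResult:
    """Time-frequency power: ``power[f, t]`` on strictly increasing axes."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("axes must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class BurstEvent:
    """One supra-threshold band-power excursion."""

    band: tuple[float, float]
    t_start: float
    duration: float
    peak_power: float


@dataclass
class BurstStatistics:
    """Detected bursts with rate and duration summaries."""

    events: list[BurstEvent]
    analysis_duration: float

    @property
    def rate_hz(self) -> float:
        return len(self.events) / self.analysis_duration

    @property
    def mean_duration_s(self) -> float:
        if not self.events:
            return float("nan")
        return float(np.mean([e.duration for e in self.events]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"band_lo": e.band[0], "band_hi": e.band[1], "t_start": e.t_start,
              "duration": e.duration, "peak_power": e.peak_power}
             for e in self.events],
            columns=["band_lo", "band_hi", "t_start", "duration", "peak_power"],
        )


def default_freq_grid(f_lo: float = 1.0, f_hi: float = 80.0, n: int = 60) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n)


def spectrogram(
    lfp: LFPRecording,
    channel: int = 0,
    freqs: np.ndarray | None = None,
    n_cycles: float = 6.0,
) -> SpectrogramResult:
    """Morlet-wavelet power spectrogram of one LFP channel.

    ``n_cycles`` sets the wavelet width (time-frequency tradeoff).  The
    frequency grid must stay below the Nyquist frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        # keep every wavelet shorter than the signal: a Morlet atom at
        # frequency f with n cycles spans ~10 sigma_t = 10 n/(2 pi f) seconds
        duration = lfp.samples.shape[0] / lfp.fs
        f_lo = max(1.0, 1.7 * n_cycles / duration)
        freqs = default_freq_grid(f_lo=f_lo, f_hi=min(80.0, lfp.fs / 2 * 0.95))
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > lfp.fs / 2:
        raise ValueError(
            f"frequency grid up to {freqs.max()} Hz exceeds Nyquist ({lfp.fs / 2} Hz)"
        )
    x = lfp.samples[:, channel][None, None, :]
    power = tfr_array_morlet(x, sfreq=lfp.fs, freqs=freqs,
                             n_cycles=n_cycles, output="power", zero_mean=True,
                             verbose="error")[0, 0]
    return SpectrogramResult(lfp.times, freqs, power)


def band_power(spec: SpectrogramResult, band: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Band power vs time (mean over in-band frequencies) and its time mean."""
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    series = spec.power[mask].mean(axis=0)
    return series, float(series.mean())


def detect_bursts(
    power_series: np.ndarray,
    times: np.ndarray,
    band: tuple[float, float] = BETA_BAND,
    threshold: float | None = None,
    threshold_percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
    min_duration_s: float = DEFAULT_MIN_BURST_S,
) -> BurstStatistics:
    """Maximal supra-threshold intervals of a band-power series.

    A burst is a run of samples strictly above threshold lasting at least
    ``min_duration_s``; the burst rate is count / analysis duration.
    """
    y = np.asarray(power_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size != t.size:
        raise ValueError("power series and times must be aligned")
    duration = t[-1] - t[0] + (t[1] - t[0] if t.size > 1 else 0.0)
    if duration < min_duration_s:
        raise ValueError("series shorter than the minimum burst duration")
    if threshold is None:
        threshold = float(np.percentile(y, threshold_percentile))
    above = y > threshold
    events: list[BurstEvent] = []
    i = 0
    n = y.size
    dt = t[1] - t[0] if n > 1 else 0.0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            dur = (j - i) * dt
            if dur >= min_duration_s:
                events.append(BurstEvent(band, float(t[i]), float(dur),
                                         float(y[i:j].max())))
            i = j
        else:
            i += 1
    return BurstStatistics(events, float(duration))
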