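"""Firing-rate, ISI-variability, spike-count-histogram and duty-cycle
statistics.

Population activity is summarised by a spike-count histogram (SCH): spikes
from all neurons of a population summed in fixed 2 ms bins.  Oscillation
periods are read off the SCH at the half-height between its minimum and
maximum: a period runs from one rising half-height crossing to the next, and
the duty cycle is the percentage of the period spent above half height.
Crossing times are linearly interpolated between bins; the histogram is
smoothed with a short Gaussian kernel first, since raw 2 ms bins are too
noisy for unique crossings.

Interspike-interval regularity is quantified by the coefficient of
variation CV = sd(ISI)/mean(ISI); neurons with CV <= 0.5 are classed as
regular and CV > 0.5 as irregular.  Neurons with fewer than 3 spikes carry
no defined CV and are excluded (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datamodel import AnalysisWindow, SpikeTrainSet

__all__ = [
    "SpikeCountHistogram",
    "OscillationPeriod",
    "CVReport",
    "firing_rates",
    "isi_cv",
    "spike_count_histogram",
    "extract_periods",
    "duty_cycle",
]

CV_REGULAR_THRESHOLD = 0.5
DEFAULT_BIN_S = 0.002


@dataclass
class SpikeCountHistogram:
    """Population-summed spike counts in fixed-width bins."""

    edges: np.ndarray  # (n_bins + 1,) seconds
    counts: np.ndarray  # (n_bins,)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class OscillationPeriod:
    """One oscillation cycle, delimited by consecutive rising half-height
    crossings of the smoothed spike-count histogram."""

    t_start: float
    t_end: float
    above_half_duration: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not 0 <= self.above_half_duration <= self.t_end - self.t_start + 1e-12:
            raise ValueError("above-half duration must lie within the period")

    @property
    def period(self) -> float:
        return self.t_end - self.t_start


@dataclass
class CVReport:
    """Per-neuron ISI coefficient of variation and regularity split."""

    per_neuron: pd.DataFrame  # columns: neuron_id, cv
    n_excluded: int  # neurons with < 3 spikes

    @property
    def mean(self) -> float:
        return float(self.per_neuron["cv"].mean()) if len(self.per_neuron) else float("nan")

    @property
    def sd(self) -> float:
        return float(self.per_neuron["cv"].std(ddof=0)) if len(self.per_neuron) else float("nan")

    @property
    def regular_fraction(self) -> float:
        if not len(self.per_neuron):
            return float("nan")
        return float((self.per_neuron["cv"] <= CV_REGULAR_THRESHOLD).mean())

    @property
    def irregular_fraction(self) -> float:
        if not len(self.per_neuron):
            return float("nan")
        return 1.0 - self.regular_fraction


def firing_rates(
    sts: SpikeTrainSet,
    window: AnalysisWindow | None = None,
    group_by: str = "population",
) -> pd.DataFrame:
    """Mean ± sd firing rate (spikes/s) per population.

    Per-neuron rate = spike count in ``window`` divided by its duration;
    silent neurons contribute zeros.  Returns a table with columns
    ``population, n_neurons, mean_rate, sd_rate``.
    """
    if window is None:
        window = sts.window
    if window.duration <= 0:
        raise ValueError("analysis window must have positive duration")
    keep = (sts.spike_times >= window.t_start) & (sts.spike_times < window.t_stop)
    counts = pd.Series(sts.spike_neuron_ids[keep]).value_counts()
    tab = sts.neurons[["neuron_id", group_by]].copy()
    tab["rate"] = tab["neuron_id"].map(counts).fillna(0.0) / window.duration
    rows = []
    for pop, grp in tab.groupby(group_by, sort=True):
        rows.append({
            group_by: pop,
            "n_neurons": len(grp),
            "mean_rate": float(grp["rate"].mean()),
            "sd_rate": float(grp["rate"].std(ddof=0)),
        })
    return pd.DataFrame(rows)


def per_neuron_rates(sts: SpikeTrainSet, window: AnalysisWindow | None = None) -> pd.DataFrame:
    """Per-neuron firing rates (spikes/s) with population labels."""
    if window is None:
        window = sts.window
    keep = (sts.spike_times >= window.t_start) & (sts.spike_times < window.t_stop)
    counts = pd.Series(sts.spike_neuron_ids[keep]).value_counts()
    tab = sts.neurons[["neuron_id", "population"]].copy()
    tab["rate"] = tab["neuron_id"].map(counts).fillna(0.0) / window.duration
    return tab


def isi_cv(sts: SpikeTrainSet, min_spikes: int = 3) -> CVReport:
    """ISI coefficient of variation per neuron with regular/irregular split."""
    rows = []
    excluded = 0
    for nid, times in sts.trains().items():
        if times.size < min_spikes:
            excluded += 1
            continue
        isi = np.diff(times)
        mean = isi.mean()
        if mean <= 0:
            excluded += 1
            continue
        rows.append({"neuron_id": nid, "cv": float(isi.std(ddof=0) / mean)})
    per_neuron = pd.DataFrame(rows, columns=["neuron_id", "cv"])
    return CVReport(per_neuron, excluded)


def spike_count_histogram(
    sts: SpikeTrainSet,
    bin_s: float = DEFAULT_BIN_S,
    window: AnalysisWindow | None = None,
) -> SpikeCountHistogram:
    """Population-summed spike counts in fixed bins (default 2 ms)."""
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if window is None:
        window = sts.window
    n_bins = max(1, int(np.ceil(window.duration / bin_s - 1e-9)))
    edges = window.t_start + np.arange(n_bins + 1) * bin_s
    keep = (sts.spike_times >= window.t_start) & (sts.spike_times < window.t_stop)
    counts, _ = np.histogram(sts.spike_times[keep], bins=edges)
    return SpikeCountHistogram(edges, counts)


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def extract_periods(
    hist: SpikeCountHistogram,
    smoothing_bins: float = 1.0,
) -> list[OscillationPeriod]:
    """Oscillation periods from half-height crossings of the smoothed SCH.

    The half-height level is (min + max)/2 of the smoothed counts over the
    whole window (a single global level, matching a horizontal half-height
    line across the histogram).  Each period spans consecutive rising
    crossings; its above-half duration is the time the smoothed counts spend
    above the level inside the period.  Crossing times are linearly
    interpolated.  A flat histogram yields no periods.
    """
    y = hist.counts.astype(float)
    if smoothing_bins > 0:
        y = gaussian_filter1d(y, sigma=smoothing_bins, mode="nearest")
    lo, hi = y.min(), y.max()
    if hi <= lo:
        return []
    level = 0.5 * (lo + hi)
    t = hist.centers
    above = y > level
    rising: list[float] = []
    crossings: list[tuple[float, int]] = []  # (time, +1 rising / -1 falling)
    for i in range(1, y.size):
        if above[i] and not above[i - 1]:
            crossings.append((_interp_crossing(t[i - 1], t[i], y[i - 1], y[i], level), +1))
        elif not above[i] and above[i - 1]:
            crossings.append((_interp_crossing(t[i - 1], t[i], y[i - 1], y[i], level), -1))
    rising = [tc for tc, kind in crossings if kind == +1]
    if len(rising) < 2:
        return []
    periods = []
    for a, b in zip(rising[:-1], rising[1:]):
        inside = [(tc, kind) for tc, kind in crossings if a <= tc <= b]
        # accumulate above-half time from the crossing sequence: the segment
        # from a rising crossing to the next falling crossing is "on"
        on = 0.0
        t_on = a
        state = True  # just crossed upward at a
        for tc, kind in inside[1:]:
            if kind == -1 and state:
                on += tc - t_on
                state = False
            elif kind == +1 and not state:
                t_on = tc
                state = True
        if state:
            on += b - t_on
        periods.append(OscillationPeriod(a, b, on))
    return periods


def duty_cycle(periods: list[OscillationPeriod]) -> float:
    """Percentage of an oscillation period spent above half height.

    Averaged across all supplied periods.  Requires at least one period.
    """
    if not periods:
        raise ValueError("duty cycle requires at least one oscillation period")
    fractions = [p.above_half_duration / p.period for p in periods]
    return 100.0 * float(np.mean(fractions))
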