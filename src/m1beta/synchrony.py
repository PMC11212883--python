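"""Population coincidence detection and unitary-event (joint-surprise)
analysis.

A *coincidence* is a 1 ms bin of the analysis window in which two or more
distinct neurons spike.  The unitary-event test asks, within each sliding
100 ms window, whether the number of coincident bins exceeds the count
expected if every neuron fired as an independent Poisson process at its
rate estimated *in that same window* ("frequency-matched").  Under that
null, with per-neuron bin probabilities ``p_i = r_i * delta``, the chance
that a bin holds spikes from >= 2 distinct neurons is

    q = 1 - prod(1 - p_i) - sum_i p_i * prod_{j != i}(1 - p_j)

so the expected coincident-bin count over a window of ``W/delta`` bins is
``n_exp = (W/delta) * q``.  The empirical count is compared with a Poisson
tail: ``p = P(X >= n_emp)`` for ``X ~ Poisson(n_exp)``, and the surprise is
``S = log10((1 - p)/p)``.  Windows with ``p < alpha`` are merged (by union
of their spans) into significant epochs; the oscillation frequency inside
an epoch is read off the peaks of the smoothed coincidence-count series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .datamodel import AnalysisWindow, SpikeTrainSet

__all__ = [
    "CoincidenceSeries",
    "Epoch",
    "CoincidenceResult",
    "detect_coincidences",
    "expected_coincidences",
    "joint_surprise",
    "sliding_ue",
    "epoch_frequency",
]

DEFAULT_BIN_S = 0.001
DEFAULT_WINDOW_S = 0.100
DEFAULT_STEP_S = 0.005
DEFAULT_ALPHA = 0.05
#: numerical floor for p-values (Poisson tail underflow)
P_FLOOR = 1e-300
#: cap applied to the surprise statistic when p underflows
S_CAP = 300.0


@dataclass
class CoincidenceSeries:
    """Per-bin coincidence flags on a fixed 1 ms grid.

    The grid origin is the analysis-window start.  ``n_active`` counts
    distinct neurons spiking per bin; a bin is coincident iff
    ``n_active >= 2``.  ``participating_spikes`` is the number of spikes
    falling in coincident bins, and ``proportion_spikes`` the fraction of
    all spikes that participate; ``proportion_bins`` is the fraction of
    bins that are coincident.
    """

    bin_s: float
    t_start: float
    n_active: np.ndarray  # distinct neurons per bin
    spikes_per_bin: np.ndarray  # total spikes per bin
    total_spikes: int

    @property
    def n_bins(self) -> int:
        return self.n_active.size

    @property
    def coincident(self) -> np.ndarray:
        return self.n_active >= 2

    @property
    def participating_spikes(self) -> int:
        return int(self.spikes_per_bin[self.coincident].sum())

    @property
    def proportion_spikes(self) -> float:
        return self.participating_spikes / self.total_spikes if self.total_spikes else 0.0

    @property
    def proportion_bins(self) -> float:
        return float(self.coincident.mean()) if self.n_bins else 0.0

    @property
    def bin_times(self) -> np.ndarray:
        return self.t_start + (np.arange(self.n_bins) + 0.5) * self.bin_s


@dataclass(frozen=True)
class Epoch:
    """A merged run of significant sliding windows."""

    t_start: float
    t_stop: float

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start


@dataclass
class CoincidenceResult:
    """Sliding-window unitary-event statistics plus significant epochs."""

    windows: pd.DataFrame  # columns: t_start, t_stop, n_emp, n_exp, p, surprise
    epochs: list[Epoch]
    series: CoincidenceSeries
    analysis_window: AnalysisWindow
    alpha: float

    @property
    def total_significant_s(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    @property
    def significant_fraction(self) -> float:
        return self.total_significant_s / self.analysis_window.duration

    @property
    def significant_window_fraction(self) -> float:
        if not len(self.windows):
            return 0.0
        return float((self.windows["p"] < self.alpha).mean())


def detect_coincidences(sts: SpikeTrainSet, bin_s: float = DEFAULT_BIN_S) -> CoincidenceSeries:
    """Count distinct-neuron coincidences on a fixed bin grid.

    Multiple spikes of the *same* neuron in one bin count once toward the
    distinct-neuron tally (but each spike still counts as participating if
    the bin is coincident).
    """
    w = sts.window
    n_bins = max(1, int(np.ceil(w.duration / bin_s - 1e-9)))
    if sts.n_spikes == 0:
        zero = np.zeros(n_bins, dtype=np.int64)
        return CoincidenceSeries(bin_s, w.t_start, zero, zero.copy(), 0)
    bins = np.floor((sts.spike_times - w.t_start) / bin_s).astype(np.int64)
    bins = np.clip(bins, 0, n_bins - 1)
    spikes_per_bin = np.bincount(bins, minlength=n_bins)
    # distinct neurons per bin: unique (bin, neuron) pairs
    pair = np.unique(np.stack([bins, sts.spike_neuron_ids], axis=1), axis=0)
    n_active = np.bincount(pair[:, 0], minlength=n_bins)
    return CoincidenceSeries(bin_s, w.t_start, n_active, spikes_per_bin,
                             int(sts.n_spikes))


def expected_coincidences(rates_hz: np.ndarray, bin_s: float, window_s: float) -> float:
    """Expected coincident-bin count for independent Poisson neurons.

    ``rates_hz`` are per-neuron rates within the window; a coincident bin
    needs spikes from at least two distinct neurons.
    """
    p = np.asarray(rates_hz, dtype=float) * bin_s
    if np.any(p < 0):
        raise ValueError("rates must be >= 0")
    if np.any(p >= 1):
        raise ValueError("per-bin spike probability r*delta must be < 1")
    n_bins = window_s / bin_s
    q0 = np.prod(1.0 - p)  # P(no neuron spikes)
    with np.errstate(divide="ignore", invalid="ignore"):
        # P(exactly one) = sum_i p_i prod_{j!=i} (1-p_j)
        if np.any(p == 1.0):
            q1 = 0.0
        elif q0 > 0:
            q1 = float(q0 * np.sum(p / (1.0 - p)))
        else:  # some p_i == 1 handled above; recompute robustly
            q1 = float(np.sum([pi * np.prod(np.delete(1.0 - p, i))
                               for i, pi in enumerate(p)]))
    q = max(0.0, 1.0 - float(q0) - q1)
    return n_bins * q


def joint_surprise(n_emp: int, n_exp: float) -> tuple[float, float]:
    """Poisson-tail p-value and surprise for an observed coincidence count.

    ``p = P(X >= n_emp)`` with ``X ~ Poisson(n_exp)``;
    ``S = log10((1-p)/p)``.  ``n_emp = 0`` gives p = 1 and S capped at
    ``-S_CAP``; an impossible observation (``n_exp = 0`` with spikes seen)
    gives the underflow floor.
    """
    if n_exp < 0:
        raise ValueError("expected count must be >= 0")
    if n_emp <= 0:
        return 1.0, -S_CAP
    if n_exp == 0:
        return P_FLOOR, S_CAP
    p = float(stats.poisson.sf(n_emp - 1, n_exp))
    p = min(1.0, max(p, P_FLOOR))
    if p >= 1.0:
        return 1.0, -S_CAP
    s = float(np.log10((1.0 - p) / p))
    return p, float(np.clip(s, -S_CAP, S_CAP))


def sliding_ue(
    sts: SpikeTrainSet,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    bin_s: float = DEFAULT_BIN_S,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> CoincidenceResult:
    """Sliding-window unitary-event analysis of a population.

    Rates entering the null are re-estimated inside each window from the
    same spikes ("frequency-matched").  Windows with ``p < alpha`` are
    merged into epochs by union of their spans; by default no
    multiple-testing correction is applied (one test per window at
    ``alpha``), but ``fdr=True`` switches to Benjamini-Hochberg-adjusted
    p-values before thresholding.
    """
    w = sts.window
    if w.duration < window_s:
        raise ValueError("analysis window shorter than the sliding window")
    series = detect_coincidences(sts, bin_s)
    coincident = series.coincident.astype(np.int64)
    bins_per_win = int(round(window_s / bin_s))
    # per-neuron spike counts per bin for windowed rate estimates
    neuron_ids = sts.neurons["neuron_id"].to_numpy()
    id_index = {int(nid): i for i, nid in enumerate(neuron_ids)}
    n_neurons = neuron_ids.size
    n_bins = series.n_bins
    counts = np.zeros((n_neurons, n_bins), dtype=np.int64)
    if sts.n_spikes:
        b = np.clip(np.floor((sts.spike_times - w.t_start) / bin_s).astype(np.int64),
                    0, n_bins - 1)
        rows = np.fromiter((id_index[int(i)] for i in sts.spike_neuron_ids),
                           dtype=np.int64, count=sts.n_spikes)
        np.add.at(counts, (rows, b), 1)
    # cumulative sums for O(1) window counts
    csum_coinc = np.concatenate([[0], np.cumsum(coincident)])
    csum_counts = np.concatenate(
        [np.zeros((n_neurons, 1), dtype=np.int64), np.cumsum(counts, axis=1)], axis=1
    )
    step_bins = max(1, int(round(step_s / bin_s)))
    starts = np.arange(0, n_bins - bins_per_win + 1, step_bins)
    rows = []
    for s0 in starts:
        s1 = s0 + bins_per_win
        n_emp = int(csum_coinc[s1] - csum_coinc[s0])
        spike_counts = csum_counts[:, s1] - csum_counts[:, s0]
        rates = spike_counts / window_s
        n_exp = expected_coincidences(rates, bin_s, window_s)
        p, surprise = joint_surprise(n_emp, n_exp)
        rows.append((w.t_start + s0 * bin_s, w.t_start + s1 * bin_s,
                     n_emp, n_exp, p, surprise))
    windows = pd.DataFrame(rows, columns=["t_start", "t_stop", "n_emp",
                                          "n_exp", "p", "surprise"])
    if fdr and len(windows):
        windows["p"] = stats.false_discovery_control(
            np.clip(windows["p"].to_numpy(), P_FLOOR, 1.0), method="bh")
    epochs = _merge_epochs(windows, alpha)
    return CoincidenceResult(windows, epochs, series, w, alpha)


def _merge_epochs(windows: pd.DataFrame, alpha: float) -> list[Epoch]:
    sig = windows[windows["p"] < alpha]
    epochs: list[Epoch] = []
    for _, row in sig.iterrows():
        if epochs and row["t_start"] <= epochs[-1].t_stop:
            epochs[-1] = Epoch(epochs[-1].t_start,
                               max(epochs[-1].t_stop, row["t_stop"]))
        else:
            epochs.append(Epoch(row["t_start"], row["t_stop"]))
    return epochs


def epoch_frequency(
    series: CoincidenceSeries,
    epochs: list[Epoch],
    smooth_bins: int = 3,
    min_peaks: int = 2,
) -> tuple[float, pd.DataFrame]:
    """Mean oscillation frequency of coincidence activity within epochs.

    The coincidence-count series is smoothed with a short boxcar (default
    3 ms); per epoch, frequency = (n_peaks - 1) / (time from first to last
    peak).  Epochs with fewer than ``min_peaks`` peaks are excluded and
    flagged in the returned table.  Returns (mean Hz across usable epochs,
    per-epoch table).
    """
    y = series.coincident.astype(float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(y, kernel, mode="same")
    t = series.bin_times
    rows = []
    for ep in epochs:
        mask = (t >= ep.t_start) & (t < ep.t_stop)
        seg = y[mask]
        seg_t = t[mask]
        if seg.size < 3:
            rows.append({"t_start": ep.t_start, "t_stop": ep.t_stop,
                         "n_peaks": 0, "freq_hz": np.nan, "used": False})
            continue
        peaks, _ = find_peaks(seg, height=seg.max() * 0.25,
                              distance=max(1, int(0.01 / series.bin_s)))
        if peaks.size < min_peaks:
            rows.append({"t_start": ep.t_start, "t_stop": ep.t_stop,
                         "n_peaks": int(peaks.size), "freq_hz": np.nan,
                         "used": False})
            continue
        span = seg_t[peaks[-1]] - seg_t[peaks[0]]
        freq = (peaks.size - 1) / span if span > 0 else np.nan
        rows.append({"t_start": ep.t_start, "t_stop": ep.t_stop,
                     "n_peaks": int(peaks.size), "freq_hz": float(freq),
                     "used": bool(np.isfinite(freq))})
    table = pd.DataFrame(rows, columns=["t_start", "t_stop", "n_peaks",
                                        "freq_hz", "used"])
    usable = table[table["used"]]
    mean = float(usable["freq_hz"].mean()) if len(usable) else float("nan")
    return mean, table
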