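"""End-to-end orchestration of the four-condition experiment.

One *experiment set* crosses condition (control vs parkinsonian PT5B
excitability) with behavioural state (rest vs activated) on a shared
network build, mirroring a paired design: the same column, connectome and
placement seeds underlie all four runs, and only the PT5B parameters and
the motor-thalamic drive differ.  Each condition yields a
:class:`ConditionReport` bundling population firing rates, ISI-CV
statistics, the PT5B duty cycle, beta-band burst statistics of the
simulated LFP, and unitary-event synchrony totals, with full provenance
(seeds, scale, condition flags).

The LFP is computed from each neuron's net synaptic current by the
line-source forward model, representing every neuron as a current dipole:
the soma segment carries the net synaptic current and a return segment of
equal and opposite current extends toward the pia (apical-dendrite
orientation), so population potentials do not trivially cancel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics, spectral, synchrony
from .config import ConditionFlags, NetworkConfig, default_config
from .datamodel import AnalysisWindow, LFPRecording, SpikeTrainSet, slice_window
from .lfp import lfp_line
from .network import SimulationResult, connect, place_neurons, simulate
from .neuron import DEFAULT_NEURON_PARAMS, calibrate_parkinsonian

__all__ = [
    "ConditionReport",
    "run_condition",
    "run_experiment",
    "compare_conditions",
    "lfp_from_simulation",
    "CONDITIONS",
]

CONDITIONS = (
    ConditionFlags(parkinsonian=False, activated=False),
    ConditionFlags(parkinsonian=False, activated=True),
    ConditionFlags(parkinsonian=True, activated=False),
    ConditionFlags(parkinsonian=True, activated=True),
)

#: dipole return-segment length toward the pia (µm)
RETURN_SEGMENT_UM = 200.0


@dataclass
class ConditionReport:
    """All per-condition statistics plus provenance."""

    label: str
    rates: pd.DataFrame  # population, n_neurons, mean_rate, sd_rate
    per_neuron_rates: pd.DataFrame
    cv_mean: float
    cv_sd: float
    cv_regular_fraction: float
    duty_cycle_pct: float | None
    beta_burst_rate_hz: float | None
    beta_burst_mean_duration_s: float | None
    synchrony_fraction: float | None
    synchrony_total_s: float | None
    epoch_frequency_hz: float | None
    coincident_spike_proportion: float | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rates": self.rates.to_dict(orient="records"),
            "cv": {"mean": self.cv_mean, "sd": self.cv_sd,
                   "regular_fraction": self.cv_regular_fraction},
            "duty_cycle_pct": self.duty_cycle_pct,
            "beta_bursts": {"rate_hz": self.beta_burst_rate_hz,
                            "mean_duration_s": self.beta_burst_mean_duration_s},
            "synchrony": {"significant_fraction": self.synchrony_fraction,
                          "total_significant_s": self.synchrony_total_s,
                          "epoch_frequency_hz": self.epoch_frequency_hz,
                          "coincident_spike_proportion":
                              self.coincident_spike_proportion},
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=float))
        return path


def lfp_from_simulation(
    result: SimulationResult,
    electrode_depths_um: Sequence[float] | None = None,
    config: NetworkConfig | None = None,
) -> LFPRecording:
    """Line-source LFP from per-neuron synaptic-current traces.

    Each neuron contributes a sink (soma segment) and an equal-and-opposite
    return line segment extending ``RETURN_SEGMENT_UM`` toward the pia.
    Default electrodes sit on the cylinder axis at each layer midpoint.
    """
    neurons = result.spikes.neurons
    if electrode_depths_um is None:
        cfg = config or default_config()
        electrode_depths_um = [
            0.5 * (lo + hi) for name, (lo, hi) in
            sorted(cfg.geometry.layer_bounds_um.items(), key=lambda kv: kv[1])
            if name != "L1"
        ]
    soma = neurons[["x_um", "y_um", "z_um"]].to_numpy()
    up = soma.copy()
    up[:, 1] = np.maximum(soma[:, 1] - RETURN_SEGMENT_UM, 0.0)
    # sink: short segment at the soma; source: return segment above it
    eps = np.array([0.0, 1.0, 0.0])
    sink_segs = np.stack([soma - eps, soma + eps], axis=1)
    ret_segs = np.stack([up, soma], axis=1)
    segments = np.concatenate([sink_segs, ret_segs])
    currents = np.concatenate([result.currents_na, -result.currents_na])
    electrodes = np.array([[0.0, d, 0.0] for d in electrode_depths_um])
    return lfp_line(segments, currents, electrodes, fs=result.currents_fs)


def _analyze_condition(
    spikes: SpikeTrainSet,
    lfp: LFPRecording | None,
    label: str,
    rate_window: AnalysisWindow,
    sync_window: AnalysisWindow,
    focus_population: str = "PT5B",
    provenance: dict | None = None,
) -> ConditionReport:
    rates = metrics.firing_rates(spikes, rate_window)
    per_neuron = metrics.per_neuron_rates(spikes, rate_window)
    focus = spikes.select([focus_population]) if focus_population in \
        spikes.populations else spikes
    focus_rate = slice_window(focus, rate_window.intersect(spikes.window))
    cv = metrics.isi_cv(focus_rate)

    duty = None
    sch = metrics.spike_count_histogram(focus_rate)
    periods = metrics.extract_periods(sch)
    if periods:
        duty = metrics.duty_cycle(periods)

    burst_rate = burst_dur = None
    if lfp is not None and lfp.samples.shape[0] > int(0.2 * lfp.fs):
        channel = int(np.argmin(np.abs(lfp.electrode_depths_um - 857.0)))
        spec = spectral.spectrogram(lfp, channel=channel)
        series, _ = spectral.band_power(spec, spectral.BETA_BAND)
        bursts = spectral.detect_bursts(series, spec.times)
        burst_rate = bursts.rate_hz
        burst_dur = bursts.mean_duration_s

    sync_frac = sync_total = epoch_freq = coinc_prop = None
    try:
        focus_sync = slice_window(focus, sync_window.intersect(spikes.window))
        ue = synchrony.sliding_ue(focus_sync)
        sync_frac = ue.significant_fraction
        sync_total = ue.total_significant_s
        coinc_prop = ue.series.proportion_spikes
        epoch_freq, _ = synchrony.epoch_frequency(ue.series, ue.epochs)
    except ValueError:
        pass

    return ConditionReport(
        label=label, rates=rates, per_neuron_rates=per_neuron,
        cv_mean=cv.mean, cv_sd=cv.sd, cv_regular_fraction=cv.regular_fraction,
        duty_cycle_pct=duty,
        beta_burst_rate_hz=burst_rate, beta_burst_mean_duration_s=burst_dur,
        synchrony_fraction=sync_frac, synchrony_total_s=sync_total,
        epoch_frequency_hz=epoch_freq,
        coincident_spike_proportion=coinc_prop,
        provenance=provenance or {},
    )


def run_condition(
    config: NetworkConfig,
    flags: ConditionFlags,
    seed: int,
    duration_s: float = 4.3,
    transient_s: float = 2.0,
    neurons: pd.DataFrame | None = None,
    edges: pd.DataFrame | None = None,
    pd_params=None,
) -> tuple[ConditionReport, SimulationResult]:
    """Simulate and analyse one condition.

    Rates/CV/duty use the post-transient window; synchrony uses the same
    window capped at 4 s of data.
    """
    result = simulate(config, duration_s, flags, seed,
                      neurons=neurons, edges=edges, pd_params=pd_params)
    lfp = lfp_from_simulation(result, config=config)
    # drop the initialization transient from analysis
    rate_window = AnalysisWindow(transient_s, duration_s)
    sync_window = AnalysisWindow(max(0.0, duration_s - 4.0), duration_s)
    prov = {"mode": "simulate", "condition": flags.label, "seed": seed,
            "scale": config.scale, "duration_s": duration_s,
            "transient_s": transient_s}
    report = _analyze_condition(result.spikes, lfp, flags.label,
                                rate_window, sync_window, provenance=prov)
    return report, result


def run_experiment(
    config: NetworkConfig | None = None,
    mode: str = "simulate",
    seed: int = 0,
    duration_s: float = 4.3,
    spike_files: dict[str, str] | None = None,
    lfp_files: dict[str, str] | None = None,
    pd_params=None,
) -> dict[str, ConditionReport]:
    """Run all four condition-state combinations.

    ``simulate`` mode builds one column (placement and connectome seeds
    shared across conditions) and runs the four simulations;
    ``analyze-files`` mode reads the recordings named in ``spike_files``
    (keys = condition labels) and analyses them with the same statistics.
    Reports with missing inputs carry explicit gaps rather than failing.
    """
    reports: dict[str, ConditionReport] = {}
    if mode == "simulate":
        config = config or default_config(scale=0.05)
        ss = np.random.SeedSequence(seed)
        s_place, s_conn, s_run = (int(s.generate_state(1)[0] % (2 ** 31))
                                  for s in ss.spawn(3))
        neurons = place_neurons(config, seed=s_place)
        edges = connect(neurons, config.rules, config.geometry, seed=s_conn)
        if pd_params is None:
            pd_params = calibrate_parkinsonian(DEFAULT_NEURON_PARAMS["PT5B"])
        for flags in CONDITIONS:
            report, _ = run_condition(
                config, flags, seed=s_run, duration_s=duration_s,
                neurons=neurons, edges=edges,
                pd_params=pd_params if flags.parkinsonian else None,
            )
            reports[flags.label] = report
    elif mode == "analyze-files":
        from .datamodel import read_lfp, read_spikes
        spike_files = spike_files or {}
        lfp_files = lfp_files or {}
        for flags in CONDITIONS:
            label = flags.label
            if label not in spike_files:
                continue  # explicit gap
            spikes = read_spikes(spike_files[label])
            lfp = read_lfp(lfp_files[label]) if label in lfp_files else None
            w = spikes.window
            rate_window = AnalysisWindow(
                max(w.t_start, w.t_stop - 2.3), w.t_stop)
            sync_window = AnalysisWindow(
                max(w.t_start, w.t_stop - 4.0), w.t_stop)
            prov = {"mode": "analyze-files", "condition": label,
                    "source": str(spike_files[label])}
            reports[label] = _analyze_condition(
                spikes, lfp, label, rate_window, sync_window, provenance=prov)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reports


def compare_conditions(
    a: ConditionReport,
    b: ConditionReport,
    population: str = "PT5B",
) -> dict:
    """Two-sided Mann-Whitney rank test on per-neuron firing rates.

    Returns direction (sign of the mean difference b - a), effect size
    (difference of means, spikes/s) and the rank-test p-value; identical
    inputs give p close to 1 and zero effect.
    """
    ra = a.per_neuron_rates.query("population == @population")["rate"]
    rb = b.per_neuron_rates.query("population == @population")["rate"]
    if ra.empty or rb.empty:
        return {"population": population, "skipped": True,
                "note": "population absent in one report"}
    if np.allclose(ra.to_numpy().sum(), 0) and np.allclose(rb.to_numpy().sum(), 0):
        return {"population": population, "skipped": True,
                "note": "no spikes in either condition"}
    try:
        stat, p = stats.mannwhitneyu(ra, rb, alternative="two-sided")
    except ValueError:  # all values identical
        stat, p = np.nan, 1.0
    effect = float(rb.mean() - ra.mean())
    return {
        "population": population,
        "a": a.label, "b": b.label,
        "mean_a": float(ra.mean()), "mean_b": float(rb.mean()),
        "effect_spikes_per_s": effect,
        "direction": int(np.sign(effect)),
        "u_statistic": float(stat),
        "p_value": float(p),
        "skipped": False,
    }
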