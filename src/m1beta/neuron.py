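"""Surrogate point neurons and synapse kinetics.

Each population is represented by a conductance-based adaptive exponential
integrate-and-fire (aEIF) neuron:

    C dV/dt = -gL (V - EL) + gL * DeltaT * nat_gain * exp((V - VT)/DeltaT)
              - w + I_h + I_syn + I_inj
    tau_w dw/dt = a (V - EL) - w,     w -> w + adapt_b at each spike

The three intrinsic-current roles of the detailed biophysical model map
onto three knobs of this surrogate:

* ``adapt_b`` (pA) — spike-triggered adaptation increment, playing the
  role of the BK-type calcium-activated potassium current (larger values
  hyperpolarize the neuron after spiking and flatten the f-I curve);
* ``nat_gain`` — multiplier on the exponential spike-initiation current,
  playing the role of the transient sodium (NaT) conductance (larger
  values steepen the f-I curve and lower the effective threshold);
* ``g_h_ns`` — a constant depolarizing conductance (reversal ``E_h``)
  standing in for the hyperpolarization-activated current Ih; it is scaled
  by the behavioural-state factor (1.0 at rest, 0.25 activated) in PT5B
  neurons.

The parkinsonian PT5B phenotype is a 64% mean decrease in evoked spike
count across a somatic current-injection set; :func:`calibrate_parkinsonian`
reproduces it by increasing exactly ``adapt_b`` and ``nat_gain``.

Synapses are difference-of-exponentials conductances; the NMDA component
is scaled by the voltage-dependent magnesium-block factor
``1 / (1 + 0.28 exp(-0.062 V))`` (1 mM Mg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

__all__ = [
    "SurrogateNeuronParams",
    "SynKinetics",
    "SYNAPSE_KINETICS",
    "mg_block",
    "fi_protocol",
    "calibrate_parkinsonian",
    "mean_decrease_pct",
    "unitary_psp_weight",
    "DEFAULT_INJECTIONS_PA",
    "DEFAULT_NEURON_PARAMS",
    "PD_TARGET_DECREASE_PCT",
]

#: printed mean spike-count decrease of the dopamine-depleted PT5B phenotype
PD_TARGET_DECREASE_PCT = 64.0

#: somatic current-injection set (pA) for the f-I protocol
DEFAULT_INJECTIONS_PA = (250.0, 300.0, 350.0, 400.0, 450.0, 500.0)


@dataclass(frozen=True)
class SurrogateNeuronParams:
    """aEIF parameters for one population (SI-ish units: pF, nS, mV, pA, ms)."""

    c_pf: float = 150.0
    g_leak_ns: float = 10.0
    e_leak_mv: float = -70.0
    v_thresh_mv: float = -50.0  # exponential-threshold parameter VT
    delta_t_mv: float = 2.0  # spike-initiation slope factor
    v_reset_mv: float = -60.0
    v_peak_mv: float = 0.0  # spike-detection ceiling
    adapt_a_ns: float = 2.0  # subthreshold adaptation coupling
    adapt_b_pa: float = 60.0  # spike-triggered adaptation increment (BK-like)
    tau_w_ms: float = 200.0
    nat_gain: float = 1.0  # exponential-current multiplier (NaT-like)
    g_h_ns: float = 0.0  # h-like depolarizing conductance
    e_h_mv: float = -30.0
    t_ref_ms: float = 2.0

    def __post_init__(self) -> None:
        if min(self.c_pf, self.g_leak_ns, self.tau_w_ms, self.delta_t_mv) <= 0:
            raise ValueError("capacitance, leak, tau_w and DeltaT must be positive")
        if self.adapt_b_pa < 0 or self.g_h_ns < 0 or self.nat_gain <= 0:
            raise ValueError("conductances and gains must be non-negative")


DEFAULT_NEURON_PARAMS: dict[str, SurrogateNeuronParams] = {
    # regular-spiking excitatory
    "E": SurrogateNeuronParams(),
    # corticospinal PT5B: as E plus the h-like depolarizing conductance
    "PT5B": SurrogateNeuronParams(g_h_ns=1.0),
    # fast-spiking PV: little adaptation, sharp spike initiation
    "PV": SurrogateNeuronParams(c_pf=100.0, g_leak_ns=10.0, e_leak_mv=-65.0,
                                v_thresh_mv=-45.0, delta_t_mv=0.8,
                                v_reset_mv=-55.0, adapt_a_ns=0.0,
                                adapt_b_pa=20.0, tau_w_ms=60.0, t_ref_ms=1.5),
    # low-threshold-spiking SOM
    "SOM": SurrogateNeuronParams(c_pf=100.0, g_leak_ns=8.0, e_leak_mv=-62.0,
                                 v_thresh_mv=-52.0, delta_t_mv=2.5,
                                 v_reset_mv=-58.0, adapt_a_ns=4.0,
                                 adapt_b_pa=30.0, tau_w_ms=150.0),
}


def params_for_population(population: str) -> SurrogateNeuronParams:
    if population == "PT5B":
        return DEFAULT_NEURON_PARAMS["PT5B"]
    if population.startswith("PV"):
        return DEFAULT_NEURON_PARAMS["PV"]
    if population.startswith("SOM"):
        return DEFAULT_NEURON_PARAMS["SOM"]
    return DEFAULT_NEURON_PARAMS["E"]


@dataclass(frozen=True)
class SynKinetics:
    """Difference-of-exponentials conductance kernel."""

    name: str
    tau_rise_ms: float
    tau_decay_ms: float
    e_rev_mv: float
    mg_gated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("need 0 < rise tau < decay tau")

    @property
    def peak_norm(self) -> float:
        """Normalisation so a unit-weight event peaks at conductance 1."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        tp = tr * td / (td - tr) * np.log(td / tr)
        return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))

    def kernel_area_ms(self) -> float:
        return self.peak_norm * (self.tau_decay_ms - self.tau_rise_ms)


SYNAPSE_KINETICS: dict[str, SynKinetics] = {
    "AMPA": SynKinetics("AMPA", 0.05, 5.3, 0.0),
    "NMDA": SynKinetics("NMDA", 15.0, 150.0, 0.0, mg_gated=True),
    "GABAA_fast": SynKinetics("GABAA_fast", 0.07, 18.2, -80.0),
    "GABAA_slow": SynKinetics("GABAA_slow", 2.0, 100.0, -80.0),
    # slow double-exponential stand-in for the GABAB/GIRK cascade
    "GABAB": SynKinetics("GABAB", 40.0, 200.0, -95.0),
}


def mg_block(v_mv: np.ndarray | float) -> np.ndarray | float:
    """Voltage-dependent NMDA magnesium unblock, ``1/(1+0.28 e^{-0.062 V})``.

    Evaluates to ~0.78 at 0 mV and approaches 1 with depolarization
    ([Mg] = 1 mM).
    """
    return 1.0 / (1.0 + 0.28 * np.exp(-0.062 * np.asarray(v_mv, dtype=float)))


# ---------------------------------------------------------------------------
# f-I protocol
# ---------------------------------------------------------------------------

_EXP_CLIP = 20.0  # clamp on the exponential argument for numerical safety


def fi_protocol(
    params: SurrogateNeuronParams,
    injections_pa: tuple[float, ...] = DEFAULT_INJECTIONS_PA,
    duration_s: float = 2.0,
    dt_ms: float = 0.025,
    ih_scale: float = 1.0,
) -> np.ndarray:
    """Spike counts evoked by constant somatic current injections.

    All injection amplitudes are integrated simultaneously (forward Euler,
    fixed step) from rest; returns one count per injection.
    """
    inj = np.asarray(injections_pa, dtype=float)
    if np.any(np.diff(inj) < 0):
        raise ValueError("injections must be sorted ascending")
    n = inj.size
    p = params
    v = np.full(n, p.e_leak_mv)
    w = np.zeros(n)
    refr = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    for _ in range(n_steps):
        active = refr <= 0
        arg = np.clip((v - p.v_thresh_mv) / p.delta_t_mv, None, _EXP_CLIP)
        i_exp = p.g_leak_ns * p.delta_t_mv * p.nat_gain * np.exp(arg)
        i_h = p.g_h_ns * ih_scale * (p.e_h_mv - v)
        dv = (-p.g_leak_ns * (v - p.e_leak_mv) + i_exp - w + i_h + inj) / p.c_pf
        dw = (p.adapt_a_ns * (v - p.e_leak_mv) - w) / p.tau_w_ms
        v = np.where(active, v + dt_ms * dv, v)
        w = w + dt_ms * dw
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("membrane potential diverged; reduce dt")
        spiking = active & (v >= p.v_peak_mv)
        if np.any(spiking):
            counts[spiking] += 1
            v[spiking] = p.v_reset_mv
            w[spiking] += p.adapt_b_pa
            refr[spiking] = p.t_ref_ms
        refr = np.maximum(refr - dt_ms, 0.0)
    return counts


# ---------------------------------------------------------------------------
# parkinsonian calibration
# ---------------------------------------------------------------------------

def mean_decrease_pct(control_counts: np.ndarray, pd_counts: np.ndarray) -> float:
    """Mean per-injection percentage decrease, over injections with spikes."""
    c = np.asarray(control_counts, dtype=float)
    d = np.asarray(pd_counts, dtype=float)
    mask = c > 0
    if not mask.any():
        raise ValueError("control f-I curve is degenerate (no spikes)")
    return float(np.mean(100.0 * (1.0 - d[mask] / c[mask])))


def calibrate_parkinsonian(
    control: SurrogateNeuronParams,
    injections_pa: tuple[float, ...] = DEFAULT_INJECTIONS_PA,
    duration_s: float = 2.0,
    target_pct: float = PD_TARGET_DECREASE_PCT,
    nat_gain_factor: float = 1.15,
    tol_pct: float = 2.0,
) -> SurrogateNeuronParams:
    """Reduced-excitability parameters matching the dopamine-depleted
    PT5B phenotype.

    Mirrors the experimental adjustment order: first a small fixed increase
    of the NaT-like gain (steepening the f-I slope), then the BK-like
    adaptation increment is raised until the mean evoked-spike-count
    decrease across the injection set reaches ``target_pct`` (bisection on
    ``adapt_b``, which affects the decrease monotonically).  Exactly
    ``adapt_b_pa`` and ``nat_gain`` differ from ``control``; the result is
    a pure function of the control parameters and the injection set.

    Raises ``RuntimeError`` with the residual if the target cannot be
    reached within ``tol_pct`` percentage points.
    """
    control_counts = fi_protocol(control, injections_pa, duration_s)
    if not np.any(control_counts > 0):
        raise ValueError("control parameters evoke no spikes")

    def decrease(b: float) -> float:
        cand = replace(control, adapt_b_pa=b,
                       nat_gain=control.nat_gain * nat_gain_factor)
        return mean_decrease_pct(control_counts,
                                 fi_protocol(cand, injections_pa, duration_s))

    lo = control.adapt_b_pa
    hi = max(4.0 * lo, 400.0)
    while decrease(hi) < target_pct and hi < 1e5:
        hi *= 2.0
    d_lo, d_hi = decrease(lo), decrease(hi)
    if d_hi < target_pct:
        raise RuntimeError(
            f"calibration failed: max achievable decrease {d_hi:.1f}% "
            f"< target {target_pct}%"
        )
    # bisection; spike counts are integers so the decrease is a step
    # function of b -- track the best point seen
    best_b, best_res = hi, abs(d_hi - target_pct)
    while hi - lo > 0.25:
        mid = 0.5 * (lo + hi)
        d_mid = decrease(mid)
        if abs(d_mid - target_pct) < best_res:
            best_b, best_res = mid, abs(d_mid - target_pct)
        if d_mid < target_pct:
            lo = mid
        else:
            hi = mid
    if best_res > tol_pct:
        raise RuntimeError(
            f"calibration residual {best_res:.2f} points exceeds "
            f"tolerance {tol_pct}"
        )
    return replace(control, adapt_b_pa=best_b,
                   nat_gain=control.nat_gain * nat_gain_factor)


# ---------------------------------------------------------------------------
# unitary-PSP weight normalization
# ---------------------------------------------------------------------------

def unitary_psp_weight(
    post: SurrogateNeuronParams,
    kinetics: list[SynKinetics] | list[tuple[SynKinetics, float]],
    target_mv: float,
    dt_ms: float = 0.05,
    duration_ms: float = 400.0,
) -> float:
    """Synaptic weight (nS) giving a somatic PSP of ``target_mv`` at rest.

    Simulates the passive membrane response to a single unit-weight event
    through the given kinetics mix (``(kinetics, fraction)`` pairs, or a
    bare list for an equal split; NMDA magnesium-gated) and scales the
    weight to hit the target peak deflection.  Used once per
    post-synaptic population.
    """
    mix: list[tuple[SynKinetics, float]] = [
        k if isinstance(k, tuple) else (k, 1.0 / len(kinetics)) for k in kinetics
    ]
    p = post
    v = p.e_leak_mv
    n_steps = int(round(duration_ms / dt_ms))
    peak = 0.0
    # deliver the event at t=0, split across the mix
    states = [(frac, frac, k) for k, frac in mix]
    for _ in range(n_steps):
        i_syn = 0.0
        new_states = []
        for x_r, x_d, k in states:
            g = k.peak_norm * (x_d - x_r)
            scale = mg_block(v) if k.mg_gated else 1.0
            i_syn += g * scale * (k.e_rev_mv - v)
            new_states.append((x_r * np.exp(-dt_ms / k.tau_rise_ms),
                               x_d * np.exp(-dt_ms / k.tau_decay_ms), k))
        states = new_states
        dv = (-p.g_leak_ns * (v - p.e_leak_mv) + i_syn) / p.c_pf
        v = v + dt_ms * dv
        peak = max(peak, abs(v - p.e_leak_mv))
    if peak <= 0:
        raise RuntimeError("unit event produced no deflection")
    return target_mv / peak
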