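# Methods

This note documents the models, estimators and numerical choices behind
`m1beta`, and what its synthetic benchmarks do and do not establish about
real recordings.

## Scientific setting

In rodent models of Parkinson's disease (6-OHDA dopamine depletion), layer-5B
pyramidal-tract (PT5B) corticospinal neurons of primary motor cortex (M1)
lose intrinsic excitability: across a set of somatic current injections
their evoked spike count drops by about 64% on average, attributed to an
increased BK-type potassium conductance (hyperpolarizing, moving the cell
away from threshold) partially offset by a small increase in transient
sodium (NaT) conductance (steepening the current–frequency curve). The
package asks how such a cell-intrinsic change reshapes network activity —
firing rates and regularity, beta-band (~13–30 Hz) LFP power and bursts,
population duty cycles, and millisecond-scale spike synchrony — and provides
the analysis chain to quantify those signatures in simulated or recorded
data.

## Surrogate neuron model

Each population is represented by a conductance-based adaptive exponential
integrate-and-fire (aEIF) point neuron:

    C dV/dt = −g_L (V − E_L) + g_L Δ_T g_NaT exp((V − V_T)/Δ_T)
              − w + g_h s_h (E_h − V) + I_syn + I_inj
    τ_w dw/dt = a (V − E_L) − w,      w ← w + b at each spike

The three intrinsic currents of the detailed biophysical PT5B model map
onto three surrogate knobs:

| knob | role | default (PT5B) |
| --- | --- | --- |
| `adapt_b_pa` (b) | BK-like spike-triggered adaptation increment | 60 pA |
| `nat_gain` (g_NaT) | NaT-like multiplier on the exponential spike-initiation current | 1.0 |
| `g_h_ns` × `ih_scale` | Ih-like constant depolarizing conductance (E_h = −30 mV) | 1 nS; scale 1.0 at rest, 0.25 in the activated state |

Remaining defaults (C = 150 pF, g_L = 10 nS, E_L = −70 mV, V_T = −50 mV,
Δ_T = 2 mV, reset −60 mV, τ_w = 200 ms, a = 2 nS, 2 ms refractory) are
standard regular-spiking values; PV interneurons use a sharper spike
initiation (Δ_T = 0.8 mV) with weak adaptation, SOM cells a lower-threshold
adapting profile. No claim of quantitative equivalence to the published
multicompartment Hodgkin–Huxley models is made: the surrogate exists to
exercise the construction rules and the analysis pipeline end to end.

### f-I protocol and parkinsonian calibration

`fi_protocol` integrates the neuron (forward Euler, fixed 0.025 ms step,
exponential argument clamped at 20) for 2 s at each injection amplitude.
The default injection set is 250–500 pA in 50 pA steps, chosen to start
above the control cell's rheobase so every control count is nonzero; a
half-step convergence test keeps counts stable to ±1 spike.

`calibrate_parkinsonian` reproduces the 64% mean evoked-spike-count
decrease in the order the experimental adjustment is described: the
NaT-like gain is first raised by a fixed small factor (1.15), then the
BK-like increment `b` is found by bisection (the decrease is monotone in
`b`; interval narrowed to 0.25 pA, best point tracked because integer spike
counts make the objective a step function). Exactly these two parameters
differ from control, and the result is a pure function of the control
parameters and the injection set. Residuals beyond 2 percentage points
raise an error rather than returning a silently mis-calibrated cell.

## Column construction

The modeled volume is a cylinder, 300 µm diameter × 1350 µm depth, with
layer boundaries at fractions 0.1 / 0.29 / 0.37 / 0.47 / 0.8 / 1.0 of the
depth (L1, L2/3, L4, L5A, L5B, L6; L1 holds no somata). Population counts
derive from per-layer densities and excitatory fractions with the ratio
rules IT:PT5B = 1:1 in L5B, IT:CT = 1:1 in L6, PV:SOM = 2:1 per layer, and
PV5A/SOM5A covering layers 4 and 5A jointly. Absolute per-layer densities
are not part of the published circuit description (they trace to external
histology); the shipped defaults (107–135 × 10³ neurons/mm³, excitatory
fractions 0.85–0.90) were chosen once so that the full-scale column
contains exactly 10,073 neurons under these rules, and are overridable from
YAML. A `scale` factor multiplies densities for desk-scale work; analyses
in the test-suite use scale 0.04–0.05 (~400–500 neurons), a size chosen so
a four-condition experiment runs in minutes on one core.

Connection probability between somata at 3-D distance d is
`c(post) · pcon · exp(−d/λ)` with λ = 100 µm. The border correction
`c(post) ≥ 1` is the inverse of the fraction of the horizontal exponential
kernel mass lying inside the cylinder cross-section around the
post-synaptic soma (radial lookup table, numerically integrated), so
wall-adjacent neurons are not under-connected; probabilities pushed above 1
are clamped with a warning. Per-pair `pcon`/`vcon` matrices are not
published; defaults are class-level (E→E 0.10/0.5 mV, E→I 0.20/0.8 mV,
I→E 0.25/0.8 mV, I→I 0.25/1.0 mV) with the distance kernel supplying
spatial specificity. Conduction delay is 2 ms + d/(0.5 m/s). Autapses are
excluded.

## Synapses and drives

Synapses are difference-of-exponentials conductances normalised to unit
peak: AMPA (0.05/5.3 ms, 0 mV), NMDA (15/150 ms, 0 mV, magnesium factor
1/(1 + 0.28 e^(−0.062 V)) at 1 mM Mg), fast GABA_A (0.07/18.2 ms, −80 mV),
slow GABA_A (2/100 ms, −80 mV). The GABA_B/GIRK second-messenger cascade is
approximated by a slow double-exponential conductance (40/200 ms, −95 mV) —
a deliberate simplification preserving sign and timescale only. Excitatory
projections split their weight 1:1 across AMPA and NMDA; PV projections use
fast GABA_A; SOM→E uses a 90/10 slow-GABA_A/GABA_B mix and SOM→I slow
GABA_A alone. Each connection carries a single aggregated synapse (the
point neuron has no dendritic sites). Weights are normalised per
post-synaptic population by a one-time unitary-PSP calibration: a passive
simulation finds the conductance giving the rule's `vcon` (mV) somatic
deflection at rest.

Long-range drive comes from seven regions (VL, VM, S1, S2, cM1, M2, OC),
each holding 1000 independent Poisson generators whose constant rates are
drawn uniformly at build time from the region's range (rest: VL 0–2.5 Hz,
VM 0–5 Hz, S1/S2/OC 0–5 Hz, cM1/M2 0–2.5 Hz; the motor-thalamic regions VL
and VM switch to 0–10 Hz in the activated state). Generators contact
neurons in their target layers with probability 0.1; because a
superposition of Poisson processes is Poisson, each neuron's drive is
simulated as one aggregate process at the summed rate of its connected
generators. Drive events deliver 1.5 nS (AMPA+NMDA split) to excitatory
cells and 40% of that to interneurons; these two values set the network's
operating point and were fixed once so that resting excitatory rates fall
in the few-to-ten spikes/s range typical of M1 while interneurons remain
faster — they are surrogate calibration constants, not measurements.

Integration is clock-driven forward Euler at 0.1 ms with exact exponential
synapse decay, a per-edge delay ring buffer, and per-neuron net synaptic
current recorded at 1 kHz. Fixed seeds (split via `SeedSequence`) make
placement, wiring, drives and integration bit-reproducible; non-finite
states abort with a diagnostic.

## LFP forward model

Extracellular potentials follow the line-source approximation in an
infinite homogeneous ohmic medium with σ = 0.3 mS/mm (numerically S/m),
frequency-independent. With currents in nA and distances in µm the
potential is returned in mV (the unit factors cancel exactly). The uniform
line-source kernel integrates 1/(4πσr) along the segment to the standard
logarithmic form; for electrodes axially beyond a segment the difference
`√(h²+r²) − h` underflows, so the conjugate form (in which the r² factors
cancel) is used there. Source–electrode distances are clamped at 1 µm.

Because a point neuron's total membrane current sums to zero, each neuron
is represented as a current dipole for LFP purposes: the soma carries the
net synaptic current and an equal-and-opposite return segment extends
200 µm toward the pia (apical orientation). Default electrodes sit on the
cylinder axis at the five layer midpoints. This produces depth-dependent
population signals with the right scaling properties; it is not a
substitute for full multicompartment return-current geometry.

## Spectral analysis

Spectrograms are complex Morlet transforms (MNE backend) with 6 cycles per
frequency on a log-spaced grid up to 80 Hz; the default grid's low edge is
raised so that every wavelet (≈10 σ_t = 10·n/(2πf) s) fits inside the
signal. Power units are arbitrary but consistent across recordings
analysed with identical settings, which is all the between-condition
contrasts require. Band power is the mean over in-band grid frequencies.
Bursts are maximal supra-threshold excursions of a band-power series
lasting ≥ 50 ms; the default threshold is the series' 75th percentile, a
scale-free rule chosen because absolute spectrogram units do not transfer
across conditions. Burst counts are monotone in both threshold and minimum
duration by construction. The beta band defaults to 13–30 Hz with
configurable sub-bands.

## Spike statistics

Firing rates are per-neuron counts over the analysis window (default: the
simulation minus a 2 s initialization transient), summarised as mean ± sd
over neurons per population; silent neurons count as zeros. ISI regularity
uses CV = sd/mean of interspike intervals with the regular/irregular
threshold at 0.5; neurons with fewer than 3 spikes have no defined CV and
are excluded and counted.

The population spike-count histogram (SCH) uses 2 ms bins. Oscillation
periods are delimited by consecutive *rising* crossings of the half-height
(min+max)/2 of the Gaussian-smoothed SCH (sd = 1 bin by default; raw 2 ms
bins do not yield unique crossings), with crossing times linearly
interpolated; the half-height level is global over the analysis window,
matching a single horizontal half-height line across the histogram. The
duty cycle is the percentage of the period spent above half height,
averaged over all periods in the window. On noiseless sinusoids this gives
50.0% and on square waves the on-fraction exactly (±0.1 at 2 ms bins). On
Poisson-sampled histograms the max of the noisy SCH is biased upward
(extreme-value statistics), which biases the duty cycle low by roughly
1–2 points at per-bin counts around 100; recovery tests therefore use
populations large enough (≈2500 neurons at 12 Hz) that the residual bias
stays inside the ±2-point tolerance. This bias is a property of the
min/max half-height definition itself and should be kept in mind when
comparing duty cycles across populations of very different size or rate.

## Unitary-event synchrony

A coincidence is a 1 ms bin (grid anchored at the analysis-window start)
containing spikes from ≥ 2 distinct neurons. In each sliding 100 ms window
(5 ms step), the observed coincident-bin count n_emp is compared with the
expectation under independent Poisson firing at the rates estimated *in
that same window* ("frequency-matched"): with p_i = r_i·Δ,

    q = 1 − Π(1−p_i) − Σ_i p_i Π_{j≠i}(1−p_j),    n_exp = (W/Δ)·q,

and p = P(X ≥ n_emp) for X ~ Poisson(n_exp); the surprise is
S = log₁₀((1−p)/p), floored/capped against underflow. Windows with
p < 0.05 are merged by span union into significant epochs; no
multiple-testing correction is applied (one test per window), matching the
stated significance criterion, with an optional FDR switch available.
Within an epoch, the oscillation frequency of synchronous activity is
(n_peaks − 1)/(time between first and last peak) of the 3 ms-boxcar-
smoothed coincidence series, averaged over epochs with ≥ 2 peaks.

Two properties of this statistic matter for interpretation:

* **It is conservative.** n_exp per window is small (≈1.7 for 20 neurons
  at 10 Hz), so the discrete Poisson tail rejects only at n_emp ≥ 5, an
  exact size of ~3% rather than 5%; worse, because the rates entering the
  null are estimated from the same window, windows with many coincidences
  also have inflated n_exp, suppressing rejections further. On matched
  independent Poisson populations the measured significant-window fraction
  is ~0.5–1% at α = 0.05, not the nominal 5%. Detected epochs are
  therefore trustworthy; absence of epochs is weak evidence of absence.
* **It detects temporal structure, not added rate.** Injected coincidences
  are charged to the null quadratically through the rate estimate, so
  additive synchronous events stand out only against sparse backgrounds
  (the recovery tests use 50 neurons at 0.5 Hz with small injected
  ensembles); in dense oscillating populations what the test flags is
  within-window bunching of spikes — exactly the beta-locked synchrony of
  interest.

## Synthetic data

`gen_inhomogeneous_poisson` thins a homogeneous candidate stream at the
rate maximum — exact for any bounded rate function. Rate shapes: sinusoid
(baseline·(1 + m·sin)), threshold-rectified sinusoid, and a square wave
whose on-rate is baseline/on-fraction so the mean rate stays at baseline
and the true duty cycle equals the on-fraction. `inject_coincidences` adds
(never displaces) spikes: at each event time — Poisson by default, an
exact periodic comb when `periodic` is set — a random subset of neurons
receives one spike within ±jitter. Current phantoms provide exact
line-source and point-source potentials for the forward-model tests.

What the synthetic benchmarks do *not* emulate: refractoriness and
bursting (trains are Poisson), rate co-fluctuations beyond the shared
modulation envelope, electrode noise and filtering, and volume-conduction
inhomogeneities. Passing them shows the estimators recover known ground
truth under their own assumptions, not that those assumptions hold in any
particular recording.

## Degenerate inputs and tie-breaks

Empty spike files yield empty containers rather than errors; flat SCHs
yield "no oscillation" (no periods) and the duty cycle is then undefined
(raises on an empty period list); single-neuron populations have zero
coincidences by definition; epochs with fewer than two coincidence peaks
are excluded from frequency averaging and flagged. Spike times are stored
as float64 seconds and compared at 1 µs; sub-resolution duplicates are
rejected (containers) or collapsed (generators).

## Known limitations

* The surrogate network reproduces the construction rules and supports
  directional contrasts (activated > rest PT5B rate, determinism,
  Dale-sign structure); it is not calibrated to reproduce the published
  full-scale dynamics quantitatively, and beta-band phenomena at desk
  scale are attenuated relative to a 10,073-neuron column.
* The dipole LFP stand-in captures depth structure only coarsely.
* The NWB reader targets the package's own HDF5 layout and discovers label
  columns heuristically; arbitrary third-party NWB files may need a
  column-name mapping.
* GABA_B physiology is reduced to a slow inhibitory conductance.
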