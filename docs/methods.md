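# Methods

## Model

`engramsim` simulates a randomly connected conductance-based
excitatory-inhibitory (E-I) circuit of leaky integrate-and-fire neurons in
which memories are stored as *engrams*: disjoint groups of excitatory
neurons whose mutual synapses carry an elevated weight. The membrane
potential of neuron *i* of type *k* ∈ {E, I} follows

    τ_k dV_i/dt = V_L − V_i + G_i^E(t)(E_E − V_i) + G_i^I(t)(E_I − V_i),

with dimensionless conductances G accumulated from bi-exponential receptor
kernels: every presynaptic spike contributes

    S_R(t) = μ_R Θ(t − τ_l) / (τ_d^R − τ_r^R) · (e^{−(t−τ_l)/τ_d^R} − e^{−(t−τ_l)/τ_r^R})

for receptor class R (AMPA and NMDA for excitatory presynapses, GABA for
inhibitory ones), weighted by the synaptic weight w_{j→i}, and — for
recurrent excitatory synapses — by the Tsodyks-Markram release factor
u_j·x_j sampled at the spike time. External input is 400 independent
background Poisson trains per neuron, aggregated into a single Poisson
process at 400× the per-train rate (exactly equivalent in distribution) and
fed through AMPA kernels without short-term plasticity.

Short-term plasticity per excitatory presynaptic neuron:

    du/dt = (U − u)/τ_F + U(1 − u)·S(t)
    dx/dt = (1 − x)/τ_D − u·x·S(t)

with facilitation applied before release at a spike (u ← u + U(1−u), then
release = u·x, then x ← x − release).

Long-term plasticity acts on every E→E synapse as the sum of triplet STDP,
heterosynaptic plasticity, and transmitter-induced potentiation:

    dw/dt = S_post·A z_pre z_post^slow − S_pre·B z_post
            − S_post·β z_post³ ((w − w̃)/w̃)³ + δ₁ S_pre,

where the traces z jump by 1 at each spike of their own neuron and decay
with τ_STDP (fast) or τ_STDP^slow (slow). All trace factors are evaluated
at their values *before* the current spike's increment; at a simultaneous
pre/post pair within one step, pre-triggered terms apply first. Weights are
clamped to a floor of 0.001; no upper cap is applied by default, because
the heterosynaptic term (fourth order in activity) is the intended
stabilizer against the triplet term (third order).

## Numerics

* Clock-driven integration at dt = 0.05 ms using second-order Runge-Kutta
  (Heun), with conductances frozen within a step (operator splitting; dt is
  far below every kernel time constant).
* Spike-time correction: threshold crossings are located by linear
  interpolation inside the step; the neuron is then clamped at V_reset for
  the refractory period.
* Receptor kernels are carried by two exponential accumulators per
  (neuron, receptor) — one decaying with τ_d, one with τ_r — whose
  difference equals the sum of kernels over all past spikes exactly;
  synaptic latency is honored by a circular delay buffer at dt resolution.
  Unit tests verify the recursion against direct kernel summation to
  < 1e−10 and the clock-driven STP/plasticity updates against event-based
  closed forms to < 1e−6.
* Degenerate kernels (τ_d = τ_r within 1e−9 ms) use the alpha-function
  limit.
* Randomness is split into named streams: connectivity (numpy Generator
  seeded by the config seed), external input (engine RNG), and rescue
  resets (a private xorshift64* stream), so each protocol component is
  reproducible independently.

## Parameters

Membrane and receptor constants are adopted from the standard
conductance-based E-I circuit literature this model family builds on:
V_L = −70 mV, V_th = −50 mV, V_reset = −60 mV, E_E = 0 mV, E_I = −80 mV,
τ_E = 20 ms, τ_I = 10 ms, τ_ref = 2 ms; AMPA τ_r/τ_d = 0.5/2 ms, NMDA
2/100 ms, GABA 0.5/5 ms, latency 1 ms, unit kernel integrals. Short-term
plasticity uses U = 0.2, τ_F = 1500 ms, τ_D = 200 ms (facilitation-dominant
working-memory regime, τ_F ≫ τ_D). All are plain config fields.

Printed anchor values used as defaults: background rate 2.5 Hz per train
(400 trains), cue rate 12.5 Hz per train for 5 s per engram with cue onsets
15 s apart, non-coding E→E weight 0.02, E→I weight 0.10 (full scale),
learned/preset engram weight ≈ 0.55 (full scale), plastic-weight floor
0.001, persistent-state threshold 5 spikes/s with a 1 s moving window at
1 ms steps and sub-second gap merging.

## Desk-scale calibration

The full-scale circuit (2000 E / 400 I, 10 engrams of 200 neurons, 150 s
protocols, 10 trials) is too large for the package's test and example runs,
so protocol-level experiments run on a desk-scale circuit of 600 E / 120 I
neurons with engrams of 100, exposed as `protocols.scaled_config()`. Its
weights were recalibrated to a bistable operating point at C = 0.25:
g_M_EE = 0.25, g_EE = 0.02, g_I→E = 0.3, g_E→I = 0.25, g_I→I = 1.0,
external weights g_O_E = 0.016 / g_O_I = 0.05. The operating regime is
tonic-inhibition dominated: the inhibitory population fires at several Hz
from its own external drive while excitatory background firing is near
zero. In this regime the stability of the low-activity state scales with
the number of inhibitory afferents (∝ C) and the stability of the
persistent state scales with intra-engram recurrence (∝ C), which
reproduces the qualitative hysteresis behavior of the full model: a
staircase cue ramp (+0.2 Hz per 1 s block to f_bg + 2 Hz, then down to
f_bg − 2 Hz) shows a subcritical hysteresis loop whose stability measures
S_p = f_bg − (descending switch) and S_l = (ascending switch) − f_bg both
shrink as C is lowered through the bistable range (≈ 0.19-0.31).

Because the desk-scale external weight is larger than at full scale, a
12.5 Hz-per-train cue drives a desk engram to its refractory-limited rate;
desk protocol runs therefore use a cue of 3.5 Hz per train, which ignites
engrams reliably while keeping cued firing in the model's qualitative
range. The full-scale default remains 12.5 Hz.

For the rescue experiments the E→I weight is raised to 0.35 at the desk
scale so that cueing one engram recruits enough inhibition to terminate the
previously active engram (the competition mechanism that ends a persistent
state at the next cue); without this the rescued states outlive every
subsequent cue and the persistence score cannot measure the rescue benefit.

## Protocols

* **Recall** — engrams cued sequentially (5 s cue + 10 s gap); analysis
  windows span cue offset to the next onset; the first 5 s of each run are
  a discarded transient.
* **Rescue** — duty-cycled membrane resets: a fixed random half of the
  inhibitory population is chosen at simulation start; during the on-phase
  of each cycle (default 40 Hz, 50% duty) every chosen non-refractory
  neuron is reset to V_L with probability 0.5 per time step, from t = 5 s
  onward.
* **Excitability rescue** — elevated background to E neurons only.
* **Learning** — after warmup, Poisson learning input drives the learning
  engram (neurons 0-199 at full scale, engram 0 generally) while the
  long-term rule is active on all E→E synapses; weights are then frozen and
  all engrams recalled. Intra-engram mean weights are recorded at 1 s
  cadence.
* **Bifurcation** — single-engram staircase ramp described above; switch
  points are the first 1 s blocks crossing 5 spikes/s on each branch
  (interpolation-free; the 0.2 Hz ramp step is the precision). A missing
  crossing is reported as absent (None), never as zero.

## Statistics

Persistent states: moving-window (1 s, 1 ms step) population rate > 5/s,
with sub-second gaps merged and cue windows excluded; window rates are
assigned to the window's left edge and intervals are half-open in ms.
Persistence score: mean over engrams of ReLU(1 − |T_persist − T_ideal| /
T_ideal). Overlapping proportion: intersection-over-union of all engrams'
persistent-state time sets, cue windows excluded from both sides. Synchrony
index: Σ B_i B_j / √(Σ B_i Σ B_j) on 1 ms binary bins (identical trains
score 1; the unrooted variant is available behind a flag); population
synchrony averages up to 2000 sampled within-engram pairs. CV_ISI:
std/mean of inter-spike intervals (1 for Poisson firing, > 1 for bursts).
Oscillation power: squared rFFT magnitude of the mean-detrended average E
membrane potential (1 kHz trace, 10 s post-cue window), normalized to its
own mean, averaged in theta (4-12 Hz), slow-gamma (30-60 Hz) and fast-gamma
(60-120 Hz) bands. E/I ratio: |G_E(E_E − V)| / |G_I(E_I − V)| from recorded
population-mean current traces, with vanishing-inhibition samples flagged.

## Two-neuron lab

Pre- and postsynaptic spike trains are independent Poisson processes at
fixed rates (firing is imposed; the synapse's causal effect on
postsynaptic firing is deliberately ignored), driving one plastic synapse
for 100 s. The event-based integrator (exact exponential trace decay
between spikes) is the oracle for the clock-driven engine. Burst
manipulation: each spike is picked with probability p_pick, two spikes are
appended at +2 ms and +4 ms per pick (collisions move to the next free
0.05 ms slot), and 2N spikes are removed uniformly at random (possibly
including just-added ones), conserving the count while raising CV_ISI.

## Synthetic fixtures

`io_cli.generate_fixture_raster` draws inhomogeneous-Poisson rasters with
prescribed per-engram elevated intervals, providing exact ground truth for
the persistent-state metrics. Fixtures emulate rate structure only — no
synchrony, oscillations, refractoriness, or E-I interactions — so
fixture-driven tests validate the *metrics*, not the circuit dynamics.

## Known limitations

* No complete published parameter set exists for the full-scale circuit;
  defaults come from the standard source models of this family plus the
  desk-scale calibration above, so full-scale runs reproduce the
  architecture but not one specific parameterization.
* At desk scale, the learning engram's firing rate during a learning window
  *decreases* with connectivity C (its inhibitory afferent count grows with
  C while the tonic inhibitory rate does not fall proportionally). This
  rate confound dominates the burstiness-mediated heterosynaptic restraint
  (which does show the expected direction: CV_ISI during learning is lower
  at high C), so the mean learnt intra-engram weight at desk scale comes
  out *higher* at low C — opposite to the full-scale expectation. The
  corresponding acceptance check is retained and documents this limit; the
  two-neuron lab reproduces the underlying synapse-level mechanism
  (burstier firing → stronger heterosynaptic restraint → less potentiation)
  directly.
* At saturating drives (≈ 450 spikes/s) the per-spike cubic heterosynaptic
  update becomes numerically violent (trace z ≈ 9 gives updates of order
  β·z³); the desk configurations used by tests avoid this regime, and the
  optional weight cap `w_max` is available as a safety rail.
* NMDA kernels carry no magnesium-block voltage dependence; no receptor
  saturation; no homeostatic or inhibitory plasticity; no spatial
  structure.
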