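"""Configuration dataclasses and YAML (de)serialization.

All parameters of the circuit, synapse, plasticity, and protocol layers live
here.  Times are in ms unless a field name says otherwise (rates in Hz,
schedule fields in s).  Conductances and synaptic weights are dimensionless
(relative to the leak conductance).

Membrane, receptor, short-term-plasticity, and long-term-plasticity constants
default to values adopted from the standard source models for this class of
circuit (conductance-based E-I LIF network, Tsodyks-Markram synapses, triplet
STDP with heterosynaptic and transmitter-induced terms); all of them are
plain config fields and can be overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "NeuronParams",
    "ReceptorParams",
    "STPParams",
    "PlasticityParams",
    "NetworkConfig",
    "DegradationSpec",
    "CueSchedule",
    "RescueSpec",
    "SimParams",
    "load_config",
    "save_config",
]


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire constants for one population (E or I)."""

    tau_m: float = 20.0  # membrane time constant, ms
    v_leak: float = -70.0  # leak / resting potential, mV
    v_thresh: float = -50.0  # spike threshold, mV
    v_reset: float = -60.0  # post-spike reset, mV
    e_exc: float = 0.0  # excitatory reversal potential, mV
    e_inh: float = -80.0  # inhibitory reversal potential, mV
    tau_ref: float = 2.0  # absolute refractory period, ms

    def validate(self) -> None:
        if not (self.e_inh < self.v_leak < self.v_thresh < self.e_exc):
            raise ValueError(
                "potentials must satisfy E_I < V_L < V_th < E_E, got "
                f"{self.e_inh}, {self.v_leak}, {self.v_thresh}, {self.e_exc}"
            )
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")


@dataclass
class ReceptorParams:
    """Bi-exponential kernel constants for one receptor class.

    The kernel is mu/(tau_d - tau_r) * (exp(-(t-tau_l)/tau_d) -
    exp(-(t-tau_l)/tau_r)) for t > tau_l, zero before; its time integral is mu.
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    amplitude: float = 1.0  # mu_R, dimensionless
    latency: float = 1.0  # tau_l, ms

    def validate(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_decay < self.tau_rise:
            raise ValueError("tau_decay must be >= tau_rise")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def default_ampa() -> ReceptorParams:
    return ReceptorParams(tau_rise=0.5, tau_decay=2.0, amplitude=1.0, latency=1.0)


def default_nmda() -> ReceptorParams:
    return ReceptorParams(tau_rise=2.0, tau_decay=100.0, amplitude=1.0, latency=1.0)


def default_gaba() -> ReceptorParams:
    return ReceptorParams(tau_rise=0.5, tau_decay=5.0, amplitude=1.0, latency=1.0)


@dataclass
class STPParams:
    """Tsodyks-Markram short-term plasticity constants (per E presynaptic
    neuron): baseline release probability U, facilitation time constant tau_F
    and depression time constant tau_D, with tau_F >> tau_D."""

    U: float = 0.2
    tau_F: float = 1500.0  # ms
    tau_D: float = 200.0  # ms

    def validate(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must be in (0, 1]")
        if self.tau_F <= 0 or self.tau_D <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class PlasticityParams:
    """Composite long-term rule on E->E synapses: triplet STDP (amplitudes A
    potentiation / B depression), heterosynaptic restoring term (beta, preferred
    weight w_tilde), transmitter-induced increment delta1, with fast and slow
    postsynaptic traces."""

    A: float = 1.0e-2
    B: float = 1.0e-2
    beta: float = 25.0e-3
    w_tilde: float = 0.55  # preferred weight of the heterosynaptic term
    delta1: float = 2.0e-4
    tau_stdp: float = 20.0  # fast trace, ms
    tau_stdp_slow: float = 100.0  # slow trace, ms
    w_min: float = 0.001  # hard floor on plastic weights
    w_max: float = 0.0  # cap; <= 0 disables (heterosynaptic term is the stabilizer)

    def validate(self) -> None:
        if min(self.A, self.B, self.beta, self.delta1) < 0:
            raise ValueError("plasticity amplitudes must be non-negative")
        if self.tau_stdp_slow <= self.tau_stdp:
            raise ValueError("tau_stdp_slow must exceed tau_stdp")
        if self.w_min <= 0:
            raise ValueError("w_min must be positive")
        if self.w_tilde <= 0:
            raise ValueError("w_tilde must be positive")


@dataclass
class NetworkConfig:
    """Structural and synaptic parameters of the random E-I circuit."""

    nE: int = 2000
    nI: int = 400
    C: float = 0.25  # connection probability
    n_engrams: int = 10
    engram_size: int = 200
    g_EE: float = 0.02  # baseline (inter-engram, non-coding) E->E weight
    g_M_EE: float = 0.55  # intra-engram E->E weight
    g_IE: float = 0.35  # I->E
    g_EI: float = 0.10  # E->I
    g_II: float = 0.35  # I->I
    g_O_E: float = 0.0075  # external-input weight onto E neurons
    g_O_I: float = 0.0075  # external-input weight onto I neurons
    n_ext_trains: int = 400  # independent Poisson trains per neuron
    f_background: float = 2.5  # Hz per train
    seed: int = 0

    neuron_E: NeuronParams = field(default_factory=NeuronParams)
    neuron_I: NeuronParams = field(
        default_factory=lambda: NeuronParams(tau_m=10.0)
    )
    ampa: ReceptorParams = field(default_factory=default_ampa)
    nmda: ReceptorParams = field(default_factory=default_nmda)
    gaba: ReceptorParams = field(default_factory=default_gaba)
    stp: STPParams = field(default_factory=STPParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)

    def validate(self) -> None:
        if self.nE <= 0 or self.nI < 0:
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"connection probability C={self.C} outside [0, 1]")
        if self.n_engrams * self.engram_size > self.nE:
            raise ValueError(
                f"engram overflow: {self.n_engrams} x {self.engram_size} "
                f"> nE={self.nE}"
            )
        for name in ("g_EE", "g_M_EE", "g_IE", "g_EI", "g_II", "g_O_E", "g_O_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f_background < 0:
            raise ValueError("f_background must be non-negative")
        self.neuron_E.validate()
        self.neuron_I.validate()
        for r in (self.ampa, self.nmda, self.gaba):
            r.validate()
        self.stp.validate()
        self.plasticity.validate()

    @property
    def n_total(self) -> int:
        return self.nE + self.nI


@dataclass
class DegradationSpec:
    """Remaining fractions of neurons (R_N), connections (R_C), and synaptic
    strength (R_w), each in (0, 1], relative to the reference circuit built at
    C0 = 0.25 with N0 = nE + nI neurons and initial weights w0."""

    R_N: float = 1.0
    R_C: float = 1.0
    R_w: float = 1.0

    def validate(self) -> None:
        for name in ("R_N", "R_C", "R_w"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class CueSchedule:
    """Sequential-recall schedule: after a warmup, each engram in turn receives
    an elevated external cue for ``cue_s`` seconds followed by a
    ``gap_s``-second post-cue window, so consecutive cue onsets are
    cue_s + gap_s apart (15 s by default)."""

    engrams: list[int] = field(default_factory=lambda: list(range(10)))
    warmup_s: float = 5.0
    cue_s: float = 5.0
    gap_s: float = 10.0
    f_cue: float = 12.5  # Hz per external train, added on top of background
    f_background: float = 2.5

    @property
    def period_s(self) -> float:
        return self.cue_s + self.gap_s

    @property
    def t_ideal_s(self) -> float:
        """Ideal persistent-state duration: from one cue's offset to the next
        cue's onset."""
        return self.gap_s

    def cue_window_s(self, k: int) -> tuple[float, float]:
        """[onset, offset) of the k-th cue in seconds."""
        onset = self.warmup_s + k * self.period_s
        return onset, onset + self.cue_s

    @property
    def total_s(self) -> float:
        return self.warmup_s + len(self.engrams) * self.period_s

    def validate(self) -> None:
        if self.cue_s <= 0 or self.gap_s <= 0 or self.warmup_s < 0:
            raise ValueError("schedule durations must be positive")
        if self.f_cue < 0 or self.f_background < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class RescueSpec:
    """Duty-cycled membrane-reset stimulation of half of the inhibitory
    population, abstracting optogenetic interneuron suppression."""

    frequency: float = 40.0  # Hz
    duty_cycle: float = 0.5  # on-fraction of each cycle
    target_fraction: float = 0.5  # fraction of I neurons targeted
    start_s: float = 5.0  # after the warmup transient
    p_reset: float = 0.5  # per-step reset probability while on

    def validate(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty cycle must be in (0, 1)")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target fraction must be in [0, 1]")
        if not 0.0 <= self.p_reset <= 1.0:
            raise ValueError("p_reset must be in [0, 1]")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency

    @property
    def on_ms(self) -> float:
        return self.duty_cycle * self.period_ms


@dataclass
class SimParams:
    """Integrator settings: second-order Runge-Kutta at dt = 0.05 ms with
    linear spike-time interpolation inside the step."""

    dt: float = 0.05  # ms
    record_v_mean: bool = True  # population-mean E voltage at 1 ms cadence
    record_currents: bool = True  # population-mean E/I currents at 1 ms cadence
    weight_cadence_s: float = 1.0  # engram-mean weight recording cadence

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _NESTED.get((cls, f.name))
        kwargs[f.name] = _from_dict(sub, v) if sub and isinstance(v, dict) else v
    return cls(**kwargs)


_NESTED: dict[tuple[type, str], type] = {
    (NetworkConfig, "neuron_E"): NeuronParams,
    (NetworkConfig, "neuron_I"): NeuronParams,
    (NetworkConfig, "ampa"): ReceptorParams,
    (NetworkConfig, "nmda"): ReceptorParams,
    (NetworkConfig, "gaba"): ReceptorParams,
    (NetworkConfig, "stp"): STPParams,
    (NetworkConfig, "plasticity"): PlasticityParams,
}


def save_config(config: NetworkConfig, path: str | Path) -> None:
    """Write a NetworkConfig to a YAML file."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> NetworkConfig:
    """Read a NetworkConfig from a YAML file; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _from_dict(NetworkConfig, data)
    cfg.validate()
    return cfg
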