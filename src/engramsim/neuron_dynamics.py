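"""Integrate-and-fire membrane dynamics and network simulation driver.

The membrane equation per neuron i of type k is

    tau_k dV/dt = V_L - V + G_E(t) (E_E - V) + G_I(t) (E_I - V),

integrated with second-order Runge-Kutta at dt = 0.05 ms and linear
spike-time interpolation at threshold crossings; after a spike the neuron is
clamped at V_reset for the refractory period.  External drive is the
aggregate of 400 independent background Poisson trains per neuron (one
Poisson process at 400x the per-train rate, exactly equivalent in
distribution).

``simulate_network`` is the single entry point used by all protocols: it
converts a SynapticGraph plus per-neuron rate segments into the flat arrays
consumed by the jitted core and wraps the results in a SpikeRaster and
TraceSet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .config import NetworkConfig, PlasticityParams, RescueSpec, SimParams
from .network_builder import SynapticGraph

__all__ = [
    "SpikeRaster",
    "TraceSet",
    "SimulationResult",
    "leak_solution",
    "external_event_rate",
    "rescue_reset",
    "simulate_network",
]


@dataclass
class SpikeRaster:
    """Ordered spike events (time in ms, neuron id) for a whole run."""

    times_ms: np.ndarray
    ids: np.ndarray
    n_neurons: int
    duration_ms: float

    def __post_init__(self) -> None:
        order = np.argsort(self.times_ms, kind="stable")
        self.times_ms = np.asarray(self.times_ms, dtype=float)[order]
        self.ids = np.asarray(self.ids, dtype=np.int32)[order]

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    def select(self, neuron_ids: np.ndarray) -> "SpikeRaster":
        """Events restricted to the given neurons (ids unchanged)."""
        mask = np.isin(self.ids, neuron_ids)
        return SpikeRaster(
            self.times_ms[mask], self.ids[mask], self.n_neurons, self.duration_ms
        )

    def spike_times_of(self, neuron_id: int) -> np.ndarray:
        return self.times_ms[self.ids == neuron_id]

    def counts_per_neuron(self, t0_ms: float = 0.0, t1_ms: float | None = None):
        if t1_ms is None:
            t1_ms = self.duration_ms
        mask = (self.times_ms >= t0_ms) & (self.times_ms < t1_ms)
        return np.bincount(self.ids[mask], minlength=self.n_neurons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "neuron_id": self.ids})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int, duration_ms: float) -> "SpikeRaster":
        df = pd.read_csv(path)
        return cls(
            df["time_ms"].to_numpy(),
            df["neuron_id"].to_numpy(),
            n_neurons,
            duration_ms,
        )


@dataclass
class TraceSet:
    """Population-mean traces at 1 ms cadence over the E population."""

    v_mean_E: np.ndarray  # mV
    i_exc_mean_E: np.ndarray  # excitatory current G_E (E_E - V), mV units
    i_inh_mean_E: np.ndarray  # inhibitory current G_I (E_I - V), mV units
    dt_ms: float = 1.0


@dataclass
class SimulationResult:
    raster: SpikeRaster
    traces: TraceSet
    final_weights: np.ndarray  # per-edge, CSR order of the run
    weight_history: np.ndarray | None = None  # (n_records, n_groups)
    min_plastic_weight: float | None = None
    graph: SynapticGraph | None = None
    csr_edge_order: np.ndarray | None = None  # maps CSR edge -> graph edge index
    meta: dict = field(default_factory=dict)


def leak_solution(v0: float, t_ms, params) -> np.ndarray:
    """Closed-form input-free membrane trajectory
    V(t) = V_L + (V0 - V_L) exp(-t / tau_m)."""
    t = np.asarray(t_ms, dtype=float)
    return params.v_leak + (v0 - params.v_leak) * np.exp(-t / params.tau_m)


def external_event_rate(rate_hz: float, n_trains: int = 400) -> float:
    """Aggregate external event rate (Hz) seen by one neuron: the sum of
    ``n_trains`` independent Poisson trains at ``rate_hz`` each."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    return n_trains * rate_hz


def rescue_reset(
    v: np.ndarray,
    refractory: np.ndarray,
    chosen: np.ndarray,
    is_exc: np.ndarray,
    v_leak: float,
    on: bool,
    rng: np.random.Generator,
    p_reset: float = 0.5,
) -> np.ndarray:
    """One step of the membrane-reset rescue abstraction (reference
    implementation): while ``on``, each chosen non-refractory inhibitory
    neuron is reset to V_L independently with probability ``p_reset``."""
    if np.any(chosen & is_exc):
        raise ValueError("rescue target set contains excitatory neurons")
    if not on:
        return v
    v = v.copy()
    eligible = chosen & (refractory <= 0)
    hit = eligible & (rng.random(v.size) < p_reset)
    v[hit] = v_leak
    return v


def _csr_from_graph(graph: SynapticGraph):
    """CSR by presynaptic neuron; returns (indptr, targets, weights, order)
    where ``order`` maps CSR edge position -> original edge index."""
    n = graph.n_neurons
    order = np.argsort(graph.pre, kind="stable")
    pre_sorted = graph.pre[order]
    counts = np.bincount(pre_sorted, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    targets = graph.post[order].astype(np.int32)
    weights = graph.weight[order].astype(np.float64)
    return indptr, targets, weights, order


def _kernel_constants(params, dt: float):
    fd = float(np.exp(-dt / params.tau_decay))
    fr = float(np.exp(-dt / params.tau_rise))
    gain = params.amplitude / (params.tau_decay - params.tau_rise)
    delay = max(1, int(round(params.latency / dt)))
    return fd, fr, gain, delay


def _plasticity_dict(
    graph: SynapticGraph,
    indptr,
    targets,
    csr_order,
    params: PlasticityParams,
    start_step: int,
    end_step: int,
    dt: float,
):
    n = graph.n_neurons
    pre_of_edge = np.repeat(np.arange(n, dtype=np.int32), np.diff(indptr))
    plastic = graph.is_exc[pre_of_edge] & graph.is_exc[targets]
    # incoming-plastic-edge CSC: for each post neuron, its E->E afferents
    edge_idx = np.flatnonzero(plastic)
    post_of = targets[edge_idx]
    o = np.argsort(post_of, kind="stable")
    in_edge = edge_idx[o].astype(np.int64)
    in_src = pre_of_edge[edge_idx][o].astype(np.int32)
    counts = np.bincount(post_of[o], minlength=n)
    in_indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=in_indptr[1:])
    return dict(
        plast_on=True,
        plast_start_step=start_step,
        plast_end_step=end_step,
        pA=params.A,
        pB=params.B,
        p_beta=params.beta,
        p_wtilde=params.w_tilde,
        p_delta1=params.delta1,
        fz=float(np.exp(-dt / params.tau_stdp)),
        fz_slow=float(np.exp(-dt / params.tau_stdp_slow)),
        w_min=params.w_min,
        w_max=params.w_max,
        in_indptr=in_indptr,
        in_src=in_src,
        in_edge=in_edge,
        plastic_edge=plastic,
    )


def choose_rescue_targets(
    graph: SynapticGraph, fraction: float, seed: int
) -> np.ndarray:
    """Fixed random subset of the inhibitory population, drawn once at
    simulation start."""
    rng = np.random.default_rng(seed)
    inh = np.flatnonzero(~graph.is_exc)
    k = int(round(fraction * inh.size))
    chosen_ids = rng.choice(inh, size=k, replace=False)
    chosen = np.zeros(graph.n_neurons, dtype=bool)
    chosen[chosen_ids] = True
    return chosen


def simulate_network(
    graph: SynapticGraph,
    duration_s: float,
    *,
    ext_rate_segments: list[tuple[float, np.ndarray]] | None = None,
    rescue: RescueSpec | None = None,
    rescue_seed: int = 1,
    ext_seed: int = 1,
    plasticity_window_s: tuple[float, float] | None = None,
    sim: SimParams | None = None,
    weight_groups: bool = False,
    initial_weights: np.ndarray | None = None,
    max_spikes: int | None = None,
) -> SimulationResult:
    """Run the network for ``duration_s`` seconds.

    ``ext_rate_segments`` is a list of (segment_end_s, per-neuron aggregate
    event rate in Hz) pairs covering [0, duration]; by default every neuron
    receives 400 x f_background.  ``plasticity_window_s`` enables the
    long-term rule on E->E synapses within [start, end) seconds.  With
    ``weight_groups`` the per-engram mean intra-engram weight is recorded
    every SimParams.weight_cadence_s.
    """
    cfg: NetworkConfig = graph.config
    sim = sim or SimParams()
    sim.validate()
    dt = sim.dt
    n_steps = int(round(duration_s * 1000.0 / dt))
    n = graph.n_neurons

    indptr, targets, weights, order = _csr_from_graph(graph)
    if initial_weights is not None:
        weights = initial_weights[order].astype(np.float64).copy()

    tau_m = np.where(graph.is_exc, cfg.neuron_E.tau_m, cfg.neuron_I.tau_m)
    pE, pI = cfg.neuron_E, cfg.neuron_I
    v_leak = np.where(graph.is_exc, pE.v_leak, pI.v_leak)
    v_thresh = np.where(graph.is_exc, pE.v_thresh, pI.v_thresh)
    v_reset = np.where(graph.is_exc, pE.v_reset, pI.v_reset)
    e_exc = np.where(graph.is_exc, pE.e_exc, pI.e_exc)
    e_inh = np.where(graph.is_exc, pE.e_inh, pI.e_inh)
    ref_steps = np.where(
        graph.is_exc,
        int(round(pE.tau_ref / dt)),
        int(round(pI.tau_ref / dt)),
    ).astype(np.int64)

    if ext_rate_segments is None:
        base = np.full(
            n, external_event_rate(cfg.f_background, cfg.n_ext_trains)
        )
        ext_rate_segments = [(duration_s, base)]
    seg_end_step = np.array(
        [int(round(t * 1000.0 / dt)) for t, _ in ext_rate_segments],
        dtype=np.int64,
    )
    ext_rate_per_step = np.stack(
        [np.asarray(r, dtype=float) * dt / 1000.0 for _, r in ext_rate_segments]
    )
    g_ext = np.where(graph.is_exc, cfg.g_O_E, cfg.g_O_I).astype(np.float64)

    kernels = {
        "ampa": _kernel_constants(cfg.ampa, dt),
        "nmda": _kernel_constants(cfg.nmda, dt),
        "gaba": _kernel_constants(cfg.gaba, dt),
    }

    plast = None
    if plasticity_window_s is not None:
        s0, s1 = plasticity_window_s
        plast = _plasticity_dict(
            graph,
            indptr,
            targets,
            order,
            cfg.plasticity,
            int(round(s0 * 1000.0 / dt)),
            int(round(s1 * 1000.0 / dt)),
            dt,
        )

    resc = None
    if rescue is not None:
        rescue.validate()
        chosen = choose_rescue_targets(graph, rescue.target_fraction, rescue_seed)
        period_steps = max(1, int(round(rescue.period_ms / dt)))
        resc = dict(
            rescue_on=True,
            rescue_start_step=int(round(rescue.start_s * 1000.0 / dt)),
            rescue_period_steps=period_steps,
            rescue_on_steps=int(round(rescue.duty_cycle * period_steps)),
            rescue_chosen=chosen,
            rescue_p=rescue.p_reset,
            rescue_seed=rescue_seed,
        )

    edge_group = None
    n_groups = 0
    cadence_steps = 0
    if weight_groups:
        pre_of_edge = np.repeat(np.arange(n, dtype=np.int32), np.diff(indptr))
        eg_pre = graph.engram_id[pre_of_edge]
        eg_post = graph.engram_id[targets]
        edge_group = np.where(
            (eg_pre >= 0) & (eg_pre == eg_post), eg_pre, -1
        ).astype(np.int32)
        n_groups = graph.n_engrams
        cadence_steps = int(round(sim.weight_cadence_s * 1000.0 / dt))

    stp = cfg.stp
    out = _engine.run_simulation(
        dt=dt,
        n_steps=n_steps,
        is_exc=graph.is_exc,
        tau_m=tau_m.astype(np.float64),
        v_leak=v_leak.astype(np.float64),
        v_thresh=v_thresh.astype(np.float64),
        v_reset=v_reset.astype(np.float64),
        e_exc=e_exc.astype(np.float64),
        e_inh=e_inh.astype(np.float64),
        ref_steps=ref_steps,
        indptr=indptr,
        targets=targets,
        syn_w=weights,
        kernels=kernels,
        seg_end_step=seg_end_step,
        ext_rate_per_step=ext_rate_per_step,
        g_ext=g_ext,
        ext_seed=int(ext_seed) % (2**31),
        stp_U=stp.U,
        stp_fu=float(np.exp(-dt / stp.tau_F)),
        stp_fx=float(np.exp(-dt / stp.tau_D)),
        plasticity=plast,
        rescue=resc,
        edge_group=edge_group,
        n_groups=n_groups,
        weight_cadence_steps=cadence_steps,
        max_spikes=max_spikes,
        ms_steps=int(round(1.0 / dt)),
    )
    spike_t, spike_id, v_mean, i_exc, i_inh, w_hist, min_w = out

    raster = SpikeRaster(spike_t, spike_id, n, duration_s * 1000.0)
    traces = TraceSet(v_mean, i_exc, i_inh)
    return SimulationResult(
        raster=raster,
        traces=traces,
        final_weights=weights,
        weight_history=w_hist if weight_groups else None,
        min_plastic_weight=min_w if plast is not None else None,
        graph=graph,
        csr_edge_order=order,
        meta={"duration_s": duration_s, "dt": dt, "ext_seed": ext_seed},
    )
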