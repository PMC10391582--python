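"""Composite long-term plasticity on E->E synapses.

The weight from presynaptic neuron j to postsynaptic neuron i evolves by

    dw/dt =  S_i(t) * A z_j z_i^slow          (triplet potentiation)
           - S_j(t) * B z_i                   (pre-triggered depression)
           - S_i(t) * beta z_i^3 ((w - w~)/w~)^3   (heterosynaptic)
           + delta1 S_j(t)                    (transmitter-induced)

where z are presynaptic/postsynaptic traces that jump by 1 at each own spike
and decay exponentially (fast tau_STDP, slow tau_STDP_slow).  All trace
factors are evaluated at their values *before* the current spike's +1
increment.  A hard floor w_min = 0.001 prevents silent or negative synapses;
the heterosynaptic cubic (fourth order in activity, vs third for the triplet
term) is the stabilizer against runaway potentiation, so no cap is applied
by default.

This module holds the event-level reference operations; the network engine
applies the identical updates inside its clock-driven loop, and the
two-neuron lab composes these into an exact event-based integrator that
serves as the oracle for clock-driven runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PlasticityParams
from .neuron_dynamics import SimulationResult, simulate_network

__all__ = [
    "TraceState",
    "trace_update",
    "trace_decay",
    "on_pre_spike",
    "on_post_spike",
    "clamp_weight",
    "run_learning_window",
]


@dataclass
class TraceState:
    """Fast and slow spike traces for one neuron or an array of neurons."""

    z: np.ndarray | float
    z_slow: np.ndarray | float
    params: PlasticityParams

    @classmethod
    def zeros(cls, n: int | None, params: PlasticityParams) -> "TraceState":
        if n is None:
            return cls(0.0, 0.0, params)
        return cls(np.zeros(n), np.zeros(n), params)


def trace_decay(traces: TraceState, dt: float) -> TraceState:
    """Exact exponential decay of both traces over ``dt`` ms."""
    p = traces.params
    return replace(
        traces,
        z=traces.z * np.exp(-dt / p.tau_stdp),
        z_slow=traces.z_slow * np.exp(-dt / p.tau_stdp_slow),
    )


def trace_update(traces: TraceState, spikes, dt: float) -> TraceState:
    """One clock step: decay by ``dt`` then +1 for each spiking neuron.

    ``spikes`` is a boolean mask (array state) or bool (scalar state).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = trace_decay(traces, dt)
    if np.isscalar(t.z):
        if spikes:
            return replace(t, z=t.z + 1.0, z_slow=t.z_slow + 1.0)
        return t
    inc = np.asarray(spikes, dtype=float)
    return replace(t, z=t.z + inc, z_slow=t.z_slow + inc)


def clamp_weight(w: float, params: PlasticityParams) -> float:
    w = max(w, params.w_min)
    if params.w_max > 0.0:
        w = min(w, params.w_max)
    return w


def on_pre_spike(w: float, z_post: float, params: PlasticityParams) -> float:
    """Weight update at a presynaptic spike: depression by B z_i plus the
    transmitter-induced increment delta1, with z_post at its pre-update
    value; result clamped to the floor."""
    return clamp_weight(w - params.B * z_post + params.delta1, params)


def on_post_spike(
    w: float,
    z_pre: float,
    z_post_slow: float,
    z_post: float,
    params: PlasticityParams,
) -> float:
    """Weight update at a postsynaptic spike: triplet potentiation
    A z_j z_i^slow and the heterosynaptic restoring term
    -beta z_i^3 ((w - w~)/w~)^3, traces at pre-update values."""
    if params.w_tilde == 0:
        raise ValueError("w_tilde must be non-zero")
    dev = (w - params.w_tilde) / params.w_tilde
    w_new = w + params.A * z_pre * z_post_slow - params.beta * z_post**3 * dev**3
    return clamp_weight(w_new, params)


def run_learning_window(
    graph,
    duration_s: float,
    *,
    learn_start_s: float,
    learn_end_s: float,
    ext_rate_segments=None,
    ext_seed: int = 1,
    sim=None,
) -> SimulationResult:
    """Run the network with plasticity enabled in [learn_start, learn_end) s,
    recording the mean intra-engram weight per engram at the configured
    cadence (default 1 s)."""
    if learn_end_s < learn_start_s:
        raise ValueError("learning window must be ordered")
    return simulate_network(
        graph,
        duration_s,
        ext_rate_segments=ext_rate_segments,
        plasticity_window_s=(learn_start_s, learn_end_s),
        ext_seed=ext_seed,
        sim=sim,
        weight_groups=True,
    )
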