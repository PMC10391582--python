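"""Receptor kernels, conductance accumulation, and short-term plasticity.

A presynaptic spike at time t0 contributes a bi-exponential conductance time
course to its targets,

    S_R(t) = mu_R / (tau_d - tau_r) * (exp(-(t - tau_l)/tau_d)
                                       - exp(-(t - tau_l)/tau_r)),  t > tau_l,

gated by a Heaviside step at the synaptic latency tau_l.  The effective
conductance of a postsynaptic neuron is tau_k times the weighted sum of
kernels over all presynaptic spikes; excitatory (E) presynapses drive AMPA
plus NMDA kernels scaled additionally by the Tsodyks-Markram release factor
u*x sampled at the spike, inhibitory (I) presynapses drive GABA kernels, and
external Poisson input drives AMPA kernels without short-term plasticity.

Numerically the kernel sum is carried by two exponential accumulators per
(postsynaptic neuron, receptor) pair — one decaying with tau_d, one with
tau_r — whose difference reproduces the sum over all past spikes exactly
(up to floating point), so no spike history needs to be stored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ReceptorParams, STPParams

__all__ = [
    "kernel_value",
    "kernel_peak_time",
    "STPState",
    "stp_on_spike",
    "stp_decay",
    "ConductanceState",
    "accumulate_conductances",
]

# below this rise/decay separation the analytic alpha-function limit is used
_DEGENERATE_TAU = 1e-9


def kernel_value(t, params: ReceptorParams):
    """Evaluate the bi-exponential kernel S_R at time(s) ``t`` (ms).

    Returns 0 for t < tau_l and the difference-of-exponentials elsewhere;
    when tau_d == tau_r (within 1e-9 ms) the alpha-function limit
    mu * s * exp(-s/tau) / tau^2 with s = t - tau_l is used.
    """
    t = np.asarray(t, dtype=float)
    s = t - params.latency
    out = np.zeros_like(s)
    pos = s > 0
    tau_d, tau_r = params.tau_decay, params.tau_rise
    if abs(tau_d - tau_r) < _DEGENERATE_TAU:
        out[pos] = (
            params.amplitude * s[pos] * np.exp(-s[pos] / tau_d) / tau_d**2
        )
    else:
        out[pos] = (
            params.amplitude
            / (tau_d - tau_r)
            * (np.exp(-s[pos] / tau_d) - np.exp(-s[pos] / tau_r))
        )
    return out if out.ndim else float(out)


def kernel_peak_time(params: ReceptorParams) -> float:
    """Time (ms) at which the kernel attains its maximum:
    tau_l + tau_d*tau_r/(tau_d - tau_r) * ln(tau_d/tau_r)."""
    tau_d, tau_r = params.tau_decay, params.tau_rise
    if abs(tau_d - tau_r) < _DEGENERATE_TAU:
        return params.latency + tau_d
    return params.latency + tau_d * tau_r / (tau_d - tau_r) * np.log(tau_d / tau_r)


@dataclass
class STPState:
    """Release probability u and neurotransmitter fraction x of one (or an
    array of) presynaptic E neuron(s), with their governing constants."""

    u: np.ndarray | float
    x: np.ndarray | float
    params: STPParams

    @classmethod
    def resting(cls, n: int | None, params: STPParams) -> "STPState":
        if n is None:
            return cls(u=params.U, x=1.0, params=params)
        return cls(
            u=np.full(n, params.U, dtype=float),
            x=np.ones(n, dtype=float),
            params=params,
        )


def stp_on_spike(state: STPState, spiking=None) -> tuple[STPState, np.ndarray | float]:
    """Apply the on-spike jump and return (new state, release factor u*x).

    Facilitation is applied before release: u <- u + U(1-u), then
    release = u_new * x, then x <- x - release.  ``spiking`` optionally masks
    which elements of an array state spike; others are untouched.
    """
    U = state.params.U
    u, x = state.u, state.x
    if spiking is None:
        u_new = u + U * (1.0 - u)
        release = u_new * x
        x_new = x - release
    else:
        u_new = np.where(spiking, u + U * (1.0 - u), u)
        release = np.where(spiking, u_new * x, 0.0)
        x_new = x - release
    return replace(state, u=u_new, x=x_new), release


def stp_decay(state: STPState, dt: float) -> STPState:
    """Exact exponential relaxation over ``dt`` ms: u -> U with tau_F,
    x -> 1 with tau_D."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    fu = np.exp(-dt / p.tau_F)
    fx = np.exp(-dt / p.tau_D)
    return replace(
        state,
        u=p.U + (state.u - p.U) * fu,
        x=1.0 + (state.x - 1.0) * fx,
    )


class ConductanceState:
    """Difference-of-exponentials accumulators for one receptor class over a
    population of postsynaptic neurons.

    ``a`` decays with tau_d and ``b`` with tau_r; a spike of size ``amp``
    (weight x release x mu/(tau_d - tau_r)) adds amp to both; the kernel sum
    is a - b.  Latency is honored by a circular delay buffer of pending
    increments at dt resolution.
    """

    def __init__(self, n: int, params: ReceptorParams, dt: float):
        params.validate()
        self.params = params
        self.dt = dt
        self.n = n
        self.a = np.zeros(n)
        self.b = np.zeros(n)
        tau_d, tau_r = params.tau_decay, params.tau_rise
        self._fd = np.exp(-dt / tau_d)
        self._fr = np.exp(-dt / tau_r)
        self._gain = params.amplitude / (tau_d - tau_r)
        self.delay_steps = max(1, int(round(params.latency / dt)))
        self._buffer = np.zeros((self.delay_steps, n))
        self._head = 0

    def add_spikes(self, targets: np.ndarray, amounts) -> None:
        """Queue weighted increments (weight x release factor) for delivery
        after the synaptic latency."""
        np.add.at(self._buffer[self._head], targets, amounts)

    def step(self) -> None:
        """Advance one dt: decay accumulators and deliver due increments."""
        self.a *= self._fd
        self.b *= self._fr
        tail = (self._head + 1) % self.delay_steps
        due = self._buffer[tail]
        inc = due * self._gain
        self.a += inc
        self.b += inc
        due[:] = 0.0
        self._head = tail

    @property
    def kernel_sum(self) -> np.ndarray:
        """Sum of kernel values over all delivered past spikes."""
        return self.a - self.b


def accumulate_conductances(
    states: dict[str, ConductanceState],
    tau_m: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine receptor accumulators into effective conductances.

    Returns (G_exc, G_inh) = tau_m * (AMPA + NMDA sums), tau_m * GABA sum,
    as entering the membrane equation.
    """
    g_exc = tau_m * (states["ampa"].kernel_sum + states["nmda"].kernel_sum)
    g_inh = tau_m * states["gaba"].kernel_sum
    return g_exc, g_inh
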