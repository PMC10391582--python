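"""Two-neuron plasticity lab.

A presynaptic and a postsynaptic neuron fire as independent Poisson
processes with fixed rates (firing is imposed, so the membrane model is
bypassed and the causal effect of the synapse on postsynaptic firing is
deliberately ignored), and the single connecting synapse evolves under the
composite long-term rule.  The event-based integrator here uses exact
exponential trace decay between spikes and is the closed-form oracle against
which the clock-driven engine is validated.

``burstify`` implements the burst-manipulation procedure: each spike is
picked with probability p_pick, two extra spikes are appended 2 ms and 4 ms
after every picked spike, and the same number of spikes (2N) is then removed
uniformly at random, so the spike count is conserved while CV_ISI grows
with p_pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PlasticityParams
from .plasticity import clamp_weight

__all__ = ["PairExperiment", "PairResult", "simulate_pair", "burstify"]

SPIKE_GRID_MS = 0.05  # event-time resolution for burst insertion


@dataclass
class PairExperiment:
    pre_rate: float  # Hz
    post_rate: float  # Hz
    duration_s: float = 100.0
    w0: float = 0.02
    params: PlasticityParams = field(default_factory=PlasticityParams)
    p_pick: float = 0.0  # burst manipulation applied to both trains
    seed: int = 0

    def validate(self) -> None:
        if self.pre_rate < 0 or self.post_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_pick <= 1.0:
            raise ValueError("p_pick must be in [0, 1]")
        self.params.validate()


@dataclass
class PairResult:
    final_weight: float
    times_ms: np.ndarray  # event (or step) times of the trajectory
    weights: np.ndarray
    pre_times_ms: np.ndarray
    post_times_ms: np.ndarray


def _poisson_train(rate_hz: float, duration_s: float, rng) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.random(n) * duration_s * 1000.0)


def simulate_pair(exp: PairExperiment, method: str = "event") -> PairResult:
    """Run the pair experiment; ``method`` is "event" (exact event-based
    integration, the reference) or "clock" (dt = 0.05 ms clock-driven
    updates mirroring the network engine)."""
    exp.validate()
    rng = np.random.default_rng(exp.seed)
    pre = _poisson_train(exp.pre_rate, exp.duration_s, rng)
    post = _poisson_train(exp.post_rate, exp.duration_s, rng)
    if exp.p_pick > 0:
        pre = burstify(pre, exp.p_pick, seed=rng.integers(2**31))
        post = burstify(post, exp.p_pick, seed=rng.integers(2**31))
    if method == "event":
        t, w = _run_events(pre, post, exp.w0, exp.params)
    elif method == "clock":
        t, w = _run_clock(pre, post, exp.w0, exp.params, exp.duration_s)
    else:
        raise ValueError(f"unknown method {method!r}")
    final = w[-1] if w.size else exp.w0
    return PairResult(
        final_weight=float(final),
        times_ms=t,
        weights=w,
        pre_times_ms=pre,
        post_times_ms=post,
    )


def _run_events(pre, post, w0, p: PlasticityParams):
    """Exact event-based integration; pre-events are processed before
    post-events at a tie, and trace factors are taken before the current
    spike's own +1."""
    events = np.concatenate([pre, post])
    kinds = np.concatenate(
        [np.zeros(pre.size, np.int8), np.ones(post.size, np.int8)]
    )
    order = np.lexsort((kinds, events))
    events, kinds = events[order], kinds[order]

    w = w0
    z_pre = z_post = z_slow = 0.0
    t_last = 0.0
    ts, ws = [], []
    i = 0
    n = events.size
    while i < n:
        t = events[i]
        dt = t - t_last
        if dt > 0:
            z_pre *= np.exp(-dt / p.tau_stdp)
            z_post *= np.exp(-dt / p.tau_stdp)
            z_slow *= np.exp(-dt / p.tau_stdp_slow)
            t_last = t
        # group simultaneous events: pre updates first, then post updates,
        # then all trace increments (matching the clock-driven convention)
        j = i
        n_pre = n_post = 0
        while j < n and events[j] == t:
            if kinds[j] == 0:
                n_pre += 1
            else:
                n_post += 1
            j += 1
        for _ in range(n_pre):
            w = clamp_weight(w - p.B * z_post + p.delta1, p)
        for _ in range(n_post):
            dev = (w - p.w_tilde) / p.w_tilde
            w = clamp_weight(
                w + p.A * z_pre * z_slow - p.beta * z_post**3 * dev**3, p
            )
        z_pre += n_pre
        z_post += n_post
        z_slow += n_post
        ts.append(t)
        ws.append(w)
        i = j
    return np.asarray(ts), np.asarray(ws)


def _run_clock(pre, post, w0, p: PlasticityParams, duration_s, dt=SPIKE_GRID_MS):
    """Clock-driven counterpart at the engine's resolution: decay traces per
    step, then pre-spike updates, post-spike updates, trace increments."""
    n_steps = int(round(duration_s * 1000.0 / dt))
    pre_step = np.bincount(
        np.minimum(np.round(pre / dt).astype(np.int64), n_steps - 1),
        minlength=n_steps,
    )
    post_step = np.bincount(
        np.minimum(np.round(post / dt).astype(np.int64), n_steps - 1),
        minlength=n_steps,
    )
    fz = np.exp(-dt / p.tau_stdp)
    fzs = np.exp(-dt / p.tau_stdp_slow)
    w = w0
    z_pre = z_post = z_slow = 0.0
    ts, ws = [], []
    active = np.flatnonzero(pre_step | post_step)
    prev = -1
    for s in active:
        gap = s - prev - 1
        if gap > 0:
            z_pre *= fz**gap
            z_post *= fz**gap
            z_slow *= fzs**gap
        prev = s
        # within-step order matches the engine: decay happened at step start
        z_pre *= fz
        z_post *= fz
        z_slow *= fzs
        for _ in range(pre_step[s]):
            w = clamp_weight(w - p.B * z_post + p.delta1, p)
        for _ in range(post_step[s]):
            dev = (w - p.w_tilde) / p.w_tilde
            w = clamp_weight(
                w + p.A * z_pre * z_slow - p.beta * z_post**3 * dev**3, p
            )
        z_pre += pre_step[s]
        z_post += post_step[s]
        z_slow += post_step[s]
        ts.append((s + 1) * dt)
        ws.append(w)
    return np.asarray(ts), np.asarray(ws)


def burstify(train_ms: np.ndarray, p_pick: float, seed: int = 0) -> np.ndarray:
    """Burst manipulation preserving the spike count.

    Each spike is picked independently with probability ``p_pick`` (N
    picked, without replacement); spikes are appended at t+2 ms and t+4 ms
    after every pick (collisions move to the next free 0.05 ms slot); then
    exactly 2N spikes are removed uniformly at random from the augmented
    train, which may include just-added spikes.
    """
    train_ms = np.sort(np.asarray(train_ms, dtype=float))
    if train_ms.size == 0:
        raise ValueError("burstify needs at least one spike")
    if not 0.0 <= p_pick <= 1.0:
        raise ValueError("p_pick must be in [0, 1]")
    if p_pick == 0.0:
        return train_ms.copy()
    rng = np.random.default_rng(seed)
    picked = rng.random(train_ms.size) < p_pick
    n_picked = int(picked.sum())
    if n_picked == 0:
        return train_ms.copy()

    occupied = set(np.round(train_ms / SPIKE_GRID_MS).astype(np.int64).tolist())
    new_slots = []
    for t in train_ms[picked]:
        for off in (2.0, 4.0):
            slot = int(round((t + off) / SPIKE_GRID_MS))
            while slot in occupied:
                slot += 1
            occupied.add(slot)
            new_slots.append(slot)
    augmented = np.concatenate(
        [train_ms, np.asarray(new_slots, dtype=float) * SPIKE_GRID_MS]
    )
    n_remove = 2 * n_picked
    if n_remove >= augmented.size:
        raise ValueError("train too short to remove 2N spikes")
    drop = rng.choice(augmented.size, size=n_remove, replace=False)
    keep = np.ones(augmented.size, dtype=bool)
    keep[drop] = False
    return np.sort(augmented[keep])
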