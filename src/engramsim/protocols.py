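"""Experiment drivers: sequential recall, rescue stimulation, excitability
rescue, learning-then-recall, and the bifurcation ramp with stability
measures.

All protocols share the drive convention: every neuron receives the
aggregate of 400 background Poisson trains at f_background; a cued engram
additionally receives 400 trains at f_cue during its cue window.  The first
warmup seconds are a transient and excluded from analysis.  Recall quality
is measured in the 10 s window from each cue's end to the next cue's onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import CueSchedule, NetworkConfig, RescueSpec, SimParams
from .metrics import (
    build_state_table,
    overlapping_proportion,
    persistence_score,
    population_rate,
)
from .neuron_dynamics import (
    SimulationResult,
    external_event_rate,
    simulate_network,
)
from .network_builder import SynapticGraph, build_network

__all__ = [
    "RecallRun",
    "BifurcationResult",
    "run_recall",
    "run_rescue",
    "run_excitability_rescue",
    "run_learning",
    "run_bifurcation",
    "switch_points_from_ramp",
    "build_learning_network",
    "scaled_config",
    "recall_metrics",
]


# ---------------------------------------------------------------------------
# drive schedules

def _cue_segments(
    graph: SynapticGraph, schedule: CueSchedule
) -> list[tuple[float, np.ndarray]]:
    """Piecewise-constant per-neuron external event rates for a sequential
    recall schedule."""
    cfg = graph.config
    n = graph.n_neurons
    base = np.full(n, external_event_rate(schedule.f_background, cfg.n_ext_trains))
    segments: list[tuple[float, np.ndarray]] = []
    t = 0.0
    if schedule.warmup_s > 0:
        segments.append((schedule.warmup_s, base))
        t = schedule.warmup_s
    for pos, eng in enumerate(schedule.engrams):
        onset, offset = schedule.cue_window_s(pos)
        if onset > t:
            segments.append((onset, base))
        cued = base.copy()
        members = graph.engram_members(eng)
        cued[members] = external_event_rate(
            schedule.f_background + schedule.f_cue, cfg.n_ext_trains
        )
        segments.append((offset, cued))
        segments.append((offset + schedule.gap_s, base))
        t = offset + schedule.gap_s
    return segments


@dataclass
class RecallRun:
    """A recall-protocol run: the simulation output plus its schedule."""

    result: SimulationResult
    schedule: CueSchedule
    graph: SynapticGraph


def run_recall(
    graph: SynapticGraph,
    schedule: CueSchedule | None = None,
    seed: int = 1,
    sim: SimParams | None = None,
) -> RecallRun:
    """Sequential recall: each engram in the schedule is cued in turn."""
    if schedule is None:
        schedule = CueSchedule(engrams=list(range(graph.n_engrams)))
    schedule.validate()
    segments = _cue_segments(graph, schedule)
    result = simulate_network(
        graph,
        schedule.total_s,
        ext_rate_segments=segments,
        ext_seed=seed,
        sim=sim,
    )
    return RecallRun(result=result, schedule=schedule, graph=graph)


def run_rescue(
    graph: SynapticGraph,
    schedule: CueSchedule | None = None,
    rescue: RescueSpec | None = None,
    seed: int = 1,
    sim: SimParams | None = None,
) -> RecallRun:
    """Recall with duty-cycled membrane-reset rescue stimulation applied to
    half of the inhibitory neurons from the end of the warmup onward."""
    if schedule is None:
        schedule = CueSchedule(engrams=list(range(graph.n_engrams)))
    rescue = rescue or RescueSpec()
    rescue.validate()
    schedule.validate()
    segments = _cue_segments(graph, schedule)
    result = simulate_network(
        graph,
        schedule.total_s,
        ext_rate_segments=segments,
        rescue=rescue,
        rescue_seed=seed + 7919,  # independent named stream
        ext_seed=seed,
        sim=sim,
    )
    return RecallRun(result=result, schedule=schedule, graph=graph)


def run_excitability_rescue(
    graph: SynapticGraph,
    f_background_exc: float,
    schedule: CueSchedule | None = None,
    seed: int = 1,
    sim: SimParams | None = None,
) -> RecallRun:
    """Recall with elevated background drive to E neurons only; I neurons
    keep the standard background rate."""
    if schedule is None:
        schedule = CueSchedule(engrams=list(range(graph.n_engrams)))
    if f_background_exc < schedule.f_background:
        raise ValueError("f_background_exc must be >= f_background")
    schedule.validate()
    cfg = graph.config
    segments = []
    boost = external_event_rate(
        f_background_exc - schedule.f_background, cfg.n_ext_trains
    )
    for t_end, rates in _cue_segments(graph, schedule):
        r = rates.copy()
        r[graph.is_exc] += boost
        segments.append((t_end, r))
    result = simulate_network(
        graph, schedule.total_s, ext_rate_segments=segments, ext_seed=seed, sim=sim
    )
    return RecallRun(result=result, schedule=schedule, graph=graph)


def recall_metrics(run: RecallRun) -> dict:
    """Persistence score, overlapping proportion, and per-engram population
    rates over the post-cue analysis windows."""
    members = {
        k: run.graph.engram_members(k) for k in run.schedule.engrams
    }
    table = build_state_table(run.result.raster, members, run.schedule)
    rates = {}
    for pos, eng in enumerate(run.schedule.engrams):
        _, off = run.schedule.cue_window_s(pos)
        rates[eng] = population_rate(
            run.result.raster,
            members[eng],
            off * 1000.0,
            (off + run.schedule.gap_s) * 1000.0,
        )
    out = {
        "persistence_score": persistence_score(table),
        "population_rate_hz": rates,
        "table": table,
    }
    if len(run.schedule.engrams) >= 2:
        out["overlapping_proportion"] = overlapping_proportion(table)
    return out


# ---------------------------------------------------------------------------
# learning

def build_learning_network(config: NetworkConfig, learning_engram: int = 0):
    """Build the learning circuit: all engrams preset at g_M_EE except the
    learning engram, whose intra-engram weights start at the non-coding
    baseline g_EE."""
    graph = build_network(config)
    eg_pre = graph.engram_id[graph.pre]
    eg_post = graph.engram_id[graph.post]
    mask = (eg_pre == learning_engram) & (eg_post == learning_engram)
    graph.weight[mask] = config.g_EE
    return graph


def run_learning(
    graph: SynapticGraph,
    *,
    learning_engram: int = 0,
    learn_duration_s: float = 100.0,
    f_learn: float = 12.5,
    warmup_s: float = 5.0,
    recall_schedule: CueSchedule | None = None,
    seed: int = 1,
    sim: SimParams | None = None,
) -> tuple[SimulationResult, CueSchedule | None]:
    """Learning-then-recall protocol.

    After a warmup with background drive, Poisson learning input at
    ``f_learn`` is applied to the learning engram for ``learn_duration_s``
    with the long-term rule active on every E->E synapse; weights are then
    frozen and, if a recall schedule is given, all engrams are cued
    sequentially.  Mean intra-engram weights are recorded each second.
    """
    cfg = graph.config
    n = graph.n_neurons
    base = np.full(n, external_event_rate(cfg.f_background, cfg.n_ext_trains))
    learn_rates = base.copy()
    learn_rates[graph.engram_members(learning_engram)] = external_event_rate(
        cfg.f_background + f_learn, cfg.n_ext_trains
    )
    segments = [(warmup_s, base), (warmup_s + learn_duration_s, learn_rates)]
    total = warmup_s + learn_duration_s

    schedule = None
    if recall_schedule is not None:
        schedule = replace(recall_schedule, warmup_s=total)
        for pos, eng in enumerate(schedule.engrams):
            onset, offset = schedule.cue_window_s(pos)
            if onset > total:
                segments.append((onset, base))
            cued = base.copy()
            cued[graph.engram_members(eng)] = external_event_rate(
                schedule.f_background + schedule.f_cue, cfg.n_ext_trains
            )
            segments.append((offset, cued))
            segments.append((offset + schedule.gap_s, base))
            total = offset + schedule.gap_s

    result = simulate_network(
        graph,
        total,
        ext_rate_segments=segments,
        plasticity_window_s=(warmup_s, warmup_s + learn_duration_s),
        ext_seed=seed,
        sim=sim,
        weight_groups=True,
    )
    return result, schedule


# ---------------------------------------------------------------------------
# bifurcation ramp

@dataclass
class BifurcationResult:
    """Staircase-ramp hysteresis analysis of a single engram M1.

    ``f_M1`` and ``rate`` tabulate the ramp: the cue-input rate applied to
    M1 in each 1 s block and M1's population mean firing rate in that block.
    Switch points are the first blocks crossing 5 spikes/s on each branch;
    S_p = f_background - descending switch (persistent-state stability) and
    S_l = ascending switch - f_background (low-activity-state stability),
    None when the respective crossing does not occur.
    """

    f_M1: np.ndarray
    rate: np.ndarray
    ascending: np.ndarray  # mask: block belongs to the ascending branch
    f_background: float
    ascending_switch: float | None
    descending_switch: float | None
    s_p: float | None
    s_l: float | None
    bistable: bool


def _ramp_values(f_background: float, df: float = 0.2, span: float = 2.0):
    n_up = int(round(span / df))
    up = f_background + df * np.arange(0, n_up + 1)  # fb .. fb+2
    down = f_background + df * np.arange(n_up - 1, -n_up - 1, -1)  # fb+1.8 .. fb-2
    return np.concatenate([up, down]), np.concatenate(
        [np.ones(up.size, bool), np.zeros(down.size, bool)]
    )


def switch_points_from_ramp(
    f_values: np.ndarray,
    rates: np.ndarray,
    ascending: np.ndarray,
    threshold: float = 5.0,
) -> tuple[float | None, float | None]:
    """Locate the hysteresis switch points on a staircase ramp table.

    Ascending switch: f_M1 of the first ascending-branch block whose rate
    exceeds ``threshold``.  Descending switch: f_M1 of the first
    descending-branch block whose rate falls to or below ``threshold``
    (requires the persistent state to be occupied when the branch starts).
    Missing crossings are returned as None, never as 0.
    """
    f_values = np.asarray(f_values, float)
    rates = np.asarray(rates, float)
    ascending = np.asarray(ascending, bool)

    asc_idx = np.flatnonzero(ascending)
    asc_switch = None
    for i in asc_idx:
        if rates[i] > threshold:
            asc_switch = float(f_values[i])
            break

    desc_idx = np.flatnonzero(~ascending)
    desc_switch = None
    if desc_idx.size:
        # the descending branch only defines a switch if it starts in the
        # persistent state
        started_high = desc_idx[0] > 0 and rates[desc_idx[0] - 1] > threshold
        if started_high or (rates[desc_idx[0]] > threshold):
            for i in desc_idx:
                if rates[i] <= threshold:
                    desc_switch = float(f_values[i])
                    break
    return asc_switch, desc_switch


def run_bifurcation(
    graph: SynapticGraph,
    f_background: float = 2.5,
    rescue: RescueSpec | None = None,
    seed: int = 1,
    *,
    block_s: float = 1.0,
    df: float = 0.2,
    span: float = 2.0,
    warmup_s: float = 2.0,
    sim: SimParams | None = None,
    literal_s_l: bool = False,
) -> BifurcationResult:
    """Hysteresis ramp on a one-engram circuit.

    The engram M1 receives cue input f_M1 stepping +``df`` Hz per block up
    to f_background + ``span``, then -``df`` per block down to
    f_background - ``span``; all other neurons receive background drive.
    M1's population rate per block gives the hysteresis table.
    ``literal_s_l`` reports S_l as the raw ascending switch point instead of
    its distance from f_background.
    """
    if graph.n_engrams != 1:
        raise ValueError("bifurcation analysis requires exactly one engram")
    cfg = graph.config
    members = graph.engram_members(0)
    n = graph.n_neurons
    f_vals, ascending = _ramp_values(f_background, df, span)

    base = np.full(n, external_event_rate(f_background, cfg.n_ext_trains))
    segments = [(warmup_s, base)]
    t = warmup_s
    for f in f_vals:
        r = base.copy()
        r[members] = external_event_rate(max(f, 0.0), cfg.n_ext_trains)
        t += block_s
        segments.append((t, r))

    if rescue is not None:
        rescue = replace(rescue, start_s=min(rescue.start_s, warmup_s))
    result = simulate_network(
        graph,
        t,
        ext_rate_segments=segments,
        rescue=rescue,
        rescue_seed=seed + 7919,
        ext_seed=seed,
        sim=sim,
    )

    rates = np.empty(f_vals.size)
    for k in range(f_vals.size):
        t0 = (warmup_s + k * block_s) * 1000.0
        rates[k] = population_rate(result.raster, members, t0, t0 + block_s * 1000.0)

    asc_switch, desc_switch = switch_points_from_ramp(f_vals, rates, ascending)
    s_p = None if desc_switch is None else f_background - desc_switch
    if asc_switch is None:
        s_l = None
    else:
        s_l = asc_switch if literal_s_l else asc_switch - f_background
    bistable = (
        asc_switch is not None
        and desc_switch is not None
        and asc_switch >= desc_switch
    )
    return BifurcationResult(
        f_M1=f_vals,
        rate=rates,
        ascending=ascending,
        f_background=f_background,
        ascending_switch=asc_switch,
        descending_switch=desc_switch,
        s_p=s_p,
        s_l=s_l,
        bistable=bistable,
    )


# ---------------------------------------------------------------------------
# desk-scale preset

def scaled_config(
    nE: int = 600,
    nI: int = 120,
    C: float = 0.25,
    n_engrams: int = 1,
    engram_size: int = 100,
    seed: int = 0,
    **overrides,
) -> NetworkConfig:
    """Desk-scale circuit (600 E / 120 I) recalibrated to a bistable point.

    The synaptic weights are recalibrated so that, at C = 0.25 and the
    standard 2.5 Hz background, a single engram shows the subcritical
    hysteresis of the full-scale model: a stable low-activity state, cue
    ignition, a persistent state surviving cue offset, and both bifurcation
    switch points inside the +-2 Hz staircase ramp.  The operating regime is
    tonic-inhibition dominated: the inhibitory population fires at a few Hz
    from its own external drive, so the stability of the low-activity state
    scales with the number of inhibitory afferents (hence with C) while the
    stability of the persistent state scales with the intra-engram
    recurrence (also with C)."""
    defaults = dict(
        g_IE=0.3,
        g_II=1.0,
        g_EI=0.25,
        g_M_EE=0.25,
        g_EE=0.02,
        g_O_E=0.016,
        g_O_I=0.05,
    )
    defaults.update(overrides)
    return NetworkConfig(
        nE=nE,
        nI=nI,
        C=C,
        n_engrams=n_engrams,
        engram_size=engram_size,
        seed=seed,
        **defaults,
    )
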