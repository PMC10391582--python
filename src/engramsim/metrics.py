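"""Spike-train and persistent-state statistics.

Persistent states are detected from a 1 s moving window of an engram's
population mean firing rate, evaluated every 1 ms: a persistent state is a
maximal period where the windowed rate exceeds 5 spikes/s per neuron;
sub-second low-rate gaps between two such periods are merged.  The rate of a
window is assigned to the window's left edge, and all intervals are half
open in ms.

The recall-quality metrics built on the detected intervals are the
persistence score (rectified closeness of each engram's persistent-state
total to the ideal duration between consecutive cues, averaged over
engrams) and the overlapping proportion (intersection over union of all
engrams' persistent-state time sets, cue windows excluded), plus standard
firing-property summaries: population rate, proportion of high-firing
neurons, pairwise synchrony index, CV of inter-spike intervals, normalized
firing rate across rescue frequencies, oscillation band power of the mean
membrane potential, and the E/I current ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neuron_dynamics import SpikeRaster

__all__ = [
    "Intervals",
    "PersistentStateTable",
    "BandPowerResult",
    "moving_window_rate",
    "detect_persistent_states",
    "persistence_score",
    "overlapping_proportion",
    "population_rate",
    "high_firing_proportion",
    "synchrony_index",
    "population_synchrony",
    "cv_isi",
    "normalized_firing_rate",
    "oscillation_power",
    "ei_ratio",
]

RATE_THRESHOLD = 5.0  # spikes/s separating low-activity from persistent state


# ---------------------------------------------------------------------------
# interval arithmetic (half-open [start, end) in ms)

class Intervals:
    """Sorted disjoint half-open intervals with measure/set operations."""

    def __init__(self, pairs=()):
        self.pairs = _normalize([(float(a), float(b)) for a, b in pairs])

    def measure(self) -> float:
        return sum(b - a for a, b in self.pairs)

    def union(self, other: "Intervals") -> "Intervals":
        return Intervals(self.pairs + other.pairs)

    def intersection(self, other: "Intervals") -> "Intervals":
        out = []
        for a1, b1 in self.pairs:
            for a2, b2 in other.pairs:
                lo, hi = max(a1, a2), min(b1, b2)
                if lo < hi:
                    out.append((lo, hi))
        return Intervals(out)

    def subtract(self, other: "Intervals") -> "Intervals":
        out = []
        for a, b in self.pairs:
            cur = [(a, b)]
            for a2, b2 in other.pairs:
                nxt = []
                for x, y in cur:
                    if b2 <= x or a2 >= y:
                        nxt.append((x, y))
                    else:
                        if x < a2:
                            nxt.append((x, a2))
                        if b2 < y:
                            nxt.append((b2, y))
                cur = nxt
            out.extend(cur)
        return Intervals(out)

    def shift(self, dt_ms: float) -> "Intervals":
        return Intervals([(a + dt_ms, b + dt_ms) for a, b in self.pairs])

    def merge_gaps(self, max_gap_ms: float) -> "Intervals":
        """Absorb gaps strictly shorter than ``max_gap_ms``."""
        if not self.pairs:
            return Intervals()
        merged = [list(self.pairs[0])]
        for a, b in self.pairs[1:]:
            if a - merged[-1][1] < max_gap_ms:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return Intervals([tuple(p) for p in merged])

    def __eq__(self, other) -> bool:
        return isinstance(other, Intervals) and self.pairs == other.pairs

    def __repr__(self) -> str:
        return f"Intervals({self.pairs})"


def _normalize(pairs):
    pairs = sorted((a, b) for a, b in pairs if b > a)
    out: list[list[float]] = []
    for a, b in pairs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(p) for p in out]


# ---------------------------------------------------------------------------
# persistent-state detection

@dataclass
class PersistentStateTable:
    """Per-engram persistent-state intervals plus the cue schedule context.

    ``intervals[k]`` excludes engram k's own cue windows; ``t_ideal_s`` is
    the ideal persistent duration (cue offset to next cue onset).
    """

    intervals: dict[int, Intervals]
    t_ideal_s: float
    cue_windows_ms: dict[int, Intervals] = field(default_factory=dict)

    def t_persist_s(self, engram: int) -> float:
        return self.intervals[engram].measure() / 1000.0

    @property
    def engrams(self) -> list[int]:
        return sorted(self.intervals)

    def all_cue_windows(self) -> Intervals:
        out = Intervals()
        for iv in self.cue_windows_ms.values():
            out = out.union(iv)
        return out


def moving_window_rate(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    window_ms: float = 1000.0,
    step_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Population mean firing rate (spikes/s per neuron) of the given
    neurons over a sliding window; returns (left-edge times ms, rates)."""
    neuron_ids = np.asarray(neuron_ids)
    if neuron_ids.size == 0:
        raise ValueError("empty neuron set")
    sub = raster.select(neuron_ids)
    n_bins = int(np.ceil(raster.duration_ms / step_ms))
    counts = np.bincount(
        np.minimum((sub.times_ms / step_ms).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    )
    w = int(round(window_ms / step_ms))
    if w > n_bins:
        raise ValueError("window longer than raster span")
    csum = np.concatenate([[0], np.cumsum(counts)])
    windowed = csum[w:] - csum[:-w]
    rate = windowed / (window_ms / 1000.0) / neuron_ids.size
    t = np.arange(rate.size) * step_ms
    return t, rate


def detect_persistent_states(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    *,
    window_ms: float = 1000.0,
    step_ms: float = 1.0,
    threshold: float = RATE_THRESHOLD,
    merge_gap_ms: float = 1000.0,
    cue_windows: Intervals | None = None,
) -> Intervals:
    """Detect one engram's persistent-state intervals.

    Maximal runs of window left-edge times with rate > threshold, sub-second
    gaps merged, own-cue windows subtracted afterwards.
    """
    t, rate = moving_window_rate(raster, neuron_ids, window_ms, step_ms)
    above = rate > threshold
    iv = _runs_to_intervals(t, above, step_ms).merge_gaps(merge_gap_ms)
    if cue_windows is not None:
        iv = iv.subtract(cue_windows)
    return iv


def _runs_to_intervals(t: np.ndarray, mask: np.ndarray, step_ms: float) -> Intervals:
    if not mask.any():
        return Intervals()
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return Intervals([(t[s], t[0] + e * step_ms) for s, e in zip(starts, ends)])


def build_state_table(
    raster: SpikeRaster,
    engram_members: dict[int, np.ndarray],
    schedule,
    **detect_kwargs,
) -> PersistentStateTable:
    """Detect persistent states for every engram of a recall run, attaching
    cue windows from the schedule (engram k's own cue window excluded from
    its interval set)."""
    cue_windows = {}
    for pos, eng in enumerate(schedule.engrams):
        on, off = schedule.cue_window_s(pos)
        cue_windows[eng] = Intervals([(on * 1000.0, off * 1000.0)])
    intervals = {}
    for eng, members in engram_members.items():
        intervals[eng] = detect_persistent_states(
            raster,
            members,
            cue_windows=cue_windows.get(eng),
            **detect_kwargs,
        )
    return PersistentStateTable(
        intervals=intervals,
        t_ideal_s=schedule.t_ideal_s,
        cue_windows_ms=cue_windows,
    )


# ---------------------------------------------------------------------------
# recall-quality metrics

def persistence_score(table: PersistentStateTable) -> float:
    """<ReLU(1 - |T_persist - T_ideal| / T_ideal)> over engrams, in [0, 1]."""
    if table.t_ideal_s <= 0:
        raise ValueError("T_ideal must be positive")
    xs = []
    for eng in table.engrams:
        x = 1.0 - abs(table.t_persist_s(eng) - table.t_ideal_s) / table.t_ideal_s
        xs.append(max(0.0, x))
    return float(np.mean(xs))


def overlapping_proportion(table: PersistentStateTable) -> float:
    """Intersection-over-union of all engrams' persistent-state time sets,
    with every cue window excluded from both; 0 for an empty union."""
    engs = table.engrams
    if len(engs) < 2:
        raise ValueError("overlapping proportion needs >= 2 engrams")
    cues = table.all_cue_windows()
    sets = [table.intervals[e].subtract(cues) for e in engs]
    union = Intervals()
    for s in sets:
        union = union.union(s)
    if union.measure() == 0:
        return 0.0
    inter = sets[0]
    for s in sets[1:]:
        inter = inter.intersection(s)
    return inter.measure() / union.measure()


def population_rate(
    raster: SpikeRaster, neuron_ids: np.ndarray, t0_ms: float, t1_ms: float
) -> float:
    """Spikes per neuron per second within [t0, t1)."""
    if t1_ms <= t0_ms:
        raise ValueError("zero-length window")
    neuron_ids = np.asarray(neuron_ids)
    sub = raster.select(neuron_ids)
    n = np.count_nonzero((sub.times_ms >= t0_ms) & (sub.times_ms < t1_ms))
    return n / ((t1_ms - t0_ms) / 1000.0) / neuron_ids.size


def high_firing_proportion(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    threshold: float = RATE_THRESHOLD,
) -> float:
    """Fraction of the given neurons with individual rate > threshold."""
    if t1_ms <= t0_ms:
        raise ValueError("zero-length window")
    neuron_ids = np.asarray(neuron_ids)
    counts = raster.counts_per_neuron(t0_ms, t1_ms)[neuron_ids]
    rates = counts / ((t1_ms - t0_ms) / 1000.0)
    return float(np.mean(rates > threshold))


def _binarize(times_ms: np.ndarray, t0_ms: float, t1_ms: float, bin_ms: float):
    n_bins = int(round((t1_ms - t0_ms) / bin_ms))
    sel = (times_ms >= t0_ms) & (times_ms < t1_ms)
    idx = ((times_ms[sel] - t0_ms) / bin_ms).astype(np.int64)
    b = np.zeros(n_bins, dtype=np.int8)
    b[np.minimum(idx, n_bins - 1)] = 1
    return b


def synchrony_index(
    times_i: np.ndarray,
    times_j: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    bin_ms: float = 1.0,
    *,
    sqrt_norm: bool = True,
) -> float:
    """Pairwise coincident-firing index on 1 ms binary bins:
    sum(B_i B_j) / sqrt(sum B_i * sum B_j); identical trains score 1.

    ``sqrt_norm=False`` uses the unrooted denominator sum(B_i)*sum(B_j).
    Returns NaN when either train has no spikes in the window.
    """
    bi = _binarize(np.asarray(times_i, float), t0_ms, t1_ms, bin_ms)
    bj = _binarize(np.asarray(times_j, float), t0_ms, t1_ms, bin_ms)
    si, sj = int(bi.sum()), int(bj.sum())
    if si == 0 or sj == 0:
        return float("nan")
    num = float(np.dot(bi.astype(float), bj.astype(float)))
    den = float(np.sqrt(si * sj)) if sqrt_norm else float(si * sj)
    return num / den


def population_synchrony(
    raster: SpikeRaster,
    neuron_ids: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    bin_ms: float = 1.0,
    max_pairs: int = 2000,
    seed: int = 0,
) -> float:
    """Mean pairwise synchrony index over within-group pairs (sampled up to
    ``max_pairs``); pairs with a silent member are excluded."""
    neuron_ids = np.asarray(neuron_ids)
    rng = np.random.default_rng(seed)
    n = neuron_ids.size
    all_pairs = n * (n - 1) // 2
    if all_pairs <= max_pairs:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pairs = set()
        while len(pairs) < max_pairs:
            i, j = rng.integers(0, n, 2)
            if i != j:
                pairs.add((min(i, j), max(i, j)))
        pairs = sorted(pairs)
    bins = {}
    vals = []
    for i, j in pairs:
        for k in (i, j):
            if k not in bins:
                bins[k] = _binarize(
                    raster.spike_times_of(neuron_ids[k]), t0_ms, t1_ms, bin_ms
                )
        bi, bj = bins[i], bins[j]
        si, sj = int(bi.sum()), int(bj.sum())
        if si == 0 or sj == 0:
            continue
        vals.append(float(np.dot(bi.astype(float), bj.astype(float))) / np.sqrt(si * sj))
    return float(np.mean(vals)) if vals else float("nan")


def cv_isi(times_ms: np.ndarray) -> float:
    """Coefficient of variation of inter-spike intervals: std/mean.  1 for
    Poisson firing, > 1 for bursting.  Requires >= 3 spikes."""
    times_ms = np.sort(np.asarray(times_ms, dtype=float))
    if times_ms.size < 3:
        raise ValueError("cv_isi needs at least 3 spikes")
    isi = np.diff(times_ms)
    return float(np.std(isi) / np.mean(isi))


def normalized_firing_rate(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize firing rates across rescue frequencies.

    ``table``: rows indexed by tau_d^GABA, columns = rescue frequencies.
    Each row is divided by its mean, so every output row averages to 1.
    """
    means = table.mean(axis=1)
    if (means == 0).any():
        raise ValueError("row with zero mean firing rate")
    return table.div(means, axis=0)


# ---------------------------------------------------------------------------
# oscillation power and E/I ratio

@dataclass
class BandPowerResult:
    """Normalized power spectrum of the mean-detrended average E membrane
    potential and band averages (theta 4-12 Hz, slow-gamma 30-60 Hz,
    fast-gamma 60-120 Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray  # normalized so that mean(power) == 1
    theta: float
    slow_gamma: float
    fast_gamma: float
    window_short: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs_hz, "power": self.power})


BANDS = {"theta": (4.0, 12.0), "slow_gamma": (30.0, 60.0), "fast_gamma": (60.0, 120.0)}


def oscillation_power(
    v_trace: np.ndarray,
    fs_hz: float = 1000.0,
    expected_window_s: float = 10.0,
) -> BandPowerResult:
    """FFT band power of a mean-detrended voltage trace.

    The power spectrum (squared rFFT magnitude, DC excluded) is divided by
    its own mean; band values are the mean normalized power over the band's
    frequency range.  A window shorter than ``expected_window_s`` is
    computed anyway but flagged.
    """
    v = np.asarray(v_trace, dtype=float)
    if v.size < 2:
        raise ValueError("trace too short")
    short = v.size / fs_hz < expected_window_s
    x = v - v.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(v.size, d=1.0 / fs_hz)
    spec, freqs = spec[1:], freqs[1:]  # drop DC
    m = spec.mean()
    power = spec / m if m > 0 else spec
    bands = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs <= hi)
        bands[name] = float(power[sel].mean()) if sel.any() else 0.0
    return BandPowerResult(
        freqs_hz=freqs,
        power=power,
        theta=bands["theta"],
        slow_gamma=bands["slow_gamma"],
        fast_gamma=bands["fast_gamma"],
        window_short=short,
    )


def ei_ratio(
    i_exc: np.ndarray, i_inh: np.ndarray, eps: float = 1e-12
) -> tuple[float, np.ndarray]:
    """E/I current ratio |G_E (E_E - V)| / |G_I (E_I - V)| from recorded
    current traces.  Returns (time-mean over defined samples, per-sample
    trace with NaN where the inhibitory current vanishes)."""
    exc = np.abs(np.asarray(i_exc, dtype=float))
    inh = np.abs(np.asarray(i_inh, dtype=float))
    ratio = np.where(inh > eps, exc / np.maximum(inh, eps), np.nan)
    if np.all(np.isnan(ratio)):
        return float("nan"), ratio
    return float(np.nanmean(ratio)), ratio
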