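import numpy as np
import pandas as pd
import pytest

from engramsim.config import CueSchedule
from engramsim.io_cli import generate_fixture_raster
from engramsim.metrics import (
    Intervals,
    PersistentStateTable,
    build_state_table,
    cv_isi,
    detect_persistent_states,
    ei_ratio,
    high_firing_proportion,
    normalized_firing_rate,
    oscillation_power,
    overlapping_proportion,
    persistence_score,
    population_rate,
    population_synchrony,
    synchrony_index,
)
from engramsim.neuron_dynamics import SpikeRaster


def make_table(durations_s, t_ideal_s=10.0):
    iv = {
        k: Intervals([(0.0, d * 1000.0)]) if d > 0 else Intervals()
        for k, d in enumerate(durations_s)
    }
    return PersistentStateTable(intervals=iv, t_ideal_s=t_ideal_s)


class TestIntervals:
    def test_measure_and_union(self):
        a = Intervals([(0, 10), (20, 30)])
        b = Intervals([(5, 25)])
        assert a.measure() == 20
        assert a.union(b).measure() == 30
        assert a.intersection(b).measure() == 10

    def test_subtract(self):
        a = Intervals([(0, 100)])
        out = a.subtract(Intervals([(10, 20), (50, 60)]))
        assert out.pairs == [(0.0, 10.0), (20.0, 50.0), (60.0, 100.0)]

    def test_merge_gaps_below_threshold(self):
        a = Intervals([(0, 4000), (4500, 8500)])
        assert a.merge_gaps(1000.0).pairs == [(0.0, 8500.0)]
        wide = Intervals([(0, 4000), (5500, 8500)])
        assert wide.merge_gaps(1000.0).pairs == [(0.0, 4000.0), (5500.0, 8500.0)]


class TestPersistenceScore:
    def test_exact_ideal_duration_scores_one(self):
        assert persistence_score(make_table([10.0, 10.0, 10.0])) == 1.0

    def test_zero_duration_contributes_zero(self):
        assert persistence_score(make_table([0.0])) == 0.0

    def test_double_ideal_rectified_to_zero(self):
        assert persistence_score(make_table([20.0])) == 0.0

    def test_mixed_mean(self):
        # x = [1, 0.5, 0] -> mean 0.5
        assert persistence_score(make_table([10.0, 5.0, 0.0])) == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            t = make_table(rng.uniform(0, 40, 5))
            assert 0.0 <= persistence_score(t) <= 1.0

    def test_invalid_ideal_rejected(self):
        with pytest.raises(ValueError):
            persistence_score(make_table([5.0], t_ideal_s=0.0))


class TestOverlappingProportion:
    def test_identical_sets_give_one(self):
        iv = {0: Intervals([(0, 5000)]), 1: Intervals([(0, 5000)])}
        t = PersistentStateTable(iv, 10.0)
        assert overlapping_proportion(t) == 1.0

    def test_disjoint_sets_give_zero(self):
        iv = {0: Intervals([(0, 5000)]), 1: Intervals([(6000, 9000)])}
        t = PersistentStateTable(iv, 10.0)
        assert overlapping_proportion(t) == 0.0

    def test_partial_overlap_interval_arithmetic(self):
        iv = {0: Intervals([(0, 10_000)]), 1: Intervals([(5000, 10_000)])}
        t = PersistentStateTable(iv, 10.0)
        assert overlapping_proportion(t) == pytest.approx(0.5)

    def test_empty_union_gives_zero(self):
        t = PersistentStateTable({0: Intervals(), 1: Intervals()}, 10.0)
        assert overlapping_proportion(t) == 0.0

    def test_cue_windows_excluded_from_both_sets(self):
        iv = {0: Intervals([(0, 10_000)]), 1: Intervals([(0, 10_000)])}
        cues = {0: Intervals([(0, 5000)])}
        t = PersistentStateTable(iv, 10.0, cue_windows_ms=cues)
        # both reduce to [5000, 10000): still identical
        assert overlapping_proportion(t) == 1.0

    def test_bounded_over_random_configurations(self, rng):
        """IoU of random interval configurations never exceeds 1."""
        for _ in range(1000):
            iv = {}
            for k in range(3):
                starts = np.sort(rng.uniform(0, 50_000, 3))
                iv[k] = Intervals(
                    [(s, s + rng.uniform(0, 5000)) for s in starts]
                )
            t = PersistentStateTable(iv, 10.0)
            v = overlapping_proportion(t)
            assert 0.0 <= v <= 1.0


class TestDetection:
    def test_silent_raster_has_no_states(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 10, 30_000.0)
        iv = detect_persistent_states(r, np.arange(10))
        assert iv.pairs == []

    def test_block_of_elevated_firing_detected(self, rng):
        """20 Hz firing over [10 s, 20 s) detects one interval within one
        window length of the true boundaries."""
        members = {0: np.arange(20)}
        r = generate_fixture_raster(
            {0: [(10_000.0, 20_000.0)]}, members, 30_000.0, 20,
            baseline_rate=0.5, elevated_rate=20.0, seed=4,
        )
        iv = detect_persistent_states(r, members[0])
        assert len(iv.pairs) == 1
        a, b = iv.pairs[0]
        assert abs(a - 10_000.0) <= 1000.0
        assert abs(b - 20_000.0) <= 1000.0

    def test_short_gap_merged(self):
        """Two elevated blocks separated by a 0.5 s silent gap count as one
        persistent state."""
        members = {0: np.arange(20)}
        r = generate_fixture_raster(
            {0: [(5000.0, 9000.0), (9500.0, 13_500.0)]}, members, 20_000.0, 20,
            baseline_rate=0.0, elevated_rate=20.0, seed=4,
        )
        iv = detect_persistent_states(r, members[0])
        assert len(iv.pairs) == 1

    def test_translation_invariance(self, rng):
        members = {0: np.arange(15)}
        shift = 3000.0
        r1 = generate_fixture_raster(
            {0: [(5000.0, 11_000.0)]}, members, 25_000.0, 15,
            baseline_rate=0.0, elevated_rate=25.0, seed=9,
        )
        r2 = SpikeRaster(
            r1.times_ms + shift, r1.ids.copy(), 15, 25_000.0 + shift
        )
        iv1 = detect_persistent_states(r1, members[0])
        iv2 = detect_persistent_states(r2, members[0])
        assert np.allclose(
            np.asarray(iv2.pairs) - shift, np.asarray(iv1.pairs), atol=1e-9
        )

    def test_empty_engram_rejected(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 10, 5000.0)
        with pytest.raises(ValueError):
            detect_persistent_states(r, np.array([], dtype=int))


class TestFixtureRoundTrip:
    def test_prescribed_intervals_recover_score_and_overlap(self):
        """A fixture raster with T_persist = T_ideal for both engrams yields
        a persistence score near 1 and overlap near 1 for identical
        intervals."""
        schedule = CueSchedule(engrams=[0, 1], warmup_s=5.0)
        members = {0: np.arange(0, 30), 1: np.arange(30, 60)}
        # engram k active from its cue offset for exactly T_ideal = 10 s
        intervals = {
            0: [(10_000.0, 20_000.0)],
            1: [(25_000.0, 35_000.0)],
        }
        r = generate_fixture_raster(
            intervals, members, schedule.total_s * 1000.0, 60,
            baseline_rate=0.5, elevated_rate=25.0, seed=11,
        )
        table = build_state_table(r, members, schedule)
        assert persistence_score(table) == pytest.approx(1.0, abs=0.1)
        assert overlapping_proportion(table) == pytest.approx(0.0, abs=0.05)

    def test_identical_intervals_full_overlap(self):
        schedule = CueSchedule(engrams=[0, 1], warmup_s=5.0)
        members = {0: np.arange(0, 30), 1: np.arange(30, 60)}
        intervals = {
            0: [(10_000.0, 20_000.0)],
            1: [(10_000.0, 20_000.0)],
        }
        r = generate_fixture_raster(
            intervals, members, schedule.total_s * 1000.0, 60,
            baseline_rate=0.0, elevated_rate=25.0, seed=11,
        )
        table = build_state_table(r, members, schedule)
        assert overlapping_proportion(table) == pytest.approx(1.0, abs=0.1)


class TestFiringProperties:
    def test_population_rate_arithmetic(self):
        # 200 neurons, 10 s, 4000 spikes -> 2 per second per neuron
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 10_000, 4000)
        ids = rng.integers(0, 200, 4000)
        r = SpikeRaster(times, ids, 200, 10_000.0)
        assert population_rate(r, np.arange(200), 0.0, 10_000.0) == pytest.approx(2.0)

    def test_silent_engram_zero(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 50, 10_000.0)
        assert population_rate(r, np.arange(50), 0.0, 10_000.0) == 0.0
        assert high_firing_proportion(r, np.arange(50), 0.0, 10_000.0) == 0.0

    def test_uniform_rate_above_threshold(self):
        # every neuron at 6 Hz over 10 s -> proportion 1
        n = 30
        times = np.concatenate([np.arange(60) / 60 * 10_000 for _ in range(n)])
        ids = np.repeat(np.arange(n), 60)
        r = SpikeRaster(times, ids, n, 10_000.0)
        assert high_firing_proportion(r, np.arange(n), 0.0, 10_000.0) == 1.0

    def test_zero_length_window_rejected(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 5, 1000.0)
        with pytest.raises(ValueError):
            population_rate(r, np.arange(5), 500.0, 500.0)


class TestSynchronyIndex:
    def test_identical_trains_score_one(self):
        t = np.array([10.0, 55.0, 230.0, 400.0])
        assert synchrony_index(t, t, 0.0, 1000.0) == pytest.approx(1.0)

    def test_no_coincidence_scores_zero(self):
        a = np.array([10.0, 110.0])
        b = np.array([60.0, 160.0])
        assert synchrony_index(a, b, 0.0, 1000.0) == 0.0

    def test_independent_poisson_expectation(self, rng):
        """Independent Poisson trains at 10 Hz over 100 s:
        K ~ sqrt(p_i p_j) with p = 0.01 per 1 ms bin."""
        T = 100_000.0
        vals = []
        for _ in range(20):
            a = rng.uniform(0, T, 1000)
            b = rng.uniform(0, T, 1000)
            vals.append(synchrony_index(a, b, 0.0, T))
        assert np.mean(vals) == pytest.approx(0.01, abs=0.003)

    def test_silent_train_is_nan(self):
        v = synchrony_index(np.array([]), np.array([5.0]), 0.0, 100.0)
        assert np.isnan(v)

    def test_population_mean_excludes_silent(self, rng):
        times = rng.uniform(0, 10_000, 300)
        ids = rng.integers(0, 5, 300)  # neurons 5..9 silent
        r = SpikeRaster(times, ids, 10, 10_000.0)
        v = population_synchrony(r, np.arange(10), 0.0, 10_000.0)
        assert np.isfinite(v)


class TestCVISI:
    def test_periodic_train_is_zero(self):
        assert cv_isi(np.arange(0, 1000, 10.0)) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_near_one(self, rng):
        isi = rng.exponential(100.0, 100_000)
        assert cv_isi(np.cumsum(isi)) == pytest.approx(1.0, abs=0.02)

    def test_burst_doublet_closed_form(self):
        """Doublets 2 ms apart repeated every 1 s: the ISI distribution is a
        two-point mixture {2, 998} with equal weights."""
        starts = np.arange(0, 100_000, 1000.0)
        train = np.sort(np.concatenate([starts, starts + 2.0]))
        isi = np.diff(train)
        mean = isi.mean()
        std = isi.std()
        assert cv_isi(train) == pytest.approx(std / mean)
        # analytic two-point mixture (equal counts up to the boundary ISI)
        vals = np.array([2.0, 998.0])
        m = vals.mean()
        s = np.sqrt(((vals - m) ** 2).mean())
        assert cv_isi(train) == pytest.approx(s / m, rel=0.02)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            cv_isi(np.array([1.0, 2.0]))


class TestNormalizedFiringRate:
    def test_constant_row_maps_to_ones(self):
        t = pd.DataFrame({10: [2.0], 40: [2.0], 100: [2.0]}, index=[5.0])
        out = normalized_firing_rate(t)
        assert np.allclose(out.to_numpy(), 1.0)

    def test_two_entry_row(self):
        t = pd.DataFrame({10: [2.0], 40: [4.0]}, index=[5.0])
        out = normalized_firing_rate(t)
        assert np.allclose(out.to_numpy(), [[2 / 3, 4 / 3]])

    def test_row_means_are_one(self, rng):
        t = pd.DataFrame(rng.uniform(1, 5, (4, 6)))
        out = normalized_firing_rate(t)
        assert np.allclose(out.mean(axis=1), 1.0)

    def test_zero_mean_row_rejected(self):
        t = pd.DataFrame({10: [0.0], 40: [0.0]})
        with pytest.raises(ValueError):
            normalized_firing_rate(t)


class TestOscillationPower:
    def test_pure_40hz_dominates_slow_gamma(self, rng):
        fs = 1000.0
        t = np.arange(10_000) / fs
        v = np.sin(2 * np.pi * 40.0 * t) + 0.01 * rng.standard_normal(t.size)
        res = oscillation_power(v, fs)
        assert res.slow_gamma > 10 * res.theta
        assert res.slow_gamma > 10 * res.fast_gamma
        peak = res.freqs_hz[np.argmax(res.power)]
        assert peak == pytest.approx(40.0, abs=0.2)

    def test_white_noise_flat_bands(self, rng):
        v = rng.standard_normal(200_000)
        res = oscillation_power(v, 1000.0)
        for band in (res.theta, res.slow_gamma, res.fast_gamma):
            assert band == pytest.approx(1.0, abs=0.15)

    def test_constant_trace_zero_power(self):
        res = oscillation_power(np.full(10_000, -65.0), 1000.0)
        assert np.all(res.power == 0.0)

    def test_short_window_flagged(self):
        res = oscillation_power(np.random.default_rng(0).normal(size=2000), 1000.0)
        assert res.window_short

    def test_spectrum_mean_normalized(self, rng):
        res = oscillation_power(rng.standard_normal(50_000), 1000.0)
        assert res.power.mean() == pytest.approx(1.0)


class TestEIRatio:
    def test_zero_inhibition_flagged(self):
        mean, trace = ei_ratio(np.ones(10), np.zeros(10))
        assert np.isnan(mean)
        assert np.all(np.isnan(trace))

    def test_balanced_currents_give_one(self):
        mean, _ = ei_ratio(np.full(5, 2.0), np.full(5, -2.0))
        assert mean == pytest.approx(1.0)

    def test_scripted_traces_match_hand_computation(self):
        exc = np.array([1.0, 2.0, 3.0])
        inh = np.array([-2.0, -2.0, 0.0])
        mean, trace = ei_ratio(exc, inh)
        assert trace[0] == pytest.approx(0.5)
        assert trace[1] == pytest.approx(1.0)
        assert np.isnan(trace[2])
        assert mean == pytest.approx(0.75)
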