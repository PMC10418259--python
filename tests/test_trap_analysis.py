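"""Downsampling, stall detection and stall statistics."""
import numpy as np
import pytest

from conftest import brute_force_stalls, random_stall_trace
from dynmech.synthetic import MotorModelParams, TrapSimParams, simulate_bead_trace
from dynmech.trace import ForceTrace
from dynmech.trap import (
    StallCriteria,
    StallEvent,
    detect_stalls,
    downsample,
    mutant_criteria,
    stall_force,
    stall_time,
    summarize_stalls,
    wild_type_criteria,
)


def make_trace(force: np.ndarray, fs: float = 250.0) -> ForceTrace:
    return ForceTrace(
        time=np.arange(force.size) / fs,
        position=np.asarray(force, dtype=float),
        force=np.asarray(force, dtype=float),
        sampling_rate=fs,
        trap_stiffness=1.0,
    )


class TestDownsample:
    def test_identity_at_factor_one(self):
        trace = make_trace(np.random.default_rng(0).normal(size=500))
        assert downsample(trace, 250.0) is trace

    def test_5000_to_250_reduces_by_20(self):
        trace = make_trace(np.zeros(100_000), fs=5000.0)
        ds = downsample(trace, 250.0)
        assert ds.n_samples == 5000
        assert ds.sampling_rate == 250.0
        assert ds.metadata["original_sampling_rate_hz"] == 5000.0

    def test_linear_ramp_block_means_are_block_midpoints(self):
        fs = 1000.0
        n = 1000
        force = np.arange(n) / fs  # affine in time
        trace = make_trace(force, fs=fs)
        ds = downsample(trace, 100.0)
        # block mean of an affine signal = value at the block's mid time
        assert np.allclose(ds.force, ds.time)
        assert np.allclose(ds.time, (np.arange(100) * 10 + 4.5) / fs)

    def test_non_integer_factor_rejected(self):
        trace = make_trace(np.zeros(100), fs=250.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(trace, 99.0)


class TestDetectStalls:
    def test_below_threshold_gives_no_events(self):
        rng = np.random.default_rng(2)
        trace = make_trace(np.clip(rng.normal(1.0, 0.2, 2000), 0, 2.4))
        assert detect_stalls(trace, wild_type_criteria()) == []

    def test_empty_trace(self):
        trace = make_trace(np.empty(0))
        assert detect_stalls(trace, wild_type_criteria()) == []

    def test_ramp_hold_drop_yields_one_event_covering_hold(self):
        fs = 250.0
        ramp = np.linspace(0.0, 4.0, int(fs))  # 1 s ramp
        hold = np.full(int(0.5 * fs), 4.0)  # 0.5 s plateau
        tail = np.zeros(int(0.5 * fs))
        trace = make_trace(np.concatenate([ramp, hold, tail]), fs=fs)
        events = detect_stalls(trace, wild_type_criteria())
        assert len(events) == 1
        event = events[0]
        assert event.start <= 1.0 and event.end >= 1.5 - 2 / fs
        assert event.detached
        assert event.stall_force == pytest.approx(4.0, abs=1e-6)

    def test_mutant_criteria_admit_low_force_pause(self):
        fs = 250.0
        force = np.zeros(int(2 * fs))
        plateau = slice(int(0.5 * fs), int(0.5 * fs) + 51)  # 200 ms at 1.2 pN
        force[plateau] = 1.2
        trace = make_trace(force, fs=fs)
        assert detect_stalls(trace, wild_type_criteria()) == []
        events = detect_stalls(trace, mutant_criteria())
        assert len(events) == 1
        assert events[0].stall_force == pytest.approx(1.2)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(3)
        criteria = wild_type_criteria()
        for _ in range(10):
            trace = random_stall_trace(rng, n=10_000)
            got = detect_stalls(trace, criteria)
            expected = brute_force_stalls(trace, criteria)
            got_idx = [
                (int(round(e.start * 250)), int(round(e.end * 250)), e.detached)
                for e in got
            ]
            assert got_idx == expected

    def test_monotone_in_min_duration(self):
        # a longer minimum duration can only remove events: the candidate
        # runs are fixed, the duration filter just prunes them.  (The
        # analogous statement for min_force is not a theorem of the rule:
        # a higher threshold can split one run into two qualifying
        # fragments.)
        rng = np.random.default_rng(4)
        for _ in range(10):
            trace = random_stall_trace(rng, n=8_000)
            counts_by_duration = [
                len(detect_stalls(trace, StallCriteria(min_force=2.5, min_duration=d)))
                for d in (0.05, 0.1, 0.3)
            ]
            assert counts_by_duration == sorted(counts_by_duration, reverse=True)

    def test_stall_force_within_event_force_range(self):
        rng = np.random.default_rng(5)
        trace = random_stall_trace(rng, n=10_000)
        for e in detect_stalls(trace, wild_type_criteria()):
            i0 = int(round(e.start * 250))
            i1 = int(round(e.end * 250))
            seg = trace.force[i0 : i1 + 1]
            assert seg.min() - 1e-12 <= e.stall_force <= seg.max() + 1e-12


class TestStallForceAndTime:
    def test_constant_plateau(self):
        trace = make_trace(np.full(251, 4.0))
        event = StallEvent(start=0.0, end=1.0, stall_force=0.0, stall_time=0.0, detached=True)
        assert stall_force(trace, event) == pytest.approx(4.0)

    def test_affine_plateau_last_fifth_mean(self):
        fs = 250.0
        force = 3.0 + np.arange(251) / 250.0  # 3 -> 4 pN over 1 s
        trace = make_trace(force, fs=fs)
        event = StallEvent(start=0.0, end=1.0, stall_force=0.0, stall_time=0.0, detached=True)
        assert stall_force(trace, event) == pytest.approx(3.9)

    def test_window_is_final_fifth_inclusive_of_end(self):
        fs = 250.0
        force = np.zeros(251)
        force[200:] = 5.0  # exactly the last 20% of [0, 1]
        trace = make_trace(force, fs=fs)
        event = StallEvent(start=0.0, end=1.0, stall_force=0.0, stall_time=0.0, detached=True)
        assert stall_force(trace, event) == pytest.approx(5.0)

    def test_too_few_samples_error(self):
        trace = make_trace(np.full(3, 4.0))
        event = StallEvent(start=0.0, end=2 / 250, stall_force=0.0, stall_time=0.0, detached=True)
        with pytest.raises(ValueError, match="fewer than 2"):
            stall_force(trace, event)

    def test_rectangular_plateau_stall_time(self):
        fs = 250.0
        force = np.full(300, 4.0)
        trace = make_trace(force, fs=fs)
        event = StallEvent(start=0.0, end=0.5, stall_force=4.0, stall_time=0.0, detached=True)
        assert stall_time(trace, event) == pytest.approx(0.5)

    def test_excursion_below_80pct_subtracted(self):
        fs = 250.0
        force = np.full(200, 4.0)
        force[25:50] = 3.0  # 0.1 s below 0.8 * 4.0 = 3.2 pN
        trace = make_trace(force, fs=fs)
        event = StallEvent(start=0.0, end=0.6, stall_force=0.0, stall_time=0.0, detached=True)
        sf = stall_force(trace, event)
        assert sf == pytest.approx(4.0)
        event.stall_force = sf
        assert stall_time(trace, event) == pytest.approx(0.5)

    def test_threshold_uses_event_stall_force_not_min_force(self):
        # 2 pN plateau: 80% of stall force = 1.6 pN, well below the 2.5 pN
        # wild-type min_force; every sample still qualifies
        fs = 250.0
        trace = make_trace(np.full(200, 2.0), fs=fs)
        event = StallEvent(start=0.0, end=0.6, stall_force=2.0, stall_time=0.0, detached=True)
        assert stall_time(trace, event) == pytest.approx(0.6)


class TestSummarize:
    def test_single_event_has_nan_sem(self):
        event = StallEvent(start=0, end=1, stall_force=4.0, stall_time=0.5, detached=True)
        summary = summarize_stalls([event])
        assert summary.mean_stall_force == 4.0
        assert np.isnan(summary.sem)
        assert summary.n == 1

    def test_simulated_stalls_recover_detachment_force(self):
        events = []
        for seed in range(6):
            trace, _ = simulate_bead_trace(
                TrapSimParams(duration=10.0, seed=100 + seed),
                MotorModelParams(detachment_force_mean=4.0, detachment_force_sd=0.5),
            )
            events.extend(detect_stalls(downsample(trace), wild_type_criteria()))
        assert len(events) >= 20
        summary = summarize_stalls(events)
        assert summary.mean_stall_force == pytest.approx(4.0, abs=0.2)
        assert summary.sem > 0
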