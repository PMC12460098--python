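"""Schedule generation and the agent-based school simulator."""

import numpy as np
import pytest

from pensonar import (
    SchoolParams,
    make_invalid_frames,
    make_schedule,
    school_radius,
    simulate_frames,
)
from pensonar.segmentation import _sample_polar
from pensonar.cfp import accumulate_cfp


@pytest.fixture
def short_schedule():
    return make_schedule(["s"], 1, duration=60, break_duration=60, order="sequential", start=120)


class TestMakeSchedule:
    def test_protocol_layout(self):
        # 5 tones x 3 repetitions, 60 s each, 10 min breaks
        sched = make_schedule(list("abcde"), 3, duration=60, break_duration=600, seed=0)
        assert len(sched.events) == 15
        levels = [e.level for e in sched.events]
        assert all(levels.count(l) == 3 for l in "abcde")
        onsets = [e.onset for e in sched.events]
        assert np.allclose(np.diff(onsets), 660.0)

    def test_single_event(self):
        sched = make_schedule(["x"], 1, start=42.0)
        assert len(sched.events) == 1
        assert sched.events[0].onset == 42.0

    def test_seeds_permute_the_same_multiset(self):
        a = make_schedule(list("abc"), 2, seed=1)
        b = make_schedule(list("abc"), 2, seed=2)
        assert sorted(e.level for e in a.events) == sorted(e.level for e in b.events)
        assert [e.onset for e in a.events] == [e.onset for e in b.events]
        assert [e.level for e in a.events] != [e.level for e in b.events]

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            make_schedule([], 3)


class TestSchoolRadius:
    def test_baseline_before_onset(self, short_schedule):
        p = SchoolParams(displacement_factor=0.3)
        assert school_radius(p, 119.0, short_schedule) == pytest.approx(p.baseline_radius)

    def test_null_displacement_is_flat(self, short_schedule):
        p = SchoolParams(displacement_factor=0.0)
        t = np.linspace(0, 240, 200)
        assert np.allclose(school_radius(p, t, short_schedule), p.baseline_radius)

    def test_exponential_approach_saturates(self, short_schedule):
        p = SchoolParams(displacement_factor=0.3, relaxation_tau=1.0)
        r = school_radius(p, 130.0, short_schedule)  # 10 s after onset
        target = p.baseline_radius * 1.3
        assert abs(r - target) / target < 1e-3

    def test_baseline_restored_after_relaxation(self, short_schedule):
        p = SchoolParams(displacement_factor=0.3, relaxation_tau=1.0)
        # beyond onset + duration + 5 tau the baseline holds exactly
        assert school_radius(p, 186.0, short_schedule) == pytest.approx(p.baseline_radius)


class TestSimulateFrames:
    def test_reproducible_bit_identical(self, small_config, short_schedule):
        p = SchoolParams(n_agents=40)
        f1, _ = simulate_frames(p, short_schedule, small_config, seed=5, span=40)
        f2, _ = simulate_frames(p, short_schedule, small_config, seed=5, span=40)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_displacement_raises_ground_truth_radius(self, small_config, short_schedule):
        p = SchoolParams(n_agents=10, displacement_factor=0.4)
        _, gt = simulate_frames(p, short_schedule, small_config, seed=0)
        during = np.array([ph == "during" for ph in gt.phase])
        before = np.array([ph == "before" for ph in gt.phase])
        assert gt.true_radius[during].mean() > gt.true_radius[before].mean()

    def test_empty_pen_has_no_echoes_beyond_structure(self, small_config, short_schedule):
        p = SchoolParams(n_agents=0)
        frames, _ = simulate_frames(p, short_schedule, small_config, seed=0, span=40)
        ranges = small_config.sample_ranges()
        beyond = ranges > small_config.exclusion_radius + 2 * small_config.range_resolution
        for f in frames:
            assert not (f.intensities[:, beyond] > 0.5).any()

    def test_prestimulus_mean_echo_range_matches_model(self, default_config, short_schedule):
        # mean above-threshold echo range ~ r0 + mean of the half-normal spread
        p = SchoolParams()
        frames, _ = simulate_frames(p, short_schedule, default_config, seed=3, span=64)
        ranges = default_config.sample_ranges()
        ok = ranges > default_config.exclusion_radius + 2 * default_config.range_resolution
        vals = []
        for f in frames:
            above = f.intensities > 0.5
            above[:, ~ok] = False
            vals.append(np.broadcast_to(ranges, above.shape)[above])
        observed = np.concatenate(vals).mean()
        expected = p.baseline_radius + p.radial_spread * np.sqrt(2 / np.pi)
        assert abs(observed - expected) / expected < 0.10

    def test_flight_empties_instrumented_volume(self, small_config, short_schedule):
        p = SchoolParams(
            n_agents=40, displacement_factor=8.0, out_of_range_flag=True, radial_spread=0.2
        )
        frames, gt = simulate_frames(p, short_schedule, small_config, seed=0)
        ranges = small_config.sample_ranges()
        ok = ranges > small_config.exclusion_radius + 2 * small_config.range_resolution
        during = [f for f, ph in zip(frames, gt.phase) if ph == "during"]
        # above the echo scale (background tails stay well below it)
        empty = sum(not (f.intensities[:, ok] > 1.0).any() for f in during)
        assert empty / len(during) >= 0.95

    def test_out_of_range_without_flag_rejected(self, small_config, short_schedule):
        p = SchoolParams(n_agents=10, displacement_factor=8.0, out_of_range_flag=False)
        with pytest.raises(ValueError):
            simulate_frames(p, short_schedule, small_config, seed=0)

    def test_frame_count_tracks_window_length(self, small_config, short_schedule):
        p = SchoolParams(n_agents=5)
        frames, _ = simulate_frames(p, short_schedule, small_config, seed=0, span=100)
        window = (0.0, 50.0)
        inside = [
            f for f in frames
            if f.t_start >= window[0] and f.t_start + small_config.scan_period <= window[1]
        ]
        expected = int(50.0 // small_config.scan_period)
        assert abs(len(inside) - expected) <= 1


class TestInvalidFrames:
    def test_zero_burst_reduces_to_background_only(self, small_config):
        frames = make_invalid_frames(small_config, burst_level=0.0, n_frames=3, seed=0)
        for f in frames:
            assert not f.intensities.any()

    def test_seeds_differ_in_pattern_not_in_level(self, small_config):
        a = make_invalid_frames(small_config, burst_level=3.0, n_frames=2, seed=1)
        b = make_invalid_frames(small_config, burst_level=3.0, n_frames=2, seed=2)
        assert not np.array_equal(a[0].intensities, b[0].intensities)
        ma, mb = a[0].intensities.mean(), b[0].intensities.mean()
        assert abs(ma - mb) / ma < 0.05
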