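"""Inner-perimeter contour extraction and avoidance-distance estimation."""

import numpy as np
import pytest

from pensonar import SonarConfig, avoidance_distance, inner_contour, measurements_table
from pensonar.errors import NotMeasurableError
from pensonar.segmentation import SegmentationMask


def _mask_from_region(region, config, mpp, category="pattern"):
    side = region.shape[0]
    return SegmentationMask(
        category=category,
        fish_free=region,
        centre=((side - 1) // 2, (side - 1) // 2),
        metres_per_pixel=mpp,
        config=config,
    )


def _disc(side, radius):
    half = (side - 1) // 2
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    return np.hypot(rr - half, cc - half) <= radius


def _brute_force_boundary(region):
    """Independent oracle: fish-free pixels with a non-fish-free 4-neighbour
    (the one-pixel-thick traced contour), by direct neighbourhood scan."""
    side = region.shape[0]
    out = np.zeros_like(region)
    for r in range(side):
        for c in range(side):
            if not region[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < side and 0 <= cc < side) or not region[rr, cc]:
                    out[r, c] = True
    return out


@pytest.fixture
def cfg():
    return SonarConfig()


class TestInnerContour:
    def test_disc_contour_sits_at_radius(self, cfg):
        mask = _mask_from_region(_disc(401, 60), cfg, 0.05)
        contour = inner_contour(mask)
        d = np.hypot(contour[:, 0] - 200, contour[:, 1] - 200)
        assert (np.abs(d - 60) <= 1.0).all()
        # pixel centres sit just inside the circle: about half a pixel low
        assert d.mean() == pytest.approx(60, abs=0.6)

    def test_out_of_range_contour_at_max_range(self, cfg):
        region = _disc(401, cfg.max_range / 0.05)
        mask = _mask_from_region(region, cfg, 0.05, category="out_of_range")
        contour = inner_contour(mask)
        d = np.hypot(contour[:, 0] - 200, contour[:, 1] - 200)
        assert (np.abs(d - cfg.max_range / 0.05) <= 1.0).all()

    def test_star_region_matches_brute_force_neighbour_scan(self, cfg):
        rng = np.random.default_rng(0)
        side = 81
        half = 40
        # random star-shaped region: smooth angular radius profile
        angles = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        prof = 18 + 10 * rng.random(64)
        prof = np.convolve(np.r_[prof, prof[:8]], np.ones(5) / 5, mode="same")[:64]
        rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        theta = np.arctan2(half - rr, cc - half) % (2 * np.pi)
        idx = np.floor(theta / (2 * np.pi / 64)).astype(int)
        region = np.hypot(rr - half, cc - half) < prof[idx]
        mask = _mask_from_region(region, cfg, 0.05)
        contour = inner_contour(mask)
        got = np.zeros_like(region)
        got[contour[:, 0], contour[:, 1]] = True
        np.testing.assert_array_equal(got, _brute_force_boundary(region))

    def test_invalid_not_measurable(self, cfg):
        mask = _mask_from_region(np.zeros((401, 401), bool), cfg, 0.05, category="invalid")
        with pytest.raises(NotMeasurableError):
            inner_contour(mask)


class TestAvoidanceDistance:
    def test_disc_radius_recovered(self, cfg):
        mask = _mask_from_region(_disc(401, 60), cfg, 0.05)
        m = avoidance_distance(mask)
        assert m.distance == pytest.approx(3.0, abs=0.05)
        assert not m.censored

    def test_ellipse_matches_brute_force_contour_mean(self, cfg):
        rr, cc = np.meshgrid(np.arange(401), np.arange(401), indexing="ij")
        region = ((rr - 200) / 40.0) ** 2 + ((cc - 200) / 60.0) ** 2 <= 1.0
        mask = _mask_from_region(region, cfg, 0.05)
        m = avoidance_distance(mask)
        boundary = _brute_force_boundary(region)
        r, c = np.nonzero(boundary)
        oracle = np.hypot(r - 200, c - 200).mean() * 0.05
        assert m.distance == pytest.approx(oracle, abs=1e-6)

    def test_out_of_range_censored_at_max_range(self, cfg):
        region = _disc(401, 200)
        mask = _mask_from_region(region, cfg, 0.05, category="out_of_range")
        m = avoidance_distance(mask)
        assert m.distance == cfg.max_range
        assert m.censored

    def test_invalid_not_measurable(self, cfg):
        mask = _mask_from_region(np.zeros((401, 401), bool), cfg, 0.05, category="invalid")
        with pytest.raises(NotMeasurableError):
            avoidance_distance(mask)

    def test_radial_growth_shifts_distance_linearly(self, cfg):
        base = avoidance_distance(_mask_from_region(_disc(401, 50), cfg, 0.05)).distance
        for k in (5, 10, 20):
            grown = avoidance_distance(_mask_from_region(_disc(401, 50 + k), cfg, 0.05)).distance
            assert grown - base == pytest.approx(k * 0.05, abs=0.05)

    def test_rotation_invariance_quarter_turns(self, cfg):
        rng = np.random.default_rng(1)
        region = _disc(401, 60)
        region[180:200, 210:260] = True  # asymmetric lobe
        d0 = avoidance_distance(_mask_from_region(region, cfg, 0.05)).distance
        for k in (1, 2, 3):
            dk = avoidance_distance(
                _mask_from_region(np.rot90(region, k), cfg, 0.05)
            ).distance
            assert dk == pytest.approx(d0, abs=1e-9)


class TestPipelineRecovery:
    def test_estimate_tracks_ground_truth_phase_means(self, default_config):
        from pensonar import (
            SchoolParams, accumulate_cfp, make_schedule, phase_windows,
            segment_classical, simulate_frames,
        )

        school = SchoolParams(displacement_factor=0.4)
        sched = make_schedule(["s"], 1, order="sequential", start=660)
        frames, gt = simulate_frames(school, sched, default_config, seed=4)
        ev = sched.events[0]
        w = phase_windows(ev.onset, ev.duration, 5.0)
        for phase in ("before", "during", "after"):
            img = accumulate_cfp(frames, w[phase], 0.05)
            mask = segment_classical(img)
            est = avoidance_distance(mask).distance
            sel = [
                i for i, t in enumerate(gt.t)
                if w[phase][0] <= t and t + default_config.scan_period <= w[phase][1]
            ]
            truth = gt.true_radius[sel].mean()
            assert abs(est - truth) / truth <= 0.10


def test_measurements_table_columns():
    from pensonar import AvoidanceMeasurement

    tab = measurements_table(
        [AvoidanceMeasurement(distance=2.0, censored=False, category="pattern", phase="before")]
    )
    assert list(tab.columns) == [
        "replicate", "pen", "depth", "level", "phase",
        "category", "censored", "distance_m", "n_frames",
    ]
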