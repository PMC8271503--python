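import math

import numpy as np
import pytest

from sdmon.detection import BoundingBox, Detection, Frame
from sdmon.geometry import Homography
from sdmon.metrics import (
    SceneConfig,
    analyze_frame,
    count_violations,
    pairwise_distances,
    polygon_area,
    roi_filter,
    social_density,
    stats_from_world_points,
)
from sdmon.synthetic import SimulationConfig, simulate_frames

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]
SQUARE_10M = [(0, 0), (10, 0), (10, 10), (0, 10)]


class TestRoiFilter:
    @pytest.mark.parametrize(
        "point, kept",
        [
            ((0.5, 0.5), True),   # interior
            ((2.0, 2.0), False),  # exterior
            ((1.0, 0.5), True),   # on an edge: boundary-inclusive
            ((0.0, 0.0), True),   # vertex
        ],
    )
    def test_membership(self, point, kept):
        out = roi_filter([point], UNIT_SQUARE)
        assert (len(out) == 1) is kept

    def test_order_preserved(self):
        pts = [(0.9, 0.9), (5, 5), (0.1, 0.2), (0.3, 0.4)]
        out = roi_filter(pts, UNIT_SQUARE)
        np.testing.assert_allclose(out, [(0.9, 0.9), (0.1, 0.2), (0.3, 0.4)])

    def test_invalid_polygon_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError):
            roi_filter([(0.5, 0.5)], bowtie)


class TestPairwiseDistances:
    def test_three_four_five(self):
        np.testing.assert_allclose(pairwise_distances([(0, 0), (3, 4)]), [5.0])

    def test_fewer_than_two_points(self):
        assert pairwise_distances([(1, 1)]).size == 0
        assert pairwise_distances(np.empty((0, 2))).size == 0

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(-10, 10, size=(20, 2))
        expected = [
            math.dist(pts[i], pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        np.testing.assert_allclose(pairwise_distances(pts), expected)


class TestCountViolations:
    def test_unordered_strict(self):
        assert count_violations([1.5, 2.5, 3.0], 2.0) == 1

    def test_ordered_double_sum_counts_pairs_twice(self):
        assert count_violations([1.5, 2.5, 3.0], 2.0, pair_counting="ordered") == 2

    def test_boundary_semantics(self):
        assert count_violations([2.0], 2.0, violation_comparison="strict") == 0
        assert count_violations([2.0], 2.0, violation_comparison="inclusive") == 1

    def test_monotone_in_threshold(self, rng):
        d = rng.uniform(0, 5, size=40)
        counts = [count_violations(d, dc) for dc in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts)


class TestAreaAndDensity:
    def test_unit_square_area(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_right_triangle_area(self):
        assert polygon_area([(0, 0), (3, 0), (0, 4)]) == pytest.approx(6.0)

    def test_random_convex_polygons_vs_fan_triangulation(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            # jittered angles spread around the full circle keep the origin
            # interior, so the polygon is star-shaped about it
            angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.2, 0.8, n)) / n
            radii = rng.uniform(1, 5, size=n)
            poly = np.column_stack([radii * np.cos(angles),
                                    radii * np.sin(angles)])
            # the polygon is star-shaped about the origin (vertices sorted
            # by angle), so triangles (O, p_i, p_{i+1}) partition it exactly
            fan = sum(
                0.5 * abs(p[0] * q[1] - q[0] * p[1])
                for p, q in zip(poly, np.roll(poly, -1, axis=0))
            )
            assert polygon_area(poly) == pytest.approx(fan, abs=1e-9)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            polygon_area([(0, 0), (1, 1), (2, 2)])

    def test_social_density(self):
        assert social_density(10, 100.0) == pytest.approx(0.1)
        assert social_density(0, 50.0) == 0.0
        with pytest.raises(ValueError):
            social_density(3, 0.0)

    def test_density_matches_direct_division(self, rng):
        for _ in range(20):
            n = int(rng.integers(0, 100))
            a = float(rng.uniform(1, 1000))
            assert social_density(n, a) == n / a


def person(bottom_mid, width=1.0, height=1.0, score=0.9):
    u, v = bottom_mid
    box = BoundingBox(u - width / 2, v - height, u + width / 2, v)
    return Detection("person", box, score)


class TestAnalyzeFrame:
    def test_hand_computed_two_person_frame(self):
        """Identity map, 10 m ROI, feet at (1,1) and (1,2.5), d_c = 2 m."""
        frame = Frame(0, 0.0, [person((1.0, 1.0)), person((1.0, 2.5))])
        cfg = SceneConfig(roi_polygon=SQUARE_10M, d_c=2.0)
        st = analyze_frame(frame, Homography(np.eye(3)), cfg)
        assert st.n == 2
        assert st.v == 1
        assert st.d_avg == pytest.approx(1.5)
        assert st.r_v == pytest.approx(0.5)
        assert st.rho == pytest.approx(2 / 100.0)

    def test_empty_frame(self):
        cfg = SceneConfig(roi_polygon=SQUARE_10M)
        st = analyze_frame(Frame(0, 0.0, []), Homography(np.eye(3)), cfg)
        assert (st.n, st.rho, st.v) == (0, 0.0, 0)
        assert math.isnan(st.d_avg) and math.isnan(st.r_v)

    def test_single_pedestrian_has_defined_ratio(self):
        cfg = SceneConfig(roi_polygon=SQUARE_10M)
        st = analyze_frame(
            Frame(0, 0.0, [person((5.0, 5.0))]), Homography(np.eye(3)), cfg
        )
        assert st.n == 1 and st.v == 0
        assert st.r_v == 0.0
        assert math.isnan(st.d_avg)

    def test_noiseless_simulation_matches_truth_stats(self):
        """With a perfect detector the pipeline reproduces ground truth."""
        cfg = SimulationConfig(
            n_frames=30, pixel_noise_sigma=0.0, miss_prob=0.0,
            false_positive_rate=0.0, seed=7,
        )
        scene = cfg.scene_config()
        for sim in simulate_frames(cfg):
            st = analyze_frame(sim.frame, cfg.homography, scene)
            assert st.n == sim.truth_stats.n
            assert st.v == sim.truth_stats.v
            if st.n >= 2:
                assert st.d_avg == pytest.approx(
                    sim.truth_stats.d_avg, abs=1e-9
                )

    def test_identity_homography_equals_direct_computation(self, rng):
        """Projection is the only lossy stage: identity map changes nothing."""
        cfg = SceneConfig(roi_polygon=SQUARE_10M, d_c=2.0)
        pts = rng.uniform(0, 10, size=(15, 2))
        frame = Frame(0, 0.0, [person(tuple(p)) for p in pts])
        via_pipeline = analyze_frame(frame, Homography(np.eye(3)), cfg)
        direct = stats_from_world_points(pts, cfg)
        assert via_pipeline.v == direct.v
        np.testing.assert_allclose(via_pipeline.distances, direct.distances)

    def test_removing_pedestrian_never_increases_violations(self, rng):
        cfg = SceneConfig(roi_polygon=SQUARE_10M, d_c=2.0)
        pts = rng.uniform(0, 10, size=(12, 2))
        full = stats_from_world_points(pts, cfg).v
        for i in range(len(pts)):
            reduced = stats_from_world_points(np.delete(pts, i, 0), cfg).v
            assert reduced <= full

    def test_distance_list_length_invariant(self, rng):
        cfg = SceneConfig(roi_polygon=SQUARE_10M)
        for n in (0, 1, 2, 5, 11):
            pts = rng.uniform(0, 10, size=(n, 2))
            st = stats_from_world_points(pts, cfg)
            assert st.distances.size == st.n * (st.n - 1) // 2


class TestSceneConfig:
    def test_area_computed_from_polygon(self):
        assert SceneConfig(roi_polygon=SQUARE_10M).area_a0 == pytest.approx(100.0)

    def test_area_override(self):
        cfg = SceneConfig(roi_polygon=SQUARE_10M, area_a0=80.0)
        assert cfg.area_a0 == 80.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d_c": 0.0},
            {"u0": 1.0},
            {"pair_counting": "both"},
            {"pose_mode": "head"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(roi_polygon=SQUARE_10M, **kwargs)
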