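"""Combinatorial point-to-player assignment: enumeration, scoring, greedy
rounds, whole-frame localization, and the exhaustive oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hooploc.assignment import (
    Detection,
    DetectionSet,
    OptimizationConfig,
    brute_force_assign,
    enumerate_feasible_subsets,
    localize_frame,
    merged_score,
    score_subset,
    solve_round,
)
from hooploc.errors import ProblemSizeError
from hooploc.geometry import ImagePoint, WorldPoint, project, triangulate
from hooploc.synthetic import SceneConfig, make_camera_rig, make_scene


def _detections_from_truth(truth, cameras, frame_id=0, extra=()):
    """Noise-free projections of every player in every camera, plus extras."""
    dets, p = [], 0
    for cam in cameras:
        for _, world in truth:
            dets.append(Detection(p, cam.camera_id, project(cam, world)))
            p += 1
    for cam_id, image in extra:
        dets.append(Detection(p, cam_id, image))
        p += 1
    return DetectionSet(frame_id, dets, list(cameras))


@pytest.fixture(scope="module")
def rig(default_config):
    return make_camera_rig(SceneConfig(seed=0), seed=0)


class TestMergedScore:
    def test_zero_error_pair_scores_minus_two(self):
        assert merged_score([0.0, 0.0], 2) == -2.0

    def test_zero_error_triple_beats_pair(self):
        assert merged_score([0.0, 0.0, 0.0], 3) == -3.0 < merged_score([0.0, 0.0], 2)

    def test_error_arithmetic(self):
        assert merged_score([4.0, 9.0], 2) == pytest.approx(13.0 / 4.0 - 2.0)

    def test_strictly_decreasing_in_q_at_zero_error(self):
        scores = [merged_score([0.0] * q, q) for q in range(2, 8)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestEnumeration:
    def test_counts_two_one_one(self, rig):
        dets = [
            Detection(0, 0, ImagePoint(1, 1)),
            Detection(1, 0, ImagePoint(2, 2)),
            Detection(2, 1, ImagePoint(3, 3)),
            Detection(3, 2, ImagePoint(4, 4)),
        ]
        subsets = enumerate_feasible_subsets(DetectionSet(0, dets, rig))
        assert len(subsets) == 7  # 2 + 2 + 1 pairs + 2 triples
        sizes = sorted(len(s) for s in subsets)
        assert sizes == [2, 2, 2, 2, 2, 3, 3]
        for s in subsets:
            cams = [next(d for d in dets if d.point_index == p).camera_id for p in s]
            assert len(cams) == len(set(cams))

    def test_single_detection_yields_nothing(self, rig):
        ds = DetectionSet(0, [Detection(0, 0, ImagePoint(1, 1))], rig)
        assert enumerate_feasible_subsets(ds) == []

    def test_one_point_per_camera_over_two_cameras(self, rig):
        ds = DetectionSet(
            0, [Detection(0, 0, ImagePoint(1, 1)), Detection(1, 1, ImagePoint(2, 2))], rig[:2]
        )
        assert enumerate_feasible_subsets(ds) == [(0, 1)]

    def test_deterministic_order(self, rig):
        dets = [Detection(p, p % 3, ImagePoint(p, p)) for p in range(6)]
        ds = DetectionSet(0, dets, rig)
        assert enumerate_feasible_subsets(ds) == enumerate_feasible_subsets(ds)


class TestScoreSubset:
    def test_noise_free_triple_scores_minus_three(self, rig, default_config):
        truth = [(0, WorldPoint(3.0, 4.0, 1.8))]
        ds = _detections_from_truth(truth, rig)
        scored = score_subset((0, 1, 2), ds, default_config)
        assert scored is not None
        assert scored.score == pytest.approx(-3.0, abs=1e-9)
        assert np.max(np.abs(scored.position.as_array() - [3, 4, 1.8])) <= 1e-6

    def test_score_consistent_with_merged_objective(self, default_config):
        scene = make_scene(SceneConfig(n_players=2, noise_px=2.0, seed=9))
        for subset in enumerate_feasible_subsets(scene.detections):
            scored = score_subset(subset, scene.detections, default_config)
            if scored is None:
                continue
            assert scored.score == pytest.approx(
                merged_score(scored.squared_errors, len(subset))
            )

    def test_height_constraint_infeasible(self, rig):
        # a point triangulating at floor height violates the head-height band
        floor = [(0, WorldPoint(5.0, 5.0, 0.3))]
        ds = _detections_from_truth(floor, rig)
        cfg = OptimizationConfig(h_min=1.2, h_max=3.2)
        assert score_subset((0, 1, 2), ds, cfg) is None

    def test_pixel_tolerance_infeasible(self, rig):
        truth = [(0, WorldPoint(3.0, 4.0, 1.8))]
        ds = _detections_from_truth(truth, rig)
        # corrupt one observation far beyond any tolerance
        bad = Detection(0, ds.detections[0].camera_id,
                        ImagePoint(ds.detections[0].image.x + 200, ds.detections[0].image.y))
        ds.detections[0] = bad
        cfg = OptimizationConfig(tau_px=25.0)
        assert score_subset((0, 1, 2), ds, cfg) is None


class TestSolveRound:
    def test_picks_true_triple_over_outlier_combinations(self, rig, default_config):
        truth = [(0, WorldPoint(3.0, 4.0, 1.8))]
        outlier = ImagePoint(
            project(rig[0], truth[0][1]).x + 200, project(rig[0], truth[0][1]).y + 30
        )
        ds = _detections_from_truth(truth, rig, extra=[(0, outlier)])
        best = solve_round(ds, default_config)
        assert best is not None
        assert best.point_indices == (0, 1, 2)
        assert best.score == pytest.approx(-3.0, abs=1e-9)
        assert np.max(np.abs(best.position.as_array() - [3, 4, 1.8])) <= 1e-6

    def test_matches_independent_exhaustive_scan(self, default_config):
        """The round minimum equals an independently coded exhaustive scan."""
        for seed in range(8):
            scene = make_scene(
                SceneConfig(n_players=3, noise_px=1.5, outliers_per_camera=1, seed=200 + seed)
            )
            best = solve_round(scene.detections, default_config)
            oracle = _oracle_best(scene.detections, default_config)
            if oracle is None:
                assert best is None
            else:
                assert best is not None
                assert best.score == pytest.approx(oracle, abs=1e-9)

    def test_empty_detections_none(self, rig, default_config):
        assert solve_round(DetectionSet(0, [], rig), default_config) is None

    def test_two_points_single_camera_none(self, rig, default_config):
        ds = DetectionSet(
            0, [Detection(0, 0, ImagePoint(1, 1)), Detection(1, 0, ImagePoint(9, 9))], rig
        )
        assert solve_round(ds, default_config) is None


def _oracle_best(detections, config):
    """Independent exhaustive scan: best per-player score over all subsets."""
    by_index = {d.point_index: d for d in detections.detections}
    by_cam = {}
    for d in detections.detections:
        by_cam.setdefault(d.camera_id, []).append(d.point_index)
    best = None
    cam_ids = sorted(by_cam)
    for r in range(2, len(cam_ids) + 1):
        for cams in itertools.combinations(cam_ids, r):
            for pick in itertools.product(*(by_cam[c] for c in cams)):
                obs = [(detections.camera(by_index[p].camera_id), by_index[p].image) for p in pick]
                try:
                    world, errors = triangulate(obs)
                except Exception:
                    continue
                if not (config.h_min <= world.Z <= config.h_max):
                    continue
                sq = [e**2 for e in errors]
                if max(sq) > config.tau_px**2:
                    continue
                score = sum(sq) / len(pick) ** 2 - len(pick)
                if best is None or score < best:
                    best = score
    return best


class TestLocalizeFrame:
    def test_two_players_noise_free(self, rig, default_config):
        truth = [(0, WorldPoint(3.0, 4.0, 1.8)), (1, WorldPoint(10.0, 11.0, 2.0))]
        ds = _detections_from_truth(truth, rig)
        locs, matrix = localize_frame(ds, default_config)
        assert [l.method for l in locs] == ["optimized", "optimized"]
        positions = sorted((l.position.X, l.position.Y, l.position.Z) for l in locs)
        expected = sorted((p.X, p.Y, p.Z) for _, p in truth)
        np.testing.assert_allclose(positions, expected, atol=1e-6)
        assert matrix.entries.shape == (6, 2)

    def test_single_camera_point_falls_back_to_mean_height(self, rig, default_config):
        truth = [(0, WorldPoint(5.0, 6.0, 1.85))]
        ds = DetectionSet(0, [Detection(0, 0, project(rig[0], truth[0][1]))], rig)
        locs, matrix = localize_frame(ds, default_config)
        assert len(locs) == 1
        assert locs[0].method == "fallback"
        assert locs[0].position.Z == default_config.mean_height
        assert matrix.entries.shape == (1, 0)

    def test_three_optimized_plus_three_fallback(self, rig, default_config):
        """The worked frame pattern: three multi-view players localized by
        optimization and three leftover single-view points by the height
        prior."""
        truth = [
            (0, WorldPoint(3.0, 4.0, 1.8)),
            (1, WorldPoint(10.0, 11.0, 2.0)),
            (2, WorldPoint(6.5, 7.5, 1.7)),
        ]
        extras = [(0, ImagePoint(200.0, 200.0)), (0, ImagePoint(600.0, 300.0)),
                  (0, ImagePoint(400.0, 500.0))]
        ds = _detections_from_truth(truth, rig, extra=extras)
        locs, _ = localize_frame(ds, default_config)
        methods = [l.method for l in locs]
        assert methods.count("optimized") == 3
        assert methods.count("fallback") == 3
        for l in locs:
            if l.method == "fallback":
                assert l.n_points == 1 and l.position.Z == default_config.mean_height
            else:
                assert l.n_points >= 2

    def test_assignment_matrix_invariants_under_clutter(self, default_config):
        for seed in range(6):
            scene = make_scene(
                SceneConfig(
                    n_players=3, noise_px=2.0, miss_prob=0.2, outliers_per_camera=2,
                    seed=700 + seed,
                )
            )
            locs, matrix = localize_frame(scene.detections, default_config)
            matrix.validate(scene.detections)  # raises on any violation
            tau_sq = default_config.tau_px**2
            for l in locs:
                if l.method == "optimized":
                    assert l.n_points >= 2
                    assert all(e <= tau_sq + 1e-9 for e in l.squared_errors)
                    assert default_config.h_min <= l.position.Z <= default_config.h_max
                else:
                    assert l.n_points == 1
                    assert l.position.Z == default_config.mean_height

    def test_tightening_tau_never_adds_optimized_players(self, default_config):
        scene = make_scene(
            SceneConfig(n_players=4, noise_px=3.0, outliers_per_camera=1, seed=321)
        )
        counts = []
        for tau in (25.0, 10.0, 5.0, 2.0, 0.5):
            cfg = OptimizationConfig(tau_px=tau)
            locs, _ = localize_frame(scene.detections, cfg)
            counts.append(sum(1 for l in locs if l.method == "optimized"))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_max_players_caps_rounds(self, rig, default_config):
        truth = [(i, WorldPoint(2.0 + 3 * i, 3.0 + 3 * i, 1.8)) for i in range(3)]
        ds = _detections_from_truth(truth, rig)
        cfg = OptimizationConfig(max_players=1)
        locs, _ = localize_frame(ds, cfg)
        assert sum(1 for l in locs if l.method == "optimized") == 1


class TestBruteForce:
    def test_total_score_dominates_greedy(self, default_config):
        for seed in range(10):
            scene = make_scene(
                SceneConfig(n_players=3, noise_px=2.0, outliers_per_camera=1, seed=40 + seed)
            )
            locs, _ = localize_frame(scene.detections, default_config)
            greedy_total = sum(l.score for l in locs if l.method == "optimized")
            oracle = brute_force_assign(scene.detections, default_config)
            assert oracle.total_score <= greedy_total + 1e-9

    def test_matches_greedy_on_noise_free_instance(self, rig, default_config):
        truth = [(0, WorldPoint(3.0, 4.0, 1.8)), (1, WorldPoint(10.0, 11.0, 2.0))]
        ds = _detections_from_truth(truth, rig)
        locs, matrix = localize_frame(ds, default_config)
        oracle = brute_force_assign(ds, default_config)
        np.testing.assert_array_equal(matrix.entries, oracle.assignment.entries)

    def test_single_feasible_subset(self, default_config):
        truth = [(0, WorldPoint(5.0, 6.0, 1.85))]
        rig2 = make_camera_rig(SceneConfig(n_cameras=2, seed=0), seed=0)
        ds = _detections_from_truth(truth, rig2)
        oracle = brute_force_assign(ds, default_config)
        assert len(oracle.players) == 1
        assert oracle.players[0].score == pytest.approx(-2.0, abs=1e-9)

    def test_size_guard(self, rig, default_config):
        dets = [Detection(p, p % 3, ImagePoint(10 * p, 10 * p)) for p in range(13)]
        with pytest.raises(ProblemSizeError):
            brute_force_assign(DetectionSet(0, dets, rig), default_config)
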