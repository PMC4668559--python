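"""Maze generation, movement geometry, trial construction and behavior."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mazeview import maze_task as mt
from _oracles import brute_force_violations


def violations_as_set(violations):
    return {(v.kind, tuple(v.coords)) for v in violations}


class TestConstraintChecker:
    def test_white_patch_detected_with_coordinates(self):
        grid = np.zeros((7, 7), dtype=bool)
        grid[2:4, 2:4] = True  # a 2x2 all-path block
        kinds = {(v.kind, v.coords) for v in mt.check_map_constraints(grid)}
        assert ("WHITE_PATCH", ((2, 2), (2, 3), (3, 2), (3, 3))) in kinds

    def test_dead_end_detected(self):
        grid = np.zeros((7, 7), dtype=bool)
        grid[3, 2:5] = True  # a short corridor: both ends are dead ends
        kinds = [v.kind for v in mt.check_map_constraints(grid)]
        assert kinds.count("DEAD_END") == 2

    def test_all_wall_grid_reports_no_path(self):
        grid = np.zeros((7, 7), dtype=bool)
        assert [v.kind for v in mt.check_map_constraints(grid)] == ["NO_PATH"]

    def test_wrong_shape_raises(self):
        with pytest.raises(ValueError, match="7x7"):
            mt.check_map_constraints(np.zeros((6, 7), dtype=bool))

    @given(st.integers(0, 2**31 - 1), st.floats(0.25, 0.75))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_scan(self, seed, density):
        grid = np.random.default_rng(seed).random((7, 7)) < density
        assert violations_as_set(mt.check_map_constraints(grid)) == \
            brute_force_violations(grid)


class TestGenerateMap:
    def test_satisfies_all_constraints(self):
        maze = mt.generate_map(seed=1, map_id=1)
        assert mt.check_map_constraints(maze) == []

    def test_deterministic_given_seed(self):
        a = mt.generate_map(seed=1, map_id=1)
        b = mt.generate_map(seed=1, map_id=1)
        assert np.array_equal(a.grid, b.grid)

    def test_no_white_patch_by_exhaustive_window_scan(self):
        maze = mt.generate_map(seed=2, map_id=1)
        for r in range(6):
            for c in range(6):
                assert not maze.grid[r:r + 2, c:c + 2].all()

    def test_symmetric_flag_gives_point_symmetric_valid_map(self):
        maze = mt.generate_map(seed=3, map_id=1, symmetric=True)
        assert np.array_equal(maze.grid, maze.grid[::-1, ::-1])
        assert mt.check_map_constraints(maze) == []

    def test_exhausted_search_raises(self):
        with pytest.raises(mt.MapGenerationError):
            mt.generate_map(seed=1, map_id=1, max_restarts=1, max_steps=1)

    def test_text_and_json_round_trip(self):
        maze = mt.generate_map(seed=4, map_id=2)
        assert np.array_equal(mt.MazeMap.from_text(maze.to_text(), 2).grid, maze.grid)
        assert np.array_equal(mt.MazeMap.from_json(maze.to_json()).grid, maze.grid)


class TestMovementAndScene:
    def test_forward_advances_one_cell(self, hand_map):
        assert mt.apply_movement(mt.Pose(3, 2, "E"), "FWD", hand_map) == mt.Pose(3, 3, "E")
        assert mt.apply_movement(mt.Pose(3, 1, "N"), "FWD", hand_map) == mt.Pose(2, 1, "N")

    def test_turns_rotate_in_place(self, hand_map):
        pose = mt.Pose(3, 3, "N")
        assert mt.apply_movement(pose, "TURN_L", hand_map) == mt.Pose(3, 3, "W")
        assert mt.apply_movement(pose, "TURN_R", hand_map) == mt.Pose(3, 3, "E")

    def test_forward_into_wall_or_off_grid_raises(self, hand_map):
        with pytest.raises(mt.InvalidMovementError):
            mt.apply_movement(mt.Pose(3, 3, "N"), "FWD", hand_map)  # wall at (2,3)
        edge = mt.MazeMap(1, np.ones((7, 7), dtype=bool))
        with pytest.raises(mt.InvalidMovementError):
            mt.apply_movement(mt.Pose(0, 2, "N"), "FWD", edge)

    def test_scene_from_hand_built_grid(self):
        # only (0,1) is a path among the five squares visible from (1,1,N)
        grid = np.zeros((7, 7), dtype=bool)
        grid[1, 1] = True
        grid[0, 1] = True
        maze = mt.MazeMap(1, grid)
        scene = mt.observe_scene(maze, mt.Pose(1, 1, "N"))
        assert scene == mt.SceneView(left=False, right=False, fwd_left=False,
                                     fwd_center=True, fwd_right=False)

    def test_facing_grid_edge_sees_walls_ahead(self):
        maze = mt.MazeMap(1, np.ones((7, 7), dtype=bool))
        scene = mt.observe_scene(maze, mt.Pose(0, 3, "N"))
        assert (scene.fwd_left, scene.fwd_center, scene.fwd_right) == (False, False, False)

    def test_two_left_turns_equal_180_degree_rotation(self, hand_map):
        for pose in (mt.Pose(3, 3, "N"), mt.Pose(1, 2, "E"), mt.Pose(5, 4, "W")):
            turned = mt.apply_movement(
                mt.apply_movement(pose, "TURN_L", hand_map), "TURN_L", hand_map)
            opposite = {"N": "S", "S": "N", "E": "W", "W": "E"}[pose.heading]
            assert mt.observe_scene(hand_map, turned) == \
                mt.observe_scene(hand_map, mt.Pose(pose.row, pose.col, opposite))

    def test_pose_on_wall_raises(self, hand_map):
        with pytest.raises(ValueError, match="path"):
            mt.observe_scene(hand_map, mt.Pose(0, 0, "N"))


class TestDistracter:
    def test_flip_differs_in_exactly_one_part(self, hand_map, rng):
        pose = mt.Pose(3, 2, "E")
        scene = mt.observe_scene(hand_map, pose)
        distracter, part = mt.make_distracter(hand_map, pose, scene, rng)
        diffs = [p for p in mt.VIEW_PARTS if distracter.part(p) != scene.part(p)]
        assert diffs == [part]
        assert (distracter.left, distracter.right) == (scene.left, scene.right)

    def test_flip_creating_white_patch_is_excluded(self):
        # 2x2 path block forms if (2,2) flips to path: that part is infeasible
        grid = np.zeros((7, 7), dtype=bool)
        grid[1, 1:6] = True
        grid[2, 1] = grid[2, 5] = True
        grid[3, 1:6] = True
        maze = mt.MazeMap(1, grid)
        # from (3,2) facing N the forward-center square is (2,2)
        assert not mt.distracter_feasible(maze, mt.Pose(3, 2, "N"), "FC")

    def test_no_feasible_flip_raises_rejection_signal(self, hand_map, rng):
        pose = mt.Pose(1, 1, "N")
        scene = mt.observe_scene(hand_map, pose)
        with pytest.raises(mt.DistracterInfeasibleError):
            mt.make_distracter(hand_map, pose, scene, rng)

    def test_flipped_map_copy_passes_pattern_constraints(self, study_maps, rng):
        maze = study_maps[0]
        catalog = mt._trial_catalog(maze)
        for (part, _), entries in catalog.items():
            for _, _, post in entries[:5]:
                r, c = mt.view_part_cell(post, part)
                flipped = maze.grid.copy()
                flipped[r, c] = ~flipped[r, c]
                local = {v.kind for v in mt.check_map_constraints(flipped)} - \
                    {"DISCONNECTED", "NO_PATH"}
                assert not local


class TestTrialSet:
    def test_session_and_delay_structure(self, study_trials):
        by_session = collections.Counter(t.session_id for t in study_trials)
        assert by_session == {s: 64 for s in range(1, 6)}
        for s in range(1, 6):
            delays = [t.delay_s for t in study_trials if t.session_id == s]
            assert sum(d == 5 for d in delays) == 60
            assert sorted(set(delays)) == [1, 3, 5]

    def test_all_movements_effective(self, study_maps, study_trials):
        by_id = {m.map_id: m for m in study_maps}
        for t in study_trials:
            maze = by_id[t.map_id]
            pose = t.initial_pose
            for mv_ in t.movements:  # FWD into a wall would raise
                pose = mt.apply_movement(pose, mv_, maze)
            assert pose == t.post_pose
            assert t.movements[2] == "FWD"
            assert maze.is_path(t.post_pose.row, t.post_pose.col)

    def test_distracter_single_flip_exhaustive(self, study_trials):
        for t in study_trials:
            diffs = [p for p in mt.VIEW_PARTS
                     if t.distracter.part(p) != t.correct_scene.part(p)]
            assert diffs == [t.flipped_part]

    def test_flip_counterbalancing_within_two(self, study_trials):
        counts = collections.Counter(t.flipped_part for t in study_trials)
        values = list(counts.values())
        assert max(values) - min(values) <= 2

    def test_wall_rates_steered_to_half(self, study_trials):
        for part in mt.VIEW_PARTS:
            sub = [t for t in study_trials if t.flipped_part == part]
            wall_rate = np.mean([not t.correct_scene.part(part) for t in sub])
            assert 0.45 <= wall_rate <= 0.55

    def test_position_coverage_meets_default(self, study_maps, study_trials):
        assert mt._position_coverage(study_trials, study_maps) >= 0.6

    def test_deterministic_given_seed(self, study_maps):
        a = mt.generate_trial_set(study_maps, seed=1)
        b = mt.generate_trial_set(study_maps, seed=1)
        assert [t.set_key for t in a] == [t.set_key for t in b]

    def test_infeasible_criteria_raise_with_diagnostics(self, study_maps):
        config = mt.TaskConfig(sessions=1, trials_per_session=12,
                               delay5_per_session=12, coverage_min=0.99,
                               max_set_retries=2)
        with pytest.raises(mt.TrialGenerationError, match="coverage"):
            mt.generate_trial_set(study_maps, config, seed=1)


class TestLabels:
    def test_map_code_one_hot(self, study_maps, study_trials):
        for t in study_trials[:50]:
            labels = mt.derive_trial_labels(t, study_maps)
            assert sum(labels.map_code) == 1
            assert labels.map_code[t.map_id - 1] == 1

    def test_middle_row_is_both_upper_and_lower(self, hand_map):
        trial = _trial_at(hand_map, mt.Pose(3, 1, "N"), post=mt.Pose(3, 1, "N"))
        labels = mt.derive_trial_labels(trial, [hand_map])
        assert labels.position[0] == 1 and labels.position[1] == 1

    def test_upcoming_codes_match_scene(self, study_maps, study_trials):
        for t in study_trials[:50]:
            labels = mt.derive_trial_labels(t, study_maps)
            assert labels.upcoming == tuple(
                int(t.correct_scene.part(p)) for p in mt.VIEW_PARTS)

    def test_labels_pure_function_of_trial_and_maps(self, study_maps, study_trials):
        t = study_trials[0]
        a = mt.derive_trial_labels(t, study_maps)
        b = mt.derive_trial_labels(t, study_maps)
        assert a == b


def _trial_at(maze, pose, post):
    scene = mt.observe_scene(maze, post)
    return mt.Trial(trial_id=1, session_id=1, map_id=maze.map_id, initial_pose=pose,
                    movements=("TURN_L", "TURN_L", "FWD"), delay_s=5, post_pose=post,
                    correct_scene=scene, distracter=scene.with_part_flipped("FC"),
                    flipped_part="FC", target_position="UP")


class TestBehavior:
    def test_degenerate_model_all_correct(self, study_trials):
        model = mt.BehaviorModel(
            p_correct_by_part={"FL": 1.0, "FC": 1.0, "FR": 1.0}, p_miss=0.0, seed=1)
        done = mt.simulate_behavior(study_trials[:100], model)
        assert all(t.outcome == "CORRECT" for t in done)

    def test_half_correct_rate_within_binomial_band(self, study_maps):
        config = mt.TaskConfig(sessions=5, trials_per_session=64,
                               delay5_per_session=60)
        trials = mt.generate_trial_set(study_maps, config, seed=3)
        # ~3000 bernoulli draws at p=0.5 via ten behavioral replicates
        outcomes = []
        for rep in range(10):
            model = mt.BehaviorModel(
                p_correct_by_part={p: 0.5 for p in mt.VIEW_PARTS}, p_miss=0.0,
                seed=rep)
            outcomes += [t.outcome == "CORRECT"
                         for t in mt.simulate_behavior(trials, model)]
        assert abs(np.mean(outcomes) - 0.5) < 0.03

    def test_incorrect_trials_choose_the_distracter(self, study_trials):
        model = mt.BehaviorModel(
            p_correct_by_part={p: 0.3 for p in mt.VIEW_PARTS}, p_miss=0.0, seed=2)
        done = mt.simulate_behavior(study_trials, model)
        for t in done:
            if t.outcome == "INCORRECT":
                assert t.chosen_scene == t.distracter
            elif t.outcome == "CORRECT":
                assert t.chosen_scene == t.correct_scene

    def test_rt_z_scored_within_session(self, study_trials):
        done = mt.simulate_behavior(study_trials, mt.BehaviorModel(seed=3))
        for s in range(1, 6):
            z = [t.rt_z for t in done if t.session_id == s and t.rt_z is not None]
            assert abs(np.mean(z)) < 1e-9
            assert abs(np.std(z) - 1.0) < 1e-6

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            mt.BehaviorModel(p_correct_by_part={"FL": 1.2, "FC": 0.9, "FR": 0.9})
        with pytest.raises(ValueError):
            mt.BehaviorModel(p_miss=-0.1)
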