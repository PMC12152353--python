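"""Generator correctness: schedule balance, trajectory ground truth, scenes."""

from collections import Counter

import numpy as np
import pytest

import pickplace as pp
from pickplace.kinematics import compute_speed
from pickplace.synthetic_data import COLORS, INSTRUCTIONS, SEARCH_SIZES


class TestSchedule:
    def test_nine_blocks_give_81_trials(self):
        assert len(pp.generate_schedule(seed=1, n_blocks=9)) == 81

    def test_single_block_is_balanced(self):
        trials = pp.generate_schedule(seed=1, n_blocks=1)
        assert len(trials) == 9
        assert Counter(t.instruction for t in trials) == {i: 3 for i in INSTRUCTIONS}
        assert Counter(t.target_color for t in trials) == {c: 3 for c in COLORS}

    @pytest.mark.parametrize("seed", [0, 7, 12345])
    def test_condition_triples_balanced_across_main_experiment(self, seed):
        trials = pp.generate_schedule(seed=seed, n_blocks=9)
        triples = Counter((t.instruction, t.search_size, t.target_color)
                          for t in trials)
        assert len(triples) == 27
        assert set(triples.values()) == {3}
        for t in trials:
            block = [u for u in trials if u.block == t.block]
            assert len(block) == 9

    def test_deterministic_and_seed_sensitive(self):
        a = pp.generate_schedule(seed=3, n_blocks=2)
        b = pp.generate_schedule(seed=3, n_blocks=2)
        c = pp.generate_schedule(seed=4, n_blocks=2)
        assert a == b
        assert a != c

    def test_invalid_block_count_rejected(self):
        with pytest.raises(ValueError):
            pp.generate_schedule(seed=1, n_blocks=0)


class TestTrajectory:
    def test_alternating_reach_transport_counts(self, clean_trial):
        _, _, truth = clean_trial
        phases = [s.phase for s in truth.segments]
        assert phases == ["reach", "transport"] * 4
        bounds = truth.boundaries()
        assert all(b[0] < b[1] for b in bounds)
        assert all(bounds[i][1] < bounds[i + 1][0] for i in range(len(bounds) - 1))

    def test_unskewed_legs_have_50_percent_deceleration(self, layout):
        params = pp.CohortParams(
            noise_sd_px=0.0, p_likelihood_dropout=0.0, arc_height_frac=0.0,
            decel_jitter=0.0,
            deceleration_fraction={"collect": 0.5, "sort": 0.5, "pile": 0.5},
            reach_deceleration_fraction=0.5)
        spec = pp.TrialSpec("P01", 1, 1, "sort", "blue", 3, 2000.0)
        _, truth = pp.generate_trial_trajectory(spec, layout, params, rng=0)
        for seg in truth.segments:
            n = seg.end_frame - seg.start_frame
            assert abs(seg.decel_fraction - 0.5) <= 1.5 / n  # frame quantization

    def test_planted_deceleration_recovered_in_ground_truth(self, layout):
        params = pp.CohortParams(noise_sd_px=0.0, p_likelihood_dropout=0.0,
                                 arc_height_frac=0.0, decel_jitter=0.0)
        spec = pp.TrialSpec("P01", 1, 1, "pile", "red", 5, 2000.0)
        _, truth = pp.generate_trial_trajectory(spec, layout, params, rng=4)
        for seg in truth.segments:
            n = seg.end_frame - seg.start_frame
            assert abs(seg.decel_fraction
                       - seg.planted_decel_fraction) <= 1.5 / n

    def test_zero_noise_speed_is_zero_in_dwells_positive_in_legs(self,
                                                                 clean_trial):
        _, track, truth = clean_trial
        speed = compute_speed(track)
        for s, e in truth.boundaries():
            assert speed[s:e + 1].min() > 0
        # between a reach end and the next transport start the hand dwells
        for i in range(0, len(truth.segments) - 1, 2):
            a = truth.segments[i].end_frame
            b = truth.segments[i + 1].start_frame
            assert np.all(speed[a + 2:b] == 0)

    def test_bit_reproducible_under_seed(self, layout, clean_params):
        spec = pp.TrialSpec("P02", 1, 3, "collect", "yellow", 4, 1900.0)
        t1, _ = pp.generate_trial_trajectory(spec, layout, clean_params, rng=9)
        t2, _ = pp.generate_trial_trajectory(spec, layout, clean_params, rng=9)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)

    def test_dropouts_have_low_likelihood(self, layout):
        params = pp.CohortParams(p_likelihood_dropout=0.2)
        spec = pp.TrialSpec("P01", 1, 1, "sort", "blue", 3, 2000.0)
        track, _ = pp.generate_trial_trajectory(spec, layout, params, rng=1)
        low = track.likelihood < 0.7
        assert 0.1 < low.mean() < 0.3
        assert track.likelihood[~low].min() >= 0.98


class TestScenes:
    def test_no_picked_bricks_leaves_picking_pad_unchanged(self, layout):
        place = [layout.placing_pad.center]
        start, end = pp.generate_scene_pair(layout, place, [], seed=2,
                                            n_distractors=5)
        box = layout.pad_px("picking")
        assert np.array_equal(np.asarray(start.crop(box)),
                              np.asarray(end.crop(box)))

    @pytest.mark.filterwarnings("ignore:overlapping bricks")
    def test_seeded_scene_pair_is_bit_identical(self, layout):
        pick = [layout.picking_pad.center]
        place = [layout.placing_pad.center]
        a = pp.generate_scene_pair(layout, place, pick, seed=5)
        b = pp.generate_scene_pair(layout, place, pick, seed=5)
        assert np.array_equal(np.asarray(a[0]), np.asarray(b[0]))
        assert np.array_equal(np.asarray(a[1]), np.asarray(b[1]))

    def test_single_pick_changes_only_its_quadrant_of_picking_pad(self, layout):
        q3 = layout.picking_pad.quadrants()[3].center  # near-left
        start, end = pp.generate_scene_pair(layout, [layout.placing_pad.center],
                                            [q3], seed=8, n_distractors=0)
        diff = np.abs(np.asarray(start, dtype=int) - np.asarray(end, dtype=int)
                      ).sum(axis=2)
        left, top, right, bottom = layout.pad_px("picking")
        crop = diff[top:bottom, left:right]
        h, w = crop.shape
        assert crop[h // 2:, :w // 2].sum() > 0          # near-left changed
        assert crop[:h // 2, :].sum() == 0               # far half untouched
        assert crop[h // 2:, w // 2:].sum() == 0         # near-right untouched

    def test_positions_off_pad_rejected(self, layout):
        with pytest.raises(ValueError):
            pp.generate_scene_pair(layout, [(0.0, 0.0)], [], seed=1)


class TestCohort:
    def test_24_by_81_cohort_has_1944_trials(self):
        params = pp.CohortParams(seed=1)
        cohort = pp.generate_cohort(params)
        assert len(cohort) == 1944
        assert cohort.metadata["participant"].nunique() == 24

    def test_cohort_trials_deterministic(self):
        params = pp.CohortParams(n_participants=2, trials_per_participant=9,
                                 seed=3)
        c1, c2 = pp.generate_cohort(params), pp.generate_cohort(params)
        _, t1, _ = c1.trial(5)
        _, t2, _ = c2.trial(5)
        assert np.array_equal(t1.x, t2.x)

    def test_first_large_rate_matches_planted_probability(self, layout):
        params = pp.CohortParams(noise_sd_px=0.0, p_likelihood_dropout=0.0)
        rng = np.random.default_rng(0)
        n, hits = 300, 0
        for i in range(n):
            spec = pp.TrialSpec("P01", 1, 1, "pile", "red", 3, 2000.0)
            _, truth = pp.generate_trial_trajectory(spec, layout, params,
                                                    rng=rng)
            hits += truth.first_target_size == "large"
        # planted 0.888; binomial 3-sigma band at n=300 is about +/- 0.055
        assert abs(hits / n - 0.888) < 0.06

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pp.CohortParams(quadrant_weights=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            pp.CohortParams(p_drop_artifact=1.5)
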