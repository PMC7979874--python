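"""Schedule counterbalancing and synthetic-data generator properties."""

import numpy as np
import pandas as pd
import pytest

from fmriseq.synth import (
    BlendSpec,
    VoxelPatternSpec,
    class_templates,
    insert_events,
    make_repetition_schedule,
    make_sequence_schedule,
    make_slow_schedule,
    simulate_probabilities,
    simulate_rest,
    simulate_voxels,
    truncated_poisson,
)
from conftest import by_isi


@pytest.fixture(scope="module")
def slow_sched():
    return make_slow_schedule(seed=1)


@pytest.fixture(scope="module")
def seq_sched():
    return make_sequence_schedule(seed=1)


@pytest.fixture(scope="module")
def rep_sched():
    return make_repetition_schedule(seed=1)


class TestSlowSchedule:
    @pytest.fixture()
    def sched(self, slow_sched):
        return slow_sched

    def test_600_stimulus_events(self, sched):
        assert len(sched) == 600

    def test_all_120_orders_unique(self, sched):
        orders = sched.sort_values(["trial_id", "serial_position"]).groupby("trial_id")["item_class"].agg(tuple)
        assert len(orders) == 120
        assert len(set(orders)) == 120

    def test_24_oddballs_per_class(self, sched):
        odd = sched[sched.orientation == "upside_down"]
        assert len(odd) == 120
        assert odd.groupby("item_class").size().eq(24).all()

    def test_onsets_nondecreasing_within_run(self, sched):
        for _, g in sched.groupby("run_id"):
            assert g["onset"].is_monotonic_increasing

    def test_iti_respects_lower_limit(self, sched):
        for _, g in sched.groupby("run_id"):
            gaps = np.diff(g["onset"].to_numpy()) - 0.5
            assert (gaps >= 1.0 - 1e-9).all()


class TestSequenceSchedule:
    @pytest.fixture()
    def sched(self, seq_sched):
        return seq_sched

    def test_75_trials(self, sched):
        assert sched["trial_id"].nunique() == 75

    def test_each_class_first_and_last_three_times(self, sched):
        one_speed = sched[np.isclose(sched.isi_seconds, 0.032)]
        firsts = one_speed[one_speed.serial_position == 1]["item_class"].value_counts()
        lasts = one_speed[one_speed.serial_position == 5]["item_class"].value_counts()
        assert firsts.eq(3).all() and lasts.eq(3).all()

    def test_each_order_at_every_speed(self, sched):
        orders = sched.sort_values("serial_position").groupby("trial_id").agg(
            order=("item_class", tuple), isi=("isi_seconds", "first")
        )
        counts = orders.groupby("order")["isi"].nunique()
        assert (counts == 5).all()

    def test_sequence_trials_contain_each_class_once(self, sched):
        assert (sched.groupby("trial_id")["item_class"].nunique() == 5).all()

    def test_target_positions_in_range(self, sched):
        t = sched["target_position"]
        assert t.between(1, 5).all()

    def test_truncated_poisson_bounds_and_shape(self):
        rng = np.random.default_rng(0)
        draws = truncated_poisson(rng, 1.9, 1, 5, 5000)
        assert draws.min() >= 1 and draws.max() <= 5
        # later positions more frequent than a symmetric split would give
        assert (draws >= 2).mean() > 0.5


class TestRepetitionSchedule:
    @pytest.fixture()
    def sched(self, rep_sched):
        return rep_sched

    def test_45_trials(self, sched):
        assert sched["trial_id"].nunique() == 45

    def test_switch_positions_sweep_2_to_9(self, sched):
        nine = sched.groupby("trial_id").filter(lambda g: len(g) == 9)
        per_first = nine.groupby("trial_id").agg(
            first=("item_class", "first"), switch=("target_position", "first")
        )
        for _, g in per_first.groupby("first"):
            assert sorted(g["switch"]) == list(range(2, 10))

    def test_exactly_two_classes_per_trial(self, sched):
        assert (sched.groupby("trial_id")["item_class"].nunique() == 2).all()

    def test_each_second_class_twice_per_first(self, sched):
        nine = sched.groupby("trial_id").filter(lambda g: len(g) == 9)
        pairs = nine.sort_values("serial_position").groupby("trial_id").agg(
            first=("item_class", "first"), second=("item_class", "last")
        )
        counts = pairs.groupby(["first", "second"]).size()
        assert (counts == 2).all()
        assert len(counts) == 20

    def test_long_trials_have_16_items_switch_last(self, sched):
        long = sched.groupby("trial_id").filter(lambda g: len(g) == 16)
        assert long["trial_id"].nunique() == 5
        assert (long.groupby("trial_id")["target_position"].first() == 16).all()


class TestScheduleReproducibility:
    @pytest.mark.parametrize("maker", [make_slow_schedule, make_sequence_schedule, make_repetition_schedule])
    def test_same_seed_identical_different_seed_not(self, maker):
        a, b, c = maker(seed=4), maker(seed=4), maker(seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestSimulateProbabilities:
    def test_rows_sum_to_one(self, clean_sequence_trials):
        for tc in clean_sequence_trials[:10]:
            np.testing.assert_allclose(tc.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_forward_window_monotone_in_position(self, clean_sequence_trials):
        # with zero noise, earlier items dominate early TRs: at the first
        # TR inside the response, probabilities decrease with position
        for tc in by_isi(clean_sequence_trials, 2.048)[:5]:
            row = tc.probabilities[2]  # TR 3, well inside the forward period
            by_pos = row[list(tc.order)]
            assert np.all(np.diff(by_pos) <= 1e-12)

    def test_unknown_condition_rejected(self, response_params):
        sched = make_sequence_schedule(seed=0).copy()
        sched.loc[:, "condition"] = "mystery"
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_probabilities(sched, response_params)

    def test_slow_trials_windowed_per_event(self, response_params):
        sched = make_slow_schedule(seed=0).head(25)
        tcs = simulate_probabilities(sched, response_params, sharpening=1.0)
        assert len(tcs) == 25
        assert all(tc.n_trs == 7 for tc in tcs)

    def test_noise_seeded_reproducibly(self, response_params):
        sched = make_sequence_schedule(seed=0).head(50)
        a = simulate_probabilities(sched, response_params, noise_sd=0.05, seed=9)
        b = simulate_probabilities(sched, response_params, noise_sd=0.05, seed=9)
        np.testing.assert_array_equal(a[0].probabilities, b[0].probabilities)


class TestSimulateVoxels:
    def test_templates_negatively_correlated(self):
        T = class_templates(VoxelPatternSpec(n_voxels=80, seed=2))
        gram = T @ T.T
        off = gram[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, -0.25, atol=1e-9)

    def test_peak_volume_matches_shown_class(self, response_params):
        sched = make_slow_schedule(seed=0)
        sched = sched[sched.run_id == 0].head(20)
        runs, T = simulate_voxels(sched, VoxelPatternSpec(n_voxels=40, noise_sd=0.0), response_params)
        run = runs[0]
        for _, ev in run.events.iterrows():
            vol = int(round((ev.onset + 4.0) / 1.25))
            sims = T @ run.data[vol]
            assert int(np.argmax(sims)) == int(ev.item_class)

    def test_seeded_determinism(self, response_params):
        sched = make_slow_schedule(seed=0)
        sched = sched[sched.run_id == 0].head(10)
        a, _ = simulate_voxels(sched, VoxelPatternSpec(n_voxels=30), response_params, seed=7)
        b, _ = simulate_voxels(sched, VoxelPatternSpec(n_voxels=30), response_params, seed=7)
        np.testing.assert_array_equal(a[0].data, b[0].data)


class TestSimulateRest:
    def test_shape_and_simplex(self):
        tc = simulate_rest(50, seed=0)
        assert tc.n_trs == 50
        assert tc.probabilities.min() >= 0
        np.testing.assert_allclose(tc.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_lower_concentration_more_dispersed(self):
        sd = {}
        for conc in (0.3, 3.0):
            sds = [np.std(simulate_rest(233, seed=i, concentration=conc).probabilities, axis=1).mean() for i in range(5)]
            sd[conc] = np.mean(sds)
        assert sd[0.3] > sd[3.0]


@pytest.fixture(scope="module")
def rest_and_trials(response_params):
    rest = simulate_rest(120, seed=5)
    sched = make_sequence_schedule(seed=5)
    trials = [
        tc.slice_trs(2, 13)
        for tc in simulate_probabilities(sched, response_params)
        if abs(tc.speed.isi_seconds - 0.032) < 1e-9
    ]
    return rest, trials


class TestInsertEvents:
    def test_kappa_one_copies_trial_rows(self, rest_and_trials):
        rest, trials = rest_and_trials
        res = insert_events(rest, trials, BlendSpec(kappa=1.0, n_inserts=3), seed=0)
        s, e = res.segments[0]
        trial = trials[res.trial_indices[0]]
        np.testing.assert_allclose(res.timecourse.probabilities[s:e], trial.probabilities[:12])

    def test_kappa_zero_keeps_simplex_and_rest_statistics(self, rest_and_trials):
        rest, trials = rest_and_trials
        res = insert_events(rest, trials, BlendSpec(kappa=0.0, n_inserts=3), seed=0)
        # every inserted row is some rest row (donor sampling)
        rest_rows = {tuple(np.round(r, 12)) for r in rest.probabilities}
        for s, e in res.segments:
            for row in res.timecourse.probabilities[s:e]:
                assert tuple(np.round(row, 12)) in rest_rows

    def test_rows_remain_on_simplex(self, rest_and_trials):
        rest, trials = rest_and_trials
        res = insert_events(rest, trials, BlendSpec(kappa=0.5, n_inserts=4), seed=1)
        np.testing.assert_allclose(res.timecourse.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_segments_nonoverlapping(self, rest_and_trials):
        rest, trials = rest_and_trials
        res = insert_events(rest, trials, BlendSpec(kappa=0.5, n_inserts=6), seed=2)
        segs = sorted(res.segments)
        assert all(a[1] <= b[0] for a, b in zip(segs, segs[1:]))

    def test_infeasible_placement_raises(self, rest_and_trials):
        _, trials = rest_and_trials
        small_rest = simulate_rest(20, seed=0)
        with pytest.raises((ValueError, RuntimeError)):
            insert_events(small_rest, trials, BlendSpec(kappa=0.5, n_inserts=6), seed=0)
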