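"""CM-I and CM-II: fitting, prediction, vote traces, streaming."""

import numpy as np
import pytest
from sklearn.base import clone

from fallverify import (
    BEND,
    FALL,
    CheckpointVoteClassifier,
    Incident,
    NormalTimeModel,
    TotalTimeThresholdClassifier,
    checkpoint_grid,
    classify_cm1,
    classify_cm2,
    classify_cm2_stream,
    duration_models,
    fit_cm1,
    fit_cm2,
    midpoint_criterion,
    simulate_bend,
    simulate_fall,
    total_time,
)


def two_sample(ident, duration, label, h0=1.72):
    return Incident(id=ident, t=[0.0, duration], h=[h0, 0.0], label=label)


def paired_training(mu_fall, mu_bend, delta=0.2):
    """Two incidents per class whose mean total times are exactly the mus."""
    return [
        two_sample("f0", mu_fall - delta, FALL),
        two_sample("f1", mu_fall + delta, FALL),
        two_sample("b0", mu_bend - delta, BEND),
        two_sample("b1", mu_bend + delta, BEND),
    ]


class TestCM1Fit:
    @pytest.mark.parametrize(
        "mu_fall, mu_bend, expected_r",
        [(1.86, 3.14, 2.5), (1.3, 2.1, 1.7)],
    )
    def test_midpoint_criterion_from_fitted_means(self, mu_fall, mu_bend, expected_r):
        model = fit_cm1(paired_training(mu_fall, mu_bend))
        assert model.fall_model_.mu == pytest.approx(mu_fall, abs=1e-12)
        assert model.bend_model_.mu == pytest.approx(mu_bend, abs=1e-12)
        assert model.r_ == pytest.approx(expected_r, abs=1e-12)

    def test_midpoint_of_equal_means(self):
        assert midpoint_criterion(2.0, 2.0) == 2.0

    def test_missing_class_names_it(self):
        falls_only = [two_sample(f"f{i}", 1.8 + 0.1 * i, FALL) for i in range(3)]
        with pytest.raises(ValueError, match=BEND):
            fit_cm1(falls_only)

    def test_prespecified_models_bypass_estimation(self):
        fall, bend = duration_models("text")
        model = TotalTimeThresholdClassifier(fall_model=fall, bend_model=bend)
        model.fit([])
        assert model.r_ == pytest.approx(2.5)

    def test_prespecified_models_require_mean_ordering(self):
        fall, bend = duration_models("text")
        with pytest.raises(ValueError, match="mu"):
            TotalTimeThresholdClassifier(fall_model=bend, bend_model=fall).fit([])


class TestCM1Predict:
    @pytest.fixture()
    def model(self):
        return fit_cm1(paired_training(1.86, 3.14))  # r = 2.5

    @pytest.mark.parametrize(
        "duration, expected",
        [(2.0, FALL), (3.0, BEND), (2.5, BEND)],  # boundary t == r -> BEND
    )
    def test_threshold_rule(self, model, duration, expected):
        assert classify_cm1(model, two_sample("x", duration, None)) == expected

    def test_monotone_in_total_time(self, model):
        """Lowering total time never flips FALL -> BEND."""
        durations = np.linspace(1.0, 4.0, 61)
        labels = [
            classify_cm1(model, two_sample("x", float(d), None)) for d in durations
        ]
        flips = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert len(flips) == 1 and labels[0] == FALL and labels[-1] == BEND


class TestCM2Fit:
    def test_identical_trajectories_give_their_crossing_times(self):
        t = np.linspace(0, 2.0, 61)
        h = 1.72 * (1 - t / 2.0)
        falls = [Incident(id=f"f{i}", t=t, h=h, label=FALL) for i in range(2)]
        bends = [simulate_bend(1.72, 3.0 + 0.2 * i, incident_id=f"b{i}")
                 for i in range(2)]
        model = fit_cm2(falls + bends, k=10)
        from fallverify import checkpoint_times
        expected = checkpoint_times(falls[0], model.checkpoints_).times
        assert model.t_fall_ref_ == pytest.approx(expected)

    def test_reference_vectors_increase_and_order_below_crossover(self):
        """On noise-free defaults the fall reference crosses below the bend
        reference only beneath h ~ 0.23 h0 (the free-fall shape starts at
        rest, the lean-over starts fast), and both vectors increase."""
        data = [simulate_fall(1.72, 1.86, incident_id=f"f{i}") for i in range(2)]
        data += [simulate_bend(1.72, 3.14, incident_id=f"b{i}") for i in range(2)]
        model = fit_cm2(data, k=20)
        assert np.all(np.diff(model.t_fall_ref_) > 0)
        assert np.all(np.diff(model.t_bend_ref_) > 0)
        low = model.checkpoints_ < 0.22 * 1.72
        assert np.all(model.t_fall_ref_[low] < model.t_bend_ref_[low])
        high = model.checkpoints_ > 0.25 * 1.72
        high &= model.checkpoints_ < 1.71  # skip the shared t=0 start
        assert np.all(model.t_fall_ref_[high] > model.t_bend_ref_[high])

    def test_final_reference_entries_are_class_mean_durations(self):
        """At the floor checkpoint the references equal the class mean
        total times; with 400 simulated incidents per class they sit within
        3 SE of the configured 1.86 s and 3.14 s."""
        from fallverify import SimulationConfig, generate_dataset

        data = generate_dataset(SimulationConfig(n_fall=400, n_bend=400, seed=5))
        model = fit_cm2(data, k=20)
        for ref, label, mu in (
            (model.t_fall_ref_, FALL, 1.86),
            (model.t_bend_ref_, BEND, 3.14),
        ):
            totals = np.array([total_time(i) for i in data if i.label == label])
            se = totals.std(ddof=1) / np.sqrt(len(totals))
            assert ref[-1] == pytest.approx(totals.mean(), abs=1e-9)
            assert abs(ref[-1] - mu) < 3 * se

    def test_k_below_two_rejected(self):
        data = paired_training(1.86, 3.14)
        with pytest.raises(ValueError, match="checkpoints"):
            fit_cm2(data, k=1)


def handmade_cm2(checkpoints, t_fall, t_bend):
    model = CheckpointVoteClassifier(n_checkpoints=len(checkpoints))
    model.checkpoints_ = np.asarray(checkpoints, float)
    model.t_fall_ref_ = np.asarray(t_fall, float)
    model.t_bend_ref_ = np.asarray(t_bend, float)
    model.classes_ = np.array([BEND, FALL])
    return model


class TestCM2Predict:
    def test_hand_enumerated_three_checkpoint_vote(self):
        """K=3 worked example: distances (0.1,0.4), (0.4,0.6), (1.4,0.1)
        give votes FALL, FALL, BEND and a FALL majority."""
        model = handmade_cm2([1.0, 0.5, 0.0], [0.5, 1.0, 1.5], [1.0, 2.0, 3.0])
        inc = Incident(id="x", t=[0.0, 0.6, 1.4, 2.9], h=[1.2, 1.0, 0.5, 0.0])
        label, trace = classify_cm2(model, inc)
        assert [r.vote for r in trace.records] == [FALL, FALL, BEND]
        assert (trace.fall_count, trace.bend_count) == (2, 1)
        assert label == FALL

    def test_zero_distance_to_fall_reference_sweeps_votes(self):
        grid = [1.0, 0.5, 0.0]
        t_fall = [0.2, 0.6, 1.0]
        model = handmade_cm2(grid, t_fall, [0.4, 1.2, 2.0])
        # piecewise-linear incident crossing exactly at the fall reference
        inc = Incident(id="x", t=[0.0, 0.2, 0.6, 1.0], h=[1.2, 1.0, 0.5, 0.0])
        label, trace = classify_cm2(model, inc)
        assert [r.vote for r in trace.records] == [FALL, FALL, FALL]
        assert label == FALL

    def test_all_ties_resolve_to_bend(self):
        """An incident exactly midway between the references everywhere
        draws every per-checkpoint tie, and ties resolve to BEND."""
        # dyadic times so the distance ties are exact in floating point
        model = handmade_cm2([1.0, 0.5, 0.0], [0.25, 0.75, 1.25], [0.75, 1.25, 1.75])
        inc = Incident(id="x", t=[0.0, 0.5, 1.0, 1.5], h=[1.25, 1.0, 0.5, 0.0])
        label, trace = classify_cm2(model, inc)
        assert [r.vote for r in trace.records] == [BEND, BEND, BEND]
        assert label == BEND

    def test_vote_counts_partition_checkpoints(self, dataset86):
        model = fit_cm2(dataset86)
        for trace in model.predict_trace(dataset86[:10]):
            assert trace.fall_count + trace.bend_count == len(model.checkpoints_)
            assert trace.decision in (FALL, BEND)

    def test_separates_classes_with_overlapping_durations(self):
        """The shape contrast (accelerating vs decelerating) classifies
        correctly even when both classes share the same total duration."""
        train = [simulate_fall(1.72, d, incident_id=f"f{i}")
                 for i, d in enumerate((2.2, 2.6))]
        train += [simulate_bend(1.72, d, incident_id=f"b{i}")
                  for i, d in enumerate((2.2, 2.6))]
        model = fit_cm2(train, k=20)
        probe_fall = simulate_fall(1.72, 2.4)
        probe_bend = simulate_bend(1.72, 2.4)
        assert classify_cm2(model, probe_fall)[0] == FALL
        assert classify_cm2(model, probe_bend)[0] == BEND


class TestCM2Stream:
    def test_stream_equals_batch_on_generated_incidents(self, dataset86):
        model = fit_cm2(dataset86)
        for inc in dataset86[::9]:
            final = None
            for state in classify_cm2_stream(model, zip(inc.t, inc.h)):
                final = state
            batch = classify_cm2(model, inc)[1]
            assert final.decision == batch.decision
            assert [(r.j, r.vote) for r in final.records] == [
                (r.j, r.vote) for r in batch.records
            ]
            assert [r.t_incident for r in final.records] == pytest.approx(
                [r.t_incident for r in batch.records]
            )

    def test_truncated_stream_is_undecided(self, dataset86):
        model = fit_cm2(dataset86)
        inc = dataset86[0]
        cut = len(inc.t) // 2
        final = None
        for state in classify_cm2_stream(model, zip(inc.t[:cut], inc.h[:cut])):
            final = state
        assert final.decision is None
        assert 0 < final.n_evaluated < len(model.checkpoints_)

    def test_out_of_order_samples_rejected(self, dataset86):
        model = fit_cm2(dataset86)
        voter = model.stream()
        voter.update(0.0, 1.72)
        with pytest.raises(Exception, match="out-of-order"):
            voter.update(0.0, 1.5)

    def test_fall_majority_by_half_height(self):
        """A noise-free default fall already holds a FALL majority among
        the checkpoints crossed by half height."""
        train = [simulate_fall(1.72, d, incident_id=f"f{i}")
                 for i, d in enumerate((1.7, 2.0))]
        train += [simulate_bend(1.72, d, incident_id=f"b{i}")
                  for i, d in enumerate((3.0, 3.3))]
        model = fit_cm2(train, k=20)
        inc = simulate_fall(1.72, 1.86)
        final = None
        for state in classify_cm2_stream(model, zip(inc.t, inc.h)):
            final = state
        upper = [r for r in final.records if r.height >= 0.86]
        falls = sum(r.vote == FALL for r in upper)
        assert falls > len(upper) - falls


class TestSklearnCompat:
    def test_clone_and_params_roundtrip(self):
        model = CheckpointVoteClassifier(n_checkpoints=12)
        assert clone(model).get_params()["n_checkpoints"] == 12
        cm1 = TotalTimeThresholdClassifier()
        assert set(cm1.get_params()) == {"fall_model", "bend_model"}

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            CheckpointVoteClassifier().predict([])
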