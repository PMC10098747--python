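import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teamstate.errors import ConfigurationError, ValidationError
from teamstate.evaluation import (
    SweepConfig,
    TrialResult,
    confusion,
    run_sweep,
    split_sessions,
    state_progression,
    summarize_sweep,
)
from teamstate.selftrain import SelfTrainConfig, fit_base_classifier
from teamstate.simulate import SimulationConfig, make_study
from teamstate.states import BehaviorState, Session

E, W, S = (int(s) for s in BehaviorState)


class TestSplitSessions:
    def test_disjoint_cover_of_all_sessions(self, study6):
        train, test = split_sessions(study6, seed=7)
        assert len(train.session_ids) == 4 and len(test.session_ids) == 2
        assert set(train.session_ids) | set(test.session_ids) == {
            s.session_id for s in study6
        }
        assert set(train.session_ids).isdisjoint(test.session_ids)

    def test_both_participants_stay_on_same_side(self, study6):
        train, test = split_sessions(study6, seed=7)
        by_id = {s.session_id: s for s in study6}
        assert len(train.labels) == sum(by_id[i].n_rows for i in train.session_ids)
        assert len(test.labels) == sum(by_id[i].n_rows for i in test.session_ids)

    def test_one_one_split_of_two_sessions(self, tiny_study):
        train, test = split_sessions(tiny_study, train_sessions=1, test_sessions=1)
        assert len(train.session_ids) == len(test.session_ids) == 1

    def test_same_seed_same_split(self, study6):
        a = split_sessions(study6, seed=13)
        b = split_sessions(study6, seed=13)
        assert a[0].session_ids == b[0].session_ids
        assert a[1].session_ids == b[1].session_ids

    def test_insufficient_sessions_rejected(self, tiny_study):
        with pytest.raises(ValidationError, match="sessions"):
            split_sessions(tiny_study, train_sessions=4, test_sessions=2)


class TestConfusion:
    def test_identical_tracks_diagonal(self):
        C = confusion([E, W, W, S], [E, W, W, S])
        assert np.array_equal(C, np.diag([1, 2, 1]))

    def test_single_off_diagonal_count(self):
        C = confusion([W, W, S], [W, S, S])
        expected = np.zeros((3, 3), dtype=int)
        expected[W, W] = 1
        expected[W, S] = 1
        expected[S, S] = 1
        assert np.array_equal(C, expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.sampled_from([E, W, S]), min_size=1, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    def test_conservation(self, truth, seed):
        pred = np.random.default_rng(seed).choice([E, W, S], size=len(truth))
        C = confusion(truth, pred)
        assert C.sum() == len(truth)
        assert np.array_equal(C.sum(axis=1), np.bincount(truth, minlength=3))
        assert np.array_equal(C.sum(axis=0), np.bincount(pred, minlength=3))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValidationError):
            confusion([E], [E, W])
        with pytest.raises(ValidationError):
            confusion([], [])


def _trial(fraction, train_acc, test_acc, trial_id=0):
    C = np.diag([1, 1, 1])
    return TrialResult(
        trial_id=trial_id,
        label_fraction=fraction,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        confusion_train=C,
        confusion_test=C,
        n_pseudolabels=0,
        labeled_subset_class_counts=(1, 1, 1),
    )


class TestSummarizeSweep:
    def test_all_high_trials(self):
        out = summarize_sweep([_trial(0.1, 0.9, 0.9, i) for i in range(4)])
        row = out.loc[0.1]
        assert row["share_high_test"] == 1.0
        assert row["share_low_test"] == 0.0
        assert row["mean_test_accuracy"] == pytest.approx(0.9)

    def test_band_arithmetic(self):
        out = summarize_sweep([_trial(0.1, 0.6, 0.6), _trial(0.1, 0.85, 0.85, 1)])
        row = out.loc[0.1]
        assert row["share_high_test"] == 0.5
        assert row["share_low_test"] == 0.5
        assert row["median_train_accuracy"] == pytest.approx(0.725)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            summarize_sweep([])


@pytest.fixture(scope="module")
def mini_sweep_study():
    return make_study(SimulationConfig(n_sessions=3, steps_per_session=60, seed=17))


class TestRunSweep:
    def test_sweep_reproducible_bitwise(self, mini_sweep_study):
        cfg = SweepConfig(
            label_fractions=(0.2,),
            n_trials=2,
            train_sessions=2,
            test_sessions=1,
            seed=3,
        )
        r1 = run_sweep(mini_sweep_study, cfg)
        r2 = run_sweep(mini_sweep_study, cfg)
        assert [t.to_record() for t in r1] == [t.to_record() for t in r2]

    def test_trial_result_conservation(self, mini_sweep_study):
        cfg = SweepConfig(
            label_fractions=(0.2,),
            n_trials=1,
            train_sessions=2,
            test_sessions=1,
            seed=3,
        )
        (t,) = run_sweep(mini_sweep_study, cfg)
        n_train_rows = sum(s.n_rows for s in mini_sweep_study) - t.confusion_test.sum()
        n_labeled = sum(t.labeled_subset_class_counts)
        # train confusion covers training rows minus the supplied subset
        assert t.confusion_train.sum() == n_train_rows - n_labeled
        assert 0.0 <= t.train_accuracy <= 1.0
        assert 0.0 <= t.test_accuracy <= 1.0

    def test_infeasible_fraction_rejected(self, mini_sweep_study):
        cfg = SweepConfig(
            label_fractions=(0.001,),
            n_trials=1,
            train_sessions=2,
            test_sessions=1,
        )
        with pytest.raises(ConfigurationError, match="no labeled rows"):
            run_sweep(mini_sweep_study, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SweepConfig(label_fractions=(0.0,)).validate()
        with pytest.raises(ConfigurationError):
            SweepConfig(high_band=0.6, low_band=0.7).validate()


class TestStateProgression:
    def test_constant_session_perfect_model_flat_tracks(self):
        X = np.tile([1, 1, 1, 1, 0, 1, 0], (20, 1))
        y = np.full(20, E)
        # model fitted on separable engaged/waiting rows predicts the
        # engaged rows perfectly
        X_fit = np.vstack([X[:5], np.zeros((5, 7))])
        y_fit = np.array([E] * 5 + [W] * 5)
        model = fit_base_classifier(X_fit, y_fit, SelfTrainConfig(seed=0))
        session = Session("s0", "pc", X, X, labels_a=y, labels_b=y)
        prog = state_progression(session, model, "a")
        assert np.array_equal(prog.true_states, prog.predicted_states)
        assert prog.n_switches("true") == prog.n_switches("predicted") == 0

    def test_unlabeled_session_rejected(self, study6):
        s = study6[0]
        bare = Session("x", "pc", s.features_a, s.features_b)
        model = fit_base_classifier(
            s.features_a[:50], s.labels_a[:50], SelfTrainConfig(seed=0)
        )
        with pytest.raises(ValidationError, match="no labels"):
            state_progression(bare, model, "a")

    def test_empty_session_rejected(self):
        bare = Session(
            "x", "pc", np.empty((0, 7)), np.empty((0, 7)),
            labels_a=np.empty(0, dtype=int), labels_b=np.empty(0, dtype=int),
        )
        with pytest.raises(ValidationError, match="empty"):
            state_progression(bare, model=None, participant="a")

    def test_frame_export(self, study6):
        s = study6[0]
        model = fit_base_classifier(
            s.features_a[:80], s.labels_a[:80], SelfTrainConfig(seed=0)
        )
        prog = state_progression(s, model, "b")
        df = prog.to_frame()
        assert list(df.columns) == ["timestep", "true_state", "predicted_state"]
        assert len(df) == s.timesteps
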