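import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teamstate.errors import ValidationError
from teamstate.selftrain import (
    PartiallyLabeledDataset,
    PseudoLabel,
    SelfTrainConfig,
    fit_base_classifier,
    fit_platt,
    platt_sigmoid,
    posterior,
    select_pseudolabels,
    self_train,
    tiebreak_argmax,
)
from teamstate.states import UNLABELED, BehaviorState

E, W, S = (int(s) for s in BehaviorState)


def two_cluster_toy():
    """Two well-separated clusters in the 7-flag feature space."""
    engaged = np.tile([1, 1, 1, 1, 0, 1, 0], (6, 1))
    waiting = np.tile([0, 0, 0, 0, 0, 0, 0], (6, 1))
    X = np.vstack([engaged, waiting]).astype(float)
    y = np.array([E] * 6 + [W] * 6)
    return X, y


class TestPlattSigmoid:
    def test_origin_gives_half(self):
        assert platt_sigmoid(0.0, A=0.0, B=0.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        # s=1, A=-2, B=0 -> 1 / (1 + e^{-2})
        assert platt_sigmoid(1.0, A=-2.0, B=0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0))
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-500, max_value=500))
    def test_stable_and_bounded_everywhere(self, s):
        p = float(platt_sigmoid(s, A=-3.0, B=1.0))
        assert 0.0 <= p <= 1.0 and np.isfinite(p)

    def test_fit_recovers_known_sigmoid(self, rng):
        """Labels drawn from a known calibration curve: the fitted
        (A, B) reproduce the generating probabilities."""
        scores = rng.normal(size=4000)
        p_true = platt_sigmoid(scores, A=-2.0, B=0.5)
        labels = rng.random(4000) < p_true
        cal = fit_platt(scores, labels)
        p_hat = cal.probability(scores)
        assert np.max(np.abs(p_hat - p_true)) < 0.05

    def test_fit_requires_both_classes(self):
        with pytest.raises(ValidationError):
            fit_platt(np.array([1.0, 2.0]), np.array([True, True]))


class TestTiebreakArgmax:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ((0.2, 0.5, 0.3), BehaviorState.WAITING),
            ((0.4, 0.4, 0.2), BehaviorState.WAITING),  # exact tie -> waiting
            ((1.0, 0.0, 0.0), BehaviorState.ENGAGED),
            ((0.45, 0.1, 0.45), BehaviorState.STRUGGLING),  # tie without waiting
        ],
    )
    def test_examples(self, vec, expected):
        assert tiebreak_argmax(vec) is expected


class TestSelectPseudolabels:
    def test_strictly_above_threshold_included(self):
        out = select_pseudolabels([(0, W, 0.51)], threshold=0.5)
        assert len(out) == 1 and out[0].confidence == pytest.approx(0.51)

    def test_exactly_at_threshold_excluded(self):
        assert select_pseudolabels([(0, W, 0.50)], threshold=0.5) == []

    def test_empty_in_empty_out(self):
        assert select_pseudolabels([], threshold=0.5) == []

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 100),
                st.sampled_from([E, W, S]),
                st.floats(0.001, 1.0),
            ),
            max_size=20,
        )
    )
    def test_selection_is_exactly_the_strict_filter(self, preds):
        out = select_pseudolabels(preds, threshold=0.5, iteration=3)
        expected = [p for p in preds if p[2] > 0.5]
        assert [(o.row_index, int(o.state), o.confidence) for o in out] == expected
        assert all(o.iteration == 3 for o in out)

    def test_confidence_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            select_pseudolabels([(0, W, 1.5)], threshold=0.5)


class TestPseudoLabelInvariants:
    def test_confidence_and_iteration_bounds(self):
        with pytest.raises(ValidationError):
            PseudoLabel(0, BehaviorState.WAITING, confidence=0.0, iteration=1)
        with pytest.raises(ValidationError):
            PseudoLabel(0, BehaviorState.WAITING, confidence=0.9, iteration=0)


class TestFitBaseClassifier:
    def test_separable_clusters_reach_training_accuracy_one(self):
        X, y = two_cluster_toy()
        model = fit_base_classifier(X, y, SelfTrainConfig(seed=0))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_identical_rows_posterior_matches_class_frequencies(self):
        """All rows identical with a 2:1 label mix: the calibrated
        posterior approximates the empirical class frequencies (the
        closed-form majority baseline)."""
        X = np.ones((12, 7))
        y = np.array([W] * 8 + [S] * 4)
        model = fit_base_classifier(X, y, SelfTrainConfig(seed=0))
        p = posterior(model, X[0])
        assert p[W] == pytest.approx(8 / 12, abs=0.10)
        assert p[S] == pytest.approx(4 / 12, abs=0.10)

    def test_refit_same_seed_identical_predictions(self, split42):
        train, _ = split42
        X, y = train.features[:300], train.labels[:300]
        probe = train.features[300:400]
        m1 = fit_base_classifier(X, y, SelfTrainConfig(seed=4))
        m2 = fit_base_classifier(X, y, SelfTrainConfig(seed=4))
        assert np.array_equal(m1.predict(probe), m2.predict(probe))
        assert m1.hyperparams == m2.hyperparams

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            fit_base_classifier(np.empty((0, 7)), [], SelfTrainConfig())

    def test_single_class_degenerates_to_constant_predictor(self, caplog):
        X = np.random.default_rng(0).integers(0, 2, size=(10, 7)).astype(float)
        with caplog.at_level(logging.WARNING):
            model = fit_base_classifier(X, [W] * 10, SelfTrainConfig(seed=0))
        assert "single class" in caplog.text
        assert (model.predict(X) == W).all()
        assert posterior(model, X[0])[W] == 1.0

    def test_posterior_sums_to_one(self, split42):
        train, _ = split42
        model = fit_base_classifier(
            train.features[:200], train.labels[:200], SelfTrainConfig(seed=1)
        )
        P = model.posterior_matrix(train.features[200:500])
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9
        assert (P >= 0).all()


class TestPartiallyLabeledDataset:
    def test_ground_truth_positions_frozen(self):
        ds = PartiallyLabeledDataset(np.zeros((3, 7)), [W, UNLABELED, UNLABELED])
        with pytest.raises(ValidationError, match="ground-truth"):
            ds.add_pseudolabels([PseudoLabel(0, BehaviorState.STRUGGLING, 0.9, 1)])

    def test_double_pseudolabeling_rejected(self):
        ds = PartiallyLabeledDataset(np.zeros((3, 7)), [W, UNLABELED, UNLABELED])
        ds.add_pseudolabels([PseudoLabel(1, BehaviorState.WAITING, 0.9, 1)])
        with pytest.raises(ValidationError, match="already"):
            ds.add_pseudolabels([PseudoLabel(1, BehaviorState.WAITING, 0.8, 2)])

    def test_invalid_label_code_rejected(self):
        with pytest.raises(ValidationError, match="invalid label"):
            PartiallyLabeledDataset(np.zeros((2, 7)), [W, 7])


class TestSelfTrain:
    def test_requires_some_ground_truth(self):
        ds = PartiallyLabeledDataset(np.zeros((4, 7)), [UNLABELED] * 4)
        with pytest.raises(ValidationError, match="ground-truth"):
            self_train(ds, SelfTrainConfig())

    def test_fully_labeled_equals_supervised_fit(self, split42):
        train, test = split42
        X, y = train.features[:400], train.labels[:400]
        cfg = SelfTrainConfig(seed=6)
        ds = PartiallyLabeledDataset(X, y)
        result = self_train(ds, cfg)
        supervised = fit_base_classifier(X, y, cfg)
        probe = test.features[:300]
        assert result.ledger == []
        assert np.array_equal(result.final_model.predict(probe), supervised.predict(probe))
        assert np.array_equal(result.completed_labels, y)

    def test_toy_run_matches_supervised_oracle(self):
        """12 rows, 4 labeled, clusters separated: every first-iteration
        confidence clears the gate, all 8 rows are pseudolabeled at
        iteration 1, and the final labeling equals a single supervised
        fit on the ground-truth subset (brute-force oracle)."""
        X, y = two_cluster_toy()
        labeled_idx = [0, 1, 6, 7]
        cfg = SelfTrainConfig(seed=2)
        ds = PartiallyLabeledDataset.from_labeled_subset(X, y, labeled_idx)
        result = self_train(ds, cfg)
        oracle = fit_base_classifier(X[labeled_idx], y[labeled_idx], cfg)
        expected = y.copy()
        unlabeled = np.setdiff1d(np.arange(12), labeled_idx)
        expected[unlabeled] = oracle.predict(X[unlabeled])
        assert len(result.ledger) == 8
        assert all(p.iteration == 1 for p in result.ledger)
        assert result.per_iteration_trace[0]["labeled_size"] == 12
        assert np.array_equal(result.completed_labels, expected)

    def test_no_confident_predictions_terminates_with_argmax_fill(self, split42):
        train, _ = split42
        X, y = train.features[:100], train.labels[:100]
        cfg = SelfTrainConfig(seed=3, confidence_threshold=0.999999)
        ds = PartiallyLabeledDataset.from_labeled_subset(X, y, np.arange(10))
        result = self_train(ds, cfg)
        assert result.per_iteration_trace[-1]["n_added"] == 0
        assert (result.completed_labels != UNLABELED).all()
        assert np.array_equal(result.completed_labels[:10], y[:10])

    def test_ledger_and_trace_contracts(self, split42):
        train, _ = split42
        X, y = train.features[:600], train.labels[:600]
        cfg = SelfTrainConfig(seed=9)
        ds = PartiallyLabeledDataset.from_labeled_subset(X, y, np.arange(30))
        result = self_train(ds, cfg)
        # append-only: labeled size non-decreasing, iterations sequential
        sizes = [t["labeled_size"] for t in result.per_iteration_trace]
        assert sizes == sorted(sizes)
        assert [t["iteration"] for t in result.per_iteration_trace] == list(
            range(1, len(sizes) + 1)
        )
        # every promoted confidence strictly exceeds the gate
        assert all(p.confidence > cfg.confidence_threshold for p in result.ledger)
        # ground truth never modified
        assert np.array_equal(result.completed_labels[:30], y[:30])
        # halting: either past the stop fraction or a zero-addition round
        assert (
            sizes[-1] > cfg.stop_fraction * len(y)
            or result.per_iteration_trace[-1]["n_added"] == 0
        )

    def test_determinism(self, split42):
        train, _ = split42
        X, y = train.features[:300], train.labels[:300]

        def run():
            ds = PartiallyLabeledDataset.from_labeled_subset(X, y, np.arange(20))
            return self_train(ds, SelfTrainConfig(seed=5))

        r1, r2 = run(), run()
        assert np.array_equal(r1.completed_labels, r2.completed_labels)
        assert [
            (p.row_index, int(p.state), p.confidence, p.iteration) for p in r1.ledger
        ] == [(p.row_index, int(p.state), p.confidence, p.iteration) for p in r2.ledger]
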