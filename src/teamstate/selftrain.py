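"""Semi-supervised self-training with confidence-gated pseudolabeling.

The algorithm wraps a Gaussian-kernel SVM: starting from a small
randomly supplied set of ground-truth labels, it repeatedly

1. fits the SVM on the currently labeled rows,
2. predicts every still-unlabeled row together with a calibrated
   posterior probability (one Platt sigmoid per one-vs-rest
   subproblem, ``P(s) = 1 / (1 + exp(A s + B))``, normalized across
   classes),
3. promotes predictions whose confidence *strictly* exceeds the gate
   (default 50%, strict so that no two classes can be equally probable)
   to pseudolabels,

until more than half of all rows are labeled, an iteration adds no
pseudolabels, or a safety cap is reached. Rows still unlabeled at
termination receive the final model's highest-posterior state
regardless of confidence. Pseudolabels are append-only and never
revised; ground-truth labels are never modified.

Hyperparameters (kernel width and box constraint) are chosen by a small
cross-validated grid search on the initially labeled subset at the
first fit and reused for the rest of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import ConfigurationError, NotFittedError, ValidationError
from .states import N_STATES, UNLABELED, BehaviorState

logger = logging.getLogger(__name__)


def platt_sigmoid(score, A: float, B: float):
    """Calibration sigmoid ``1 / (1 + exp(A * score + B))``."""
    z = A * np.asarray(score, dtype=float) + B
    return expit(-z)  # stable in both tails


@dataclass(frozen=True)
class PlattCalibration:
    """Slope/intercept of one binary subproblem's calibration sigmoid."""

    A: float
    B: float

    def probability(self, score):
        return platt_sigmoid(score, self.A, self.B)


def fit_platt(scores: np.ndarray, is_positive: np.ndarray) -> PlattCalibration:
    """Maximum-likelihood fit of the calibration sigmoid.

    Uses Platt's smoothed targets ``(n+ + 1)/(n+ + 2)`` and
    ``1/(n- + 2)`` to keep the fit finite on separable data, and a
    quasi-Newton minimization of the (stable) cross-entropy.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = len(is_positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("calibration needs both positive and negative examples")
    t = np.where(is_positive, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(ab):
        z = ab[0] * scores + ab[1]
        # cross-entropy of P = sigmoid(-z): sum t*z + log(1 + exp(-z))
        obj = float(np.sum(t * z + np.logaddexp(0.0, -z)))
        p = platt_sigmoid(scores, ab[0], ab[1])
        grad = np.array([np.sum(scores * (t - p)), np.sum(t - p)])
        return obj, grad

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
    return PlattCalibration(A=float(res.x[0]), B=float(res.x[1]))


@dataclass(frozen=True)
class PseudoLabel:
    """One promoted prediction, recorded in the run ledger."""

    row_index: int
    state: BehaviorState
    confidence: float
    iteration: int

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence <= 1.0:
            raise ValidationError("pseudolabel confidence must lie in (0, 1]")
        if self.iteration < 1:
            raise ValidationError("pseudolabel iteration counts from 1")


@dataclass
class SelfTrainConfig:
    """Knobs of the self-training loop.

    ``confidence_threshold`` is a strict lower bound on the promoted
    posterior; ``stop_fraction`` is the share of all rows that must be
    labeled before the loop stops. The grids drive the one-shot
    hyperparameter search (3-fold cross-validation on the labeled
    subset).
    """

    confidence_threshold: float = 0.5
    stop_fraction: float = 0.5
    max_iterations: int = 100
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.1, 0.3, 1.0)
    cv_folds: int = 3
    seed: int = 0

    def validate(self) -> "SelfTrainConfig":
        if not 0.0 <= self.confidence_threshold < 1.0:
            raise ConfigurationError("confidence_threshold must lie in [0, 1)")
        if not 0.0 < self.stop_fraction <= 1.0:
            raise ConfigurationError("stop_fraction must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        return self


class PartiallyLabeledDataset:
    """Pooled feature rows with a frozen ground-truth subset and a ledger.

    ``labels`` holds state codes with :data:`~teamstate.states.UNLABELED`
    (-1) for rows awaiting labels. Positions labeled at construction are
    frozen (``ground_truth_mask``); pseudolabels may only ever fill
    positions that are unlabeled when added, and the ledger of additions
    is append-only.
    """

    def __init__(self, features: np.ndarray, labels: Sequence[int]):
        self.features = np.asarray(features)
        self.labels = np.asarray(labels, dtype=np.int64).copy()
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError("features and labels differ in length")
        valid = np.isin(self.labels, [UNLABELED, *range(N_STATES)])
        if not valid.all():
            raise ValidationError(f"invalid label code at row {int(np.argmax(~valid))}")
        self.ground_truth_mask = self.labels != UNLABELED
        self.pseudolabel_ledger: list[PseudoLabel] = []

    @classmethod
    def from_labeled_subset(
        cls, features: np.ndarray, full_labels: Sequence[int], labeled_indices: Sequence[int]
    ) -> "PartiallyLabeledDataset":
        """Withhold all labels except those at ``labeled_indices``."""
        labels = np.full(len(full_labels), UNLABELED, dtype=np.int64)
        idx = np.asarray(labeled_indices, dtype=int)
        labels[idx] = np.asarray(full_labels)[idx]
        return cls(features, labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels != UNLABELED))

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == UNLABELED)

    def add_pseudolabels(self, entries: Sequence[PseudoLabel]) -> None:
        for e in entries:
            if self.ground_truth_mask[e.row_index]:
                raise ValidationError(
                    f"row {e.row_index} carries a ground-truth label and cannot be pseudolabeled"
                )
            if self.labels[e.row_index] != UNLABELED:
                raise ValidationError(f"row {e.row_index} is already pseudolabeled")
            self.labels[e.row_index] = int(e.state)
            self.pseudolabel_ledger.append(e)


class ClassifierModel:
    """Gaussian-kernel SVM with one Platt-calibrated sigmoid per class.

    One binary SVM is fitted per class present in training
    (one-vs-rest); each decision function gets its own calibration
    sigmoid, and the per-class sigmoid outputs are normalized into a
    posterior over the three behavior states. Classes absent from
    training receive posterior 0.
    """

    def __init__(self, C: float, gamma: float):
        self.C = C
        self.gamma = gamma
        self.classes_present: list[int] = []
        self._svms: dict[int, SVC] = {}
        self._calibrations: dict[int, PlattCalibration] = {}
        self._constant_class: Optional[int] = None
        self._fitted = False

    @property
    def hyperparams(self) -> tuple[float, float]:
        return (self.C, self.gamma)

    @property
    def calibration(self) -> dict[int, PlattCalibration]:
        return dict(self._calibrations)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValidationError("cannot fit a classifier on an empty labeled set")
        self.classes_present = sorted(int(c) for c in np.unique(y))
        if len(self.classes_present) == 1:
            self._constant_class = self.classes_present[0]
            logger.warning(
                "labeled set contains a single class (%s); using a constant predictor",
                BehaviorState(self._constant_class).label,
            )
            self._fitted = True
            return self
        for k in self.classes_present:
            y_bin = (y == k).astype(int)
            svm = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
            svm.fit(X, y_bin)
            scores = svm.decision_function(X)
            self._svms[k] = svm
            self._calibrations[k] = fit_platt(scores, y_bin.astype(bool))
        self._fitted = True
        return self

    def posterior_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) calibrated posterior; rows sum to 1."""
        if not self._fitted:
            raise NotFittedError("model has not been fitted")
        X = np.asarray(X, dtype=float)
        P = np.zeros((len(X), N_STATES))
        if self._constant_class is not None:
            P[:, self._constant_class] = 1.0
            return P
        for k in self.classes_present:
            scores = self._svms[k].decision_function(X)
            P[:, k] = self._calibrations[k].probability(scores)
        totals = P.sum(axis=1, keepdims=True)
        degenerate = totals[:, 0] <= 0.0
        if degenerate.any():  # all sigmoids saturated at 0: fall back to uniform
            for k in self.classes_present:
                P[degenerate, k] = 1.0 / len(self.classes_present)
            totals = P.sum(axis=1, keepdims=True)
        return P / totals

    def posterior_vector(self, row: Sequence[float]) -> np.ndarray:
        return self.posterior_matrix(np.asarray(row, dtype=float)[None, :])[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self.posterior_matrix(X)
        return np.array([int(tiebreak_argmax(p)) for p in P], dtype=np.int64)


def posterior(model: ClassifierModel, row: Sequence[float]) -> np.ndarray:
    """Posterior probability vector over the three states for one row."""
    return model.posterior_vector(row)


#: tie preference: an uncertain system should default to not intervening
_TIE_PREFERENCE = (BehaviorState.WAITING, BehaviorState.STRUGGLING, BehaviorState.ENGAGED)


def tiebreak_argmax(posterior_vec: Sequence[float]) -> BehaviorState:
    """Highest-posterior state; exact ties resolve toward WAITING.

    (Then toward STRUGGLING: when in doubt the downstream feedback
    system should prefer states in which it does not interrupt or only
    prompts, rather than celebrating engagement.)
    """
    p = np.asarray(posterior_vec, dtype=float)
    best = p.max()
    for state in _TIE_PREFERENCE:
        if p[int(state)] == best:
            return state
    raise ValidationError("posterior vector has no maximum")  # pragma: no cover


def _grid_search(X: np.ndarray, y: np.ndarray, config: SelfTrainConfig) -> tuple[float, float]:
    """Small cross-validated grid search; deterministic given the seed.

    Falls back to the middle of each grid when the labeled subset is too
    small or too imbalanced for stratified folds.
    """
    default = (config.c_grid[len(config.c_grid) // 2], config.gamma_grid[len(config.gamma_grid) // 2])
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.cv_folds or len(y) < 3 * config.cv_folds:
        return default
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    best, best_score = default, -np.inf
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            scores = cross_val_score(SVC(C=C, gamma=gamma, kernel="rbf"), X, y, cv=cv)
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best, best_score = (C, gamma), score
    return best


def fit_base_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    config: Optional[SelfTrainConfig] = None,
    hyperparams: Optional[tuple[float, float]] = None,
) -> ClassifierModel:
    """Fit the calibrated Gaussian-SVM on a labeled set.

    When ``hyperparams`` is not supplied they are chosen by the
    config's grid search (the self-training loop does this once and
    reuses the result). A single-class labeled set degenerates to a
    constant predictor with a logged warning.
    """
    config = (config or SelfTrainConfig()).validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) == 0:
        raise ValidationError("cannot fit a classifier on an empty labeled set")
    if hyperparams is None:
        if len(np.unique(y)) >= 2:
            hyperparams = _grid_search(X, y, config)
        else:
            hyperparams = (config.c_grid[0], config.gamma_grid[0])
    model = ClassifierModel(C=hyperparams[0], gamma=hyperparams[1])
    return model.fit(X, y)


def select_pseudolabels(
    predictions: Sequence[tuple[int, int, float]],
    threshold: float,
    iteration: int = 1,
) -> list[PseudoLabel]:
    """Keep exactly the predictions whose confidence strictly exceeds the gate.

    Strict inequality guarantees no promoted prediction could have had
    another class equally probable at the default 50% gate.
    """
    out = []
    for row_index, state, confidence in predictions:
        if not 0.0 <= confidence <= 1.0:
            raise ValidationError(f"confidence {confidence} outside [0, 1]")
        if confidence > threshold:
            out.append(
                PseudoLabel(
                    row_index=int(row_index),
                    state=BehaviorState(int(state)),
                    confidence=float(confidence),
                    iteration=iteration,
                )
            )
    return out


@dataclass
class SelfTrainResult:
    """Everything needed to audit or replay one self-training run."""

    final_model: ClassifierModel
    completed_labels: np.ndarray
    ledger: list[PseudoLabel]
    per_iteration_trace: list[dict]
    hyperparams: tuple[float, float]


def self_train(dataset: PartiallyLabeledDataset, config: Optional[SelfTrainConfig] = None) -> SelfTrainResult:
    """Run the self-training loop on a partially labeled dataset.

    Mutates ``dataset`` (labels fill in, ledger grows) and returns the
    result bundle. Deterministic given the dataset and ``config.seed``.
    """
    config = (config or SelfTrainConfig()).validate()
    n = len(dataset)
    if dataset.n_labeled == 0:
        raise ValidationError("self-training requires at least one ground-truth label")

    hyperparams: Optional[tuple[float, float]] = None
    trace: list[dict] = []
    iteration = 0
    while (
        dataset.n_labeled <= config.stop_fraction * n
        and iteration < config.max_iterations
        and len(dataset.unlabeled_indices) > 0
    ):
        iteration += 1
        labeled = np.flatnonzero(dataset.labels != UNLABELED)
        model = fit_base_classifier(
            dataset.features[labeled], dataset.labels[labeled], config, hyperparams
        )
        hyperparams = model.hyperparams
        unlabeled = dataset.unlabeled_indices
        P = model.posterior_matrix(dataset.features[unlabeled])
        preds = [
            (int(idx), int(tiebreak_argmax(p)), float(p.max()))
            for idx, p in zip(unlabeled, P)
        ]
        added = select_pseudolabels(preds, config.confidence_threshold, iteration)
        dataset.add_pseudolabels(added)
        trace.append(
            {"iteration": iteration, "n_added": len(added), "labeled_size": dataset.n_labeled}
        )
        logger.debug(
            "iteration %d: +%d pseudolabels (labeled %d/%d)",
            iteration,
            len(added),
            dataset.n_labeled,
            n,
        )
        if not added:
            break

    # final model on everything labeled so far; also covers the
    # degenerate all-labeled case (pure supervised fit, empty ledger)
    labeled = np.flatnonzero(dataset.labels != UNLABELED)
    final_model = fit_base_classifier(
        dataset.features[labeled], dataset.labels[labeled], config, hyperparams
    )
    completed = dataset.labels.copy()
    remaining = dataset.unlabeled_indices
    if len(remaining):
        completed[remaining] = final_model.predict(dataset.features[remaining])
    return SelfTrainResult(
        final_model=final_model,
        completed_labels=completed,
        ledger=list(dataset.pseudolabel_ledger),
        per_iteration_trace=trace,
        hyperparams=final_model.hyperparams,
    )
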