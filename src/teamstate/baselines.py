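"""Supervised and unsupervised comparators for the self-training model.

Three fully supervised models (the Gaussian-kernel SVM plus two
standard low-configuration alternates, k-nearest-neighbors and a
pruned decision tree) and an unsupervised K-means labeler whose
clusters are mapped to behavior states against the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, ValidationError
from .selftrain import (
    ClassifierModel,
    PartiallyLabeledDataset,
    SelfTrainConfig,
    fit_base_classifier,
    self_train,
)
from .states import N_STATES, BehaviorState, Session, pool_rows


class _SklearnAdapter:
    """Thin wrapper giving sklearn estimators the same predict surface."""

    def __init__(self, estimator):
        self._est = estimator

    def fit(self, X, y):
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict(self, X) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float)).astype(np.int64)


def supervised_models(
    features: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    config: Optional[SelfTrainConfig] = None,
) -> dict:
    """Fit the three supervised comparators on fully labeled rows.

    Returns ``{"svm": ..., "knn": ..., "tree": ...}``. The SVM goes
    through the same fit path (grid search + Platt calibration) as the
    self-training loop, which is what makes the label-fraction-1.0
    equivalence exact.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("supervised baselines require at least two classes")
    config = config or SelfTrainConfig(seed=seed)
    svm = fit_base_classifier(features, y, config)
    knn = _SklearnAdapter(KNeighborsClassifier(n_neighbors=5)).fit(features, y)
    tree = _SklearnAdapter(
        DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
    ).fit(features, y)
    return {"svm": svm, "knn": knn, "tree": tree}


@dataclass
class ClusterLabelMap:
    """Assignment of each cluster id to a behavior state."""

    assignment: dict[int, BehaviorState]
    mapping_method: str  # "majority" or "one_to_one"

    def to_dict(self) -> dict:
        return {
            "mapping_method": self.mapping_method,
            "assignment": {int(k): v.label for k, v in self.assignment.items()},
        }


class KMeansLabeler:
    """K-means on features with a cluster-to-state map learned from labels."""

    def __init__(self, kmeans: KMeans, label_map: ClusterLabelMap):
        self.kmeans = kmeans
        self.label_map = label_map

    def predict(self, X) -> np.ndarray:
        clusters = self.kmeans.predict(np.asarray(X, dtype=float))
        return np.array(
            [int(self.label_map.assignment[int(c)]) for c in clusters], dtype=np.int64
        )


def kmeans_labeler(
    train_features: np.ndarray,
    train_labels: Sequence[int],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    mapping: str = "majority",
) -> tuple[KMeansLabeler, ClusterLabelMap]:
    """Fit K-means on features only, then map clusters to states.

    ``mapping="majority"`` assigns each cluster the majority
    ground-truth state among its training members (several clusters may
    share a state); ``"one_to_one"`` solves the optimal assignment
    problem on the cluster-state contingency table and requires
    ``k >= number of states``.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(X, axis=0)) < k:
        raise ValidationError(f"need at least {k} distinct rows to fit {k} clusters")
    if mapping not in ("majority", "one_to_one"):
        raise ConfigurationError(f"unknown mapping method {mapping!r}")
    if mapping == "one_to_one" and k < N_STATES:
        raise ConfigurationError(
            f"one-to-one mapping needs k >= {N_STATES} clusters, got {k}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    clusters = km.fit_predict(X)

    contingency = np.zeros((k, N_STATES), dtype=int)
    for c, s in zip(clusters, y):
        contingency[c, s] += 1
    if mapping == "majority":
        assignment = {
            c: BehaviorState(int(_majority_state(contingency[c]))) for c in range(k)
        }
    else:
        rows, cols = linear_sum_assignment(-contingency[:, :N_STATES])
        assignment = {int(r): BehaviorState(int(c)) for r, c in zip(rows, cols)}
        for c in range(k):  # clusters beyond the matched ones fall back to majority
            if c not in assignment:
                assignment[c] = BehaviorState(int(_majority_state(contingency[c])))
    label_map = ClusterLabelMap(assignment=assignment, mapping_method=mapping)
    return KMeansLabeler(km, label_map), label_map


def _majority_state(counts: np.ndarray) -> int:
    """Majority state of one cluster; ties resolve by state order."""
    return int(np.argmax(counts))


def compare_methods(
    study: Sequence[Session],
    seed: int = 0,
    label_fraction: float = 0.10,
    selftrain_config: Optional[SelfTrainConfig] = None,
    train_sessions: int = 4,
    test_sessions: int = 2,
) -> dict:
    """Train and holdout accuracy for supervised SVM, K-means, and self-training.

    All three methods share one session-level split and seed protocol:
    the supervised SVM sees every training label, K-means clusters the
    training features and maps clusters against the training labels,
    and self-training starts from a random ``label_fraction`` subset of
    the training labels (mirroring the headline comparison, which used
    the 10% model).
    """
    from .evaluation import split_sessions  # local import to avoid a cycle

    if len(study) < 2:
        raise ValidationError("method comparison needs at least 2 sessions")
    rng = np.random.default_rng(seed)
    train_block, test_block = split_sessions(
        study, train_sessions=train_sessions, test_sessions=test_sessions, rng=rng
    )
    X_tr, y_tr = train_block.features, train_block.labels
    X_te, y_te = test_block.features, test_block.labels
    config = selftrain_config or SelfTrainConfig(seed=seed)

    record: dict = {"seed": seed, "label_fraction": label_fraction}

    svm = fit_base_classifier(X_tr, y_tr, config)
    record["supervised"] = {
        "train_accuracy": float(np.mean(svm.predict(X_tr) == y_tr)),
        "test_accuracy": float(np.mean(svm.predict(X_te) == y_te)),
    }

    km, _ = kmeans_labeler(X_tr, y_tr, k=N_STATES, seed=seed)
    record["kmeans"] = {
        "train_accuracy": float(np.mean(km.predict(X_tr) == y_tr)),
        "test_accuracy": float(np.mean(km.predict(X_te) == y_te)),
    }

    n_labeled = max(1, int(round(label_fraction * len(y_tr))))
    labeled_idx = rng.choice(len(y_tr), size=n_labeled, replace=False)
    dataset = PartiallyLabeledDataset.from_labeled_subset(X_tr, y_tr, labeled_idx)
    result = self_train(dataset, config)
    held_in = np.setdiff1d(np.arange(len(y_tr)), labeled_idx)
    record["selftrain"] = {
        "train_accuracy": float(
            np.mean(result.completed_labels[held_in] == y_tr[held_in])
        ),
        "test_accuracy": float(np.mean(result.final_model.predict(X_te) == y_te)),
        "n_pseudolabels": len(result.ledger),
    }
    return record
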