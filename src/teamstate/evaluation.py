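"""Label-fraction evaluation protocol.

Session-level train/test splitting (whole sessions, both participants'
rows on the same side, no test-session labels ever supplied to a
learner), many-trial accuracy sweeps over label fractions, confusion
matrices, and state-progression traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .errors import ConfigurationError, ValidationError
from .selftrain import (
    ClassifierModel,
    PartiallyLabeledDataset,
    SelfTrainConfig,
    self_train,
)
from .states import N_STATES, BehaviorState, Session, pool_rows


class RowBlock(NamedTuple):
    """Pooled rows from one side of a session split."""

    features: np.ndarray
    labels: np.ndarray
    session_index: np.ndarray  # position within the block's session list
    session_ids: tuple[str, ...]


@dataclass
class SweepConfig:
    """Protocol knobs for the label-fraction sweep.

    Defaults mirror the study protocol: fractions 2.5/5/10/25%, 500
    trials per fraction, a fixed random 4/2 session split, and accuracy
    bands at 80% (high) and 70% (low).
    """

    label_fractions: tuple[float, ...] = (0.025, 0.05, 0.10, 0.25)
    n_trials: int = 500
    train_sessions: int = 4
    test_sessions: int = 2
    high_band: float = 0.80
    low_band: float = 0.70
    seed: int = 0
    selftrain: SelfTrainConfig = field(default_factory=SelfTrainConfig)

    def validate(self) -> "SweepConfig":
        if any(not 0.0 < f <= 1.0 for f in self.label_fractions):
            raise ConfigurationError("label fractions must lie in (0, 1]")
        if not self.low_band < self.high_band:
            raise ConfigurationError("bands must satisfy low < high")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        return self


def split_sessions(
    study: Sequence[Session],
    config: Optional[SweepConfig] = None,
    *,
    train_sessions: int = 4,
    test_sessions: int = 2,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[RowBlock, RowBlock]:
    """Randomly split whole sessions into train and holdout blocks.

    The split is at session granularity only: both participants' rows
    of a session stay on the same side, and the holdout block's labels
    are returned solely for scoring — callers must never feed them to a
    learner.
    """
    if config is not None:
        train_sessions, test_sessions = config.train_sessions, config.test_sessions
        seed = config.seed
    if len(study) < train_sessions + test_sessions:
        raise ValidationError(
            f"need {train_sessions + test_sessions} sessions, got {len(study)}"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    perm = rng.permutation(len(study))
    train_ids = sorted(int(i) for i in perm[:train_sessions])
    test_ids = sorted(int(i) for i in perm[train_sessions : train_sessions + test_sessions])

    def block(ids: list[int]) -> RowBlock:
        X, y, sidx = pool_rows([study[i] for i in ids])
        return RowBlock(X, y, sidx, tuple(study[i].session_id for i in ids))

    return block(train_ids), block(test_ids)


@dataclass
class TrialResult:
    """One self-training trial at one label fraction."""

    trial_id: int
    label_fraction: float
    train_accuracy: float
    test_accuracy: float
    confusion_train: np.ndarray  # 3x3, rows = true state
    confusion_test: np.ndarray
    n_pseudolabels: int
    labeled_subset_class_counts: tuple[int, ...]

    def to_record(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "label_fraction": self.label_fraction,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "confusion_train": self.confusion_train.tolist(),
            "confusion_test": self.confusion_test.tolist(),
            "n_pseudolabels": self.n_pseudolabels,
            "labeled_subset_class_counts": list(self.labeled_subset_class_counts),
        }


def confusion(true_track: Sequence[int], predicted_track: Sequence[int]) -> np.ndarray:
    """3x3 count matrix; entry (i, j) = true state i predicted as j."""
    t = np.asarray(true_track)
    p = np.asarray(predicted_track)
    if t.shape != p.shape:
        raise ValidationError(f"track lengths differ: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValidationError("cannot build a confusion matrix from empty tracks")
    return confusion_matrix(t, p, labels=list(range(N_STATES)))


def _run_trial(
    train: RowBlock,
    test: RowBlock,
    fraction: float,
    trial_id: int,
    master_seed: int,
    fraction_index: int,
    base_config: SelfTrainConfig,
) -> TrialResult:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(fraction_index, trial_id))
    trial_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(trial_seed)
    n_rows = len(train.labels)
    n_labeled = int(round(fraction * n_rows))
    if n_labeled < 1:
        raise ConfigurationError(
            f"label fraction {fraction} yields no labeled rows on {n_rows} rows"
        )
    labeled_idx = rng.choice(n_rows, size=n_labeled, replace=False)
    dataset = PartiallyLabeledDataset.from_labeled_subset(
        train.features, train.labels, labeled_idx
    )
    cfg_dict = base_config.__dict__ | {"seed": trial_seed}
    result = self_train(dataset, SelfTrainConfig(**cfg_dict))

    held_in = np.setdiff1d(np.arange(n_rows), labeled_idx)
    train_true = train.labels[held_in]
    train_pred = result.completed_labels[held_in]
    test_pred = result.final_model.predict(test.features)
    counts = np.bincount(train.labels[labeled_idx], minlength=N_STATES)
    return TrialResult(
        trial_id=trial_id,
        label_fraction=fraction,
        train_accuracy=float(np.mean(train_pred == train_true)),
        test_accuracy=float(np.mean(test_pred == test.labels)),
        confusion_train=confusion(train_true, train_pred),
        confusion_test=confusion(test.labels, test_pred),
        n_pseudolabels=len(result.ledger),
        labeled_subset_class_counts=tuple(int(c) for c in counts),
    )


def run_sweep(study: Sequence[Session], sweep: Optional[SweepConfig] = None) -> list[TrialResult]:
    """Many-trial accuracy sweep across label fractions.

    One fixed session-level split (drawn from the sweep seed) is shared
    by every trial; each (fraction, trial) pair then draws a fresh
    random labeled subset of the training rows and runs the
    self-training loop. Training accuracy is scored on training rows
    *excluding* the supplied subset; test accuracy on all holdout rows.
    Fully reproducible from the sweep seed.
    """
    sweep = (sweep or SweepConfig()).validate()
    train, test = split_sessions(study, sweep)
    results = []
    for fi, fraction in enumerate(sweep.label_fractions):
        for trial in range(sweep.n_trials):
            results.append(
                _run_trial(train, test, fraction, trial, sweep.seed, fi, sweep.selftrain)
            )
    return results


def summarize_sweep(
    results: Sequence[TrialResult], high_band: float = 0.80, low_band: float = 0.70
) -> pd.DataFrame:
    """Per-fraction summary: mean/median accuracy and band shares.

    ``share_high_*`` is the fraction of trials with accuracy above the
    high band (default 80%); ``share_low_*`` below the low band (70%).
    """
    if not results:
        raise ValidationError("cannot summarize an empty result list")
    df = pd.DataFrame(
        {
            "label_fraction": [r.label_fraction for r in results],
            "train_accuracy": [r.train_accuracy for r in results],
            "test_accuracy": [r.test_accuracy for r in results],
            "n_pseudolabels": [r.n_pseudolabels for r in results],
        }
    )
    rows = []
    for fraction, g in df.groupby("label_fraction", sort=True):
        row = {"label_fraction": fraction, "n_trials": len(g)}
        for side in ("train", "test"):
            acc = g[f"{side}_accuracy"]
            row[f"mean_{side}_accuracy"] = float(acc.mean())
            row[f"median_{side}_accuracy"] = float(acc.median())
            row[f"share_high_{side}"] = float((acc > high_band).mean())
            row[f"share_low_{side}"] = float((acc < low_band).mean())
        row["mean_pseudolabels"] = float(g["n_pseudolabels"].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("label_fraction")


@dataclass
class StateProgression:
    """Aligned true/predicted tracks for one participant in one session."""

    session_id: str
    participant: str
    true_states: np.ndarray
    predicted_states: np.ndarray

    def __post_init__(self) -> None:
        if self.true_states.shape != self.predicted_states.shape:
            raise ValidationError("progression tracks differ in length")

    def n_switches(self, track: str = "predicted") -> int:
        t = self.predicted_states if track == "predicted" else self.true_states
        return int(np.sum(t[1:] != t[:-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestep": np.arange(len(self.true_states)),
                "true_state": [BehaviorState(int(s)).label for s in self.true_states],
                "predicted_state": [
                    BehaviorState(int(s)).label for s in self.predicted_states
                ],
            }
        )


def state_progression(
    session: Session, model: ClassifierModel, participant: str = "a"
) -> StateProgression:
    """True vs predicted state track for one participant, for plotting."""
    if participant not in ("a", "b"):
        raise ValidationError("participant must be 'a' or 'b'")
    labels = session.labels_a if participant == "a" else session.labels_b
    feats = session.features_a if participant == "a" else session.features_b
    if labels is None:
        raise ValidationError(f"session {session.session_id} has no labels for '{participant}'")
    if session.timesteps == 0:
        raise ValidationError("cannot trace an empty session")
    return StateProgression(
        session_id=session.session_id,
        participant=participant,
        true_states=np.asarray(labels),
        predicted_states=model.predict(feats),
    )
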