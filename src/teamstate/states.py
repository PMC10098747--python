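"""Core domain types: behavior states, binary feature vectors, sessions.

A dyadic session records two participants working on a shared virtual task.
At every timestep each participant is described by seven binary features
derived from three capture modalities (headset speech, task controller,
eye tracker), and optionally by a behavior-state label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError


class BehaviorState(enum.IntEnum):
    """Three-class teamwork behavior taxonomy.

    The integer codes fix the axis order used everywhere (confusion
    matrices, posterior vectors): ENGAGED, WAITING, STRUGGLING.
    """

    ENGAGED = 0
    WAITING = 1
    STRUGGLING = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "BehaviorState":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown behavior state {label!r}") from None


#: canonical state order for matrices and reports
STATE_ORDER: tuple[BehaviorState, ...] = (
    BehaviorState.ENGAGED,
    BehaviorState.WAITING,
    BehaviorState.STRUGGLING,
)

N_STATES = len(STATE_ORDER)

#: sentinel code for a row with no label in a partially labeled dataset
UNLABELED = -1

#: canonical feature column order (one column per binary flag)
FEATURE_NAMES: tuple[str, ...] = (
    "speech",
    "controller_activated",
    "object_manipulated",
    "moving_toward_goal",
    "moving_away_from_goal",
    "focused_on_object",
    "not_focused_on_screen",
)

N_FEATURES = len(FEATURE_NAMES)

# (clause name, antecedent feature(s), consequent) — used for error messages
_IMPLICATION_CLAUSES = (
    ("object_manipulated requires controller_activated", "object_manipulated"),
    ("moving_toward_goal requires controller_activated", "moving_toward_goal"),
    ("moving_away_from_goal requires controller_activated", "moving_away_from_goal"),
)


@dataclass(frozen=True)
class FeatureVector:
    """One participant's seven binary flags at one timestep.

    Logical invariants (checked by :meth:`validate`):

    * controller-dependent flags (``object_manipulated``,
      ``moving_toward_goal``, ``moving_away_from_goal``) require
      ``controller_activated = 1``;
    * ``moving_toward_goal`` and ``moving_away_from_goal`` are mutually
      exclusive;
    * ``focused_on_object`` and ``not_focused_on_screen`` are mutually
      exclusive.
    """

    speech: int = 0
    controller_activated: int = 0
    object_manipulated: int = 0
    moving_toward_goal: int = 0
    moving_away_from_goal: int = 0
    focused_on_object: int = 0
    not_focused_on_screen: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=np.int8)

    @classmethod
    def from_array(cls, row: Sequence[int]) -> "FeatureVector":
        if len(row) != N_FEATURES:
            raise ValidationError(f"expected {N_FEATURES} features, got {len(row)}")
        return cls(**{name: int(v) for name, v in zip(FEATURE_NAMES, row)})

    def validate(self) -> "FeatureVector":
        violation = _first_violation(self.as_array()[None, :])
        if violation is not None:
            raise ValidationError(violation[1])
        return self


def _first_violation(X: np.ndarray) -> Optional[tuple[int, str]]:
    """Return (row index, clause description) of the first invariant breach."""
    X = np.asarray(X)
    cols = {name: X[:, i] for i, name in enumerate(FEATURE_NAMES)}
    bad = ~np.isin(X, (0, 1)).all(axis=1)
    if bad.any():
        return int(np.argmax(bad)), "feature values must be 0 or 1"
    ctrl = cols["controller_activated"]
    for clause, antecedent in _IMPLICATION_CLAUSES:
        breach = (cols[antecedent] == 1) & (ctrl == 0)
        if breach.any():
            return int(np.argmax(breach)), clause
    both_dir = (cols["moving_toward_goal"] == 1) & (cols["moving_away_from_goal"] == 1)
    if both_dir.any():
        return (
            int(np.argmax(both_dir)),
            "moving_toward_goal and moving_away_from_goal are mutually exclusive",
        )
    both_gaze = (cols["focused_on_object"] == 1) & (cols["not_focused_on_screen"] == 1)
    if both_gaze.any():
        return (
            int(np.argmax(both_gaze)),
            "focused_on_object and not_focused_on_screen are mutually exclusive",
        )
    return None


def validate_feature_matrix(X: np.ndarray) -> np.ndarray:
    """Validate an (n, 7) 0/1 matrix against the feature-logic invariants.

    Raises :class:`ValidationError` naming the violated clause and the
    offending row; returns the matrix as ``int8`` on success.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValidationError(f"expected an (n, {N_FEATURES}) matrix, got shape {X.shape}")
    violation = _first_violation(X)
    if violation is not None:
        row, clause = violation
        raise ValidationError(f"row {row}: {clause}")
    return X.astype(np.int8)


def enumerate_valid_vectors() -> np.ndarray:
    """All feature vectors in {0,1}^7 satisfying the logical invariants.

    There are 42 of them: 6 with the controller idle (speech x 3 gaze
    configurations) and 36 with it active (speech x 3 movement directions
    x object flag x 3 gaze configurations).
    """
    rows = []
    for bits in range(2 ** N_FEATURES):
        row = [(bits >> i) & 1 for i in range(N_FEATURES)]
        if _first_violation(np.array([row])) is None:
            rows.append(row)
    return np.array(rows, dtype=np.int8)


TASK_KINDS = ("furniture", "pc", "fulfillment")


@dataclass
class Session:
    """Time-aligned feature streams for one dyad, with optional labels.

    ``labels_*`` hold behavior-state codes (see :class:`BehaviorState`);
    ``prior_labels_*`` preserve any labels that were present before a
    rule-based re-annotation overwrote them.
    """

    session_id: str
    task_kind: str
    features_a: np.ndarray  # (T, 7) int8
    features_b: np.ndarray  # (T, 7) int8
    labels_a: Optional[np.ndarray] = None  # (T,) int8 state codes
    labels_b: Optional[np.ndarray] = None
    prior_labels_a: Optional[np.ndarray] = None
    prior_labels_b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features_a = np.asarray(self.features_a, dtype=np.int8)
        self.features_b = np.asarray(self.features_b, dtype=np.int8)
        if self.features_a.shape != self.features_b.shape:
            raise ValidationError(
                "participant feature streams differ in shape: "
                f"{self.features_a.shape} vs {self.features_b.shape}"
            )
        if self.task_kind not in TASK_KINDS:
            raise ValidationError(f"unknown task kind {self.task_kind!r}")
        for name in ("labels_a", "labels_b", "prior_labels_a", "prior_labels_b"):
            track = getattr(self, name)
            if track is not None:
                track = np.asarray(track, dtype=np.int8)
                if track.shape != (self.timesteps,):
                    raise ValidationError(
                        f"{name} has length {track.shape}, expected ({self.timesteps},)"
                    )
                setattr(self, name, track)

    @property
    def timesteps(self) -> int:
        return self.features_a.shape[0]

    @property
    def n_rows(self) -> int:
        """Total pooled rows (both participants)."""
        return 2 * self.timesteps

    def validate_features(self) -> "Session":
        for name, X in (("participant a", self.features_a), ("participant b", self.features_b)):
            try:
                validate_feature_matrix(X) if X.size else None
            except ValidationError as exc:
                raise ValidationError(f"{name}: {exc}") from None
        return self

    def copy(self) -> "Session":
        return replace(
            self,
            features_a=self.features_a.copy(),
            features_b=self.features_b.copy(),
            labels_a=None if self.labels_a is None else self.labels_a.copy(),
            labels_b=None if self.labels_b is None else self.labels_b.copy(),
            prior_labels_a=None if self.prior_labels_a is None else self.prior_labels_a.copy(),
            prior_labels_b=None if self.prior_labels_b is None else self.prior_labels_b.copy(),
        )


def pool_rows(sessions: Sequence[Session]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack both participants' rows across sessions.

    Returns ``(features, labels, session_index)`` where ``labels`` uses
    state codes (all sessions must be labeled) and ``session_index`` maps
    each pooled row back to its position in ``sessions``.
    """
    feats, labels, sidx = [], [], []
    for i, s in enumerate(sessions):
        if s.labels_a is None or s.labels_b is None:
            raise ValidationError(f"session {s.session_id} has unlabeled tracks")
        feats.append(s.features_a)
        feats.append(s.features_b)
        labels.append(s.labels_a)
        labels.append(s.labels_b)
        sidx.append(np.full(2 * s.timesteps, i, dtype=np.int32))
    return (
        np.concatenate(feats) if feats else np.empty((0, N_FEATURES), dtype=np.int8),
        np.concatenate(labels) if labels else np.empty(0, dtype=np.int8),
        np.concatenate(sidx) if sidx else np.empty(0, dtype=np.int32),
    )
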