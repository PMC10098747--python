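"""Deterministic rule-based behavior coder.

Mechanizes the manual-annotation flowchart used to produce ground-truth
labels: an ordered, first-match-wins list of boolean conditions over the
participant's own and their partner's feature flags, with an explicit
default state. Human annotators resolve ambiguous rows by watching the
session video; here ambiguity is resolved purely by rule order, so the
coder is a pure function of the two feature vectors.

Conditions are boolean expressions over ``own.<feature>`` and
``partner.<feature>`` names (e.g. ``"own.speech and partner.controller_activated"``),
which keeps rule sets serializable and auditable as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Sequence, Union

import numpy as np
import yaml

from .errors import ValidationError
from .states import (
    FEATURE_NAMES,
    BehaviorState,
    FeatureVector,
    Session,
    validate_feature_matrix,
)


@dataclass(frozen=True)
class CodingRule:
    """One flowchart branch: a named condition and the state it assigns."""

    name: str
    condition: str
    state: BehaviorState

    def compiled(self):
        return compile(self.condition, f"<rule {self.name}>", "eval")


@dataclass
class CodingRuleSet:
    """Ordered first-match-wins rules plus a default state.

    The rule order is part of the definition (it is what stands in for
    the annotator's judgment on ambiguous rows) and is preserved by
    serialization.
    """

    rules: list[CodingRule]
    default_state: BehaviorState = BehaviorState.WAITING

    def __post_init__(self) -> None:
        self._compiled = [(r, r.compiled()) for r in self.rules]

    def to_yaml(self) -> str:
        doc = {
            "default_state": self.default_state.label,
            "rules": [
                {"name": r.name, "condition": r.condition, "state": r.state.label}
                for r in self.rules
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CodingRuleSet":
        doc = yaml.safe_load(text)
        rules = [
            CodingRule(
                name=r["name"],
                condition=r["condition"],
                state=BehaviorState.from_label(r["state"]),
            )
            for r in doc["rules"]
        ]
        return cls(rules=rules, default_state=BehaviorState.from_label(doc["default_state"]))


def default_rules() -> CodingRuleSet:
    """The package's default coding flowchart.

    Engagement is goal-directed activity (or talking while both
    partners work); struggling is regression away from the goal,
    inattention while idle, aimless controller activity, or a fully
    stalled dyad; waiting is being idle while the partner works.
    Ambiguity not covered by any branch resolves to WAITING, the state
    in which a feedback system would deliberately not intervene.
    """
    E, W, S = BehaviorState.ENGAGED, BehaviorState.WAITING, BehaviorState.STRUGGLING
    return CodingRuleSet(
        rules=[
            CodingRule(
                "goal_directed",
                "own.moving_toward_goal or own.object_manipulated",
                E,
            ),
            CodingRule(
                "talking_while_working",
                "own.speech and own.controller_activated and partner.controller_activated",
                E,
            ),
            CodingRule("regressing", "own.moving_away_from_goal", S),
            CodingRule(
                "inattentive_idle",
                "own.not_focused_on_screen and not own.controller_activated",
                S,
            ),
            CodingRule("aimless_activity", "own.controller_activated", S),
            CodingRule(
                "turn_taking",
                "not own.controller_activated and partner.controller_activated",
                W,
            ),
            CodingRule(
                "stalled_dyad",
                "not own.controller_activated and not partner.controller_activated",
                S,
            ),
        ],
        default_state=W,
    )


def _as_namespace(vec: Union[FeatureVector, Sequence[int]]) -> SimpleNamespace:
    if isinstance(vec, FeatureVector):
        vec = vec.as_array()
    return SimpleNamespace(**{n: bool(v) for n, v in zip(FEATURE_NAMES, vec)})


def code_behavior(
    own: Union[FeatureVector, Sequence[int]],
    partner: Union[FeatureVector, Sequence[int]],
    rules: CodingRuleSet | None = None,
) -> BehaviorState:
    """Assign a behavior state from one row of own + partner features.

    Both vectors are validated against the feature-logic invariants
    first; the error names the violated clause.
    """
    rules = rules if rules is not None else default_rules()
    own_arr = own.as_array() if isinstance(own, FeatureVector) else np.asarray(own)
    partner_arr = partner.as_array() if isinstance(partner, FeatureVector) else np.asarray(partner)
    for who, arr in (("own", own_arr), ("partner", partner_arr)):
        try:
            validate_feature_matrix(arr[None, :])
        except ValidationError as exc:
            raise ValidationError(f"{who} vector: {exc}") from None
    ns = {"own": _as_namespace(own_arr), "partner": _as_namespace(partner_arr)}
    for rule, code in rules._compiled:
        if eval(code, {"__builtins__": {}}, ns):  # noqa: S307 - trusted rule files
            return rule.state
    return rules.default_state


def _annotate_track(
    own_X: np.ndarray, partner_X: np.ndarray, rules: CodingRuleSet
) -> np.ndarray:
    out = np.empty(len(own_X), dtype=np.int8)
    compiled = rules._compiled
    for t in range(len(own_X)):
        ns = {"own": _as_namespace(own_X[t]), "partner": _as_namespace(partner_X[t])}
        state = rules.default_state
        for rule, code in compiled:
            if eval(code, {"__builtins__": {}}, ns):  # noqa: S307
                state = rule.state
                break
        out[t] = int(state)
    return out


def annotate_session(session: Session, rules: CodingRuleSet | None = None) -> Session:
    """Fill both label tracks by applying the rule set row-wise.

    Returns a new session; any pre-existing labels are preserved in the
    ``prior_labels_*`` sidecar tracks. Idempotent: annotating an already
    rule-annotated session reproduces the same labels.
    """
    rules = rules if rules is not None else default_rules()
    session.validate_features()
    out = session.copy()
    if session.labels_a is not None:
        out.prior_labels_a = session.labels_a.copy()
    if session.labels_b is not None:
        out.prior_labels_b = session.labels_b.copy()
    out.labels_a = _annotate_track(session.features_a, session.features_b, rules)
    out.labels_b = _annotate_track(session.features_b, session.features_a, rules)
    return out


def agreement(labels_x: Sequence[int], labels_y: Sequence[int]) -> float:
    """Fraction of positions where two label tracks coincide."""
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape:
        raise ValidationError(f"label tracks differ in length: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("cannot compute agreement of empty tracks")
    return float(np.mean(x == y))
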