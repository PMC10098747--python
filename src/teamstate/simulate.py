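"""Synthetic dyadic-session generator.

Stands in for the (unavailable) participant data: six pairs of
participants working through collaborative virtual-environment tasks,
each described per timestep by seven binary features and a latent
behavior state (engaged / waiting / struggling).

The generator has two layers:

* **Latent dynamics.** Each participant follows a three-state Markov
  process. With partner coupling enabled (the default), waiting is
  modeled as turn-taking: an active-role token alternates between the
  two participants, the off-turn participant waits while the on-turn
  participant moves between ENGAGED and STRUGGLING. This construction
  makes "waiting while the partner is active" hold by design while
  keeping each participant's marginal state frequencies at the
  configured stationary target. With coupling disabled, the two chains
  run independently from the configured transition matrix.

* **Emissions.** Given a participant's own state, the seven flags are
  drawn from a state-conditional table structured so that every emitted
  row satisfies the feature-logic invariants (controller-dependent flags
  require the controller, movement directions and gaze targets are
  mutually exclusive). Because own features depend only on own state,
  the Bayes-optimal per-row accuracy is computable exactly over the
  2^7-point feature space and serves as the ceiling for learner tests.

An optional *flicker* knob injects rows where the participant is
rapidly alternating between waiting and struggling: the label is an
even coin flip between the two states and the features are drawn from
an even mixture of their emission tables, making those rows
intrinsically ambiguous to any per-row classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .states import (
    N_FEATURES,
    N_STATES,
    BehaviorState,
    Session,
    TASK_KINDS,
    enumerate_valid_vectors,
)

#: class mix the default configuration is calibrated to
DEFAULT_TARGET_STATIONARY = (0.1537, 0.5027, 0.3436)

#: expected consecutive steps spent in each state (engaged, waiting, struggling)
DEFAULT_MEAN_DWELL = (5.0, 10.0, 8.0)

_E, _W, _S = (int(s) for s in (BehaviorState.ENGAGED, BehaviorState.WAITING, BehaviorState.STRUGGLING))


@dataclass(frozen=True)
class EmissionTable:
    """State-conditional probabilities for the seven binary flags.

    Arrays are indexed by state code (ENGAGED, WAITING, STRUGGLING).
    Movement and object flags are conditional on the controller being
    active; the gaze flags are parameterized as a three-way choice
    (on object / off screen / neutral), movement likewise
    (toward / away / neither), so the mutual-exclusion invariants hold
    by construction.
    """

    p_speech: tuple[float, ...] = (0.50, 0.30, 0.10)
    p_controller: tuple[float, ...] = (0.95, 0.03, 0.96)
    p_toward_given_controller: tuple[float, ...] = (0.80, 0.20, 0.03)
    p_away_given_controller: tuple[float, ...] = (0.05, 0.10, 0.75)
    p_object_given_controller: tuple[float, ...] = (0.80, 0.10, 0.03)
    p_gaze_object: tuple[float, ...] = (0.80, 0.45, 0.15)
    p_gaze_offscreen: tuple[float, ...] = (0.02, 0.02, 0.55)

    def validate(self) -> "EmissionTable":
        for name in (
            "p_speech",
            "p_controller",
            "p_toward_given_controller",
            "p_away_given_controller",
            "p_object_given_controller",
            "p_gaze_object",
            "p_gaze_offscreen",
        ):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (N_STATES,):
                raise ConfigurationError(f"{name} must have one entry per state")
            if ((vals < 0) | (vals > 1)).any():
                raise ConfigurationError(f"{name} has a probability outside [0, 1]")
        toward = np.asarray(self.p_toward_given_controller)
        away = np.asarray(self.p_away_given_controller)
        if ((toward + away) > 1 + 1e-12).any():
            raise ConfigurationError("toward + away probabilities exceed 1 for some state")
        gobj = np.asarray(self.p_gaze_object)
        goff = np.asarray(self.p_gaze_offscreen)
        if ((gobj + goff) > 1 + 1e-12).any():
            raise ConfigurationError("gaze probabilities exceed 1 for some state")
        return self

    def row_probability(self, state: int, row: Sequence[int]) -> float:
        """Exact P(feature row | state) under the generative structure."""
        speech, ctrl, obj, toward, away, gobj, goff = (int(v) for v in row)
        if toward and away:
            return 0.0
        if gobj and goff:
            return 0.0
        ps = self.p_speech[state]
        p = ps if speech else 1.0 - ps
        pc = self.p_controller[state]
        if ctrl:
            p *= pc
            pt, pa = self.p_toward_given_controller[state], self.p_away_given_controller[state]
            p *= pt if toward else pa if away else 1.0 - pt - pa
            po = self.p_object_given_controller[state]
            p *= po if obj else 1.0 - po
        else:
            if obj or toward or away:
                return 0.0
            p *= 1.0 - pc
        pg, pf = self.p_gaze_object[state], self.p_gaze_offscreen[state]
        p *= pg if gobj else pf if goff else 1.0 - pg - pf
        return float(p)

    def likelihood_matrix(self, vectors: Optional[np.ndarray] = None) -> np.ndarray:
        """(n_states, n_vectors) matrix of P(row | state)."""
        if vectors is None:
            vectors = enumerate_valid_vectors()
        return np.array(
            [[self.row_probability(s, row) for row in vectors] for s in range(N_STATES)]
        )

    def sample(self, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one feature row per entry of ``states`` (vectorized)."""
        n = len(states)
        X = np.zeros((n, N_FEATURES), dtype=np.int8)
        u = rng.random((n, 4))  # speech, controller, movement, gaze
        u_obj = rng.random(n)
        for s in range(N_STATES):
            m = states == s
            if not m.any():
                continue
            X[m, 0] = u[m, 0] < self.p_speech[s]
            ctrl = u[m, 1] < self.p_controller[s]
            X[m, 1] = ctrl
            pt = self.p_toward_given_controller[s]
            pa = self.p_away_given_controller[s]
            X[m, 3] = ctrl & (u[m, 2] < pt)
            X[m, 4] = ctrl & (u[m, 2] >= pt) & (u[m, 2] < pt + pa)
            X[m, 2] = ctrl & (u_obj[m] < self.p_object_given_controller[s])
            pg, pf = self.p_gaze_object[s], self.p_gaze_offscreen[s]
            X[m, 5] = u[m, 3] < pg
            X[m, 6] = (u[m, 3] >= pg) & (u[m, 3] < pg + pf)
        return X


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via eigen-decomposition."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(w - 1.0))
    if abs(w[idx] - 1.0) > 1e-8:
        raise CalibrationError("matrix has no unit eigenvalue; not row-stochastic?")
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def calibrate_transitions(
    target_stationary: Sequence[float],
    mean_dwell: Sequence[float] = DEFAULT_MEAN_DWELL,
) -> np.ndarray:
    """Build a 3x3 row-stochastic matrix with the requested stationary law.

    The diagonal is fixed by the requested mean dwell times
    (``p_ii = 1 - 1/dwell_i``); the off-diagonal mass is found as a
    zero-diagonal flow matrix with prescribed row and column sums
    (outflow of each state equals its inflow at stationarity), computed
    by iterative proportional fitting. Feasibility requires that no
    state's stationary outflow exceed the combined outflow of the other
    states; otherwise a :class:`CalibrationError` names the violation.
    """
    pi = np.asarray(target_stationary, dtype=float)
    dwell = np.asarray(mean_dwell, dtype=float)
    if pi.shape != (N_STATES,) or dwell.shape != (N_STATES,):
        raise CalibrationError("target and dwell must each have three entries")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise CalibrationError("target stationary distribution must sum to 1")
    if (pi <= 0).any():
        raise CalibrationError(
            "target stationary has a zero (or negative) entry; the chain "
            "would need an unreachable or absorbing state"
        )
    if (dwell < 1).any():
        raise CalibrationError("mean dwell times must be at least 1 step")

    exit_prob = 1.0 / dwell
    flow_out = pi * exit_prob
    if flow_out.max() > flow_out.sum() - flow_out.max() + 1e-12:
        i = int(np.argmax(flow_out))
        raise CalibrationError(
            f"infeasible dwell/target combination: stationary outflow of state "
            f"{BehaviorState(i).label} ({flow_out[i]:.4g}) exceeds the combined "
            f"outflow of the other states ({flow_out.sum() - flow_out[i]:.4g}); "
            "lengthen its dwell or shrink its target share"
        )

    # iterative proportional fitting of a zero-diagonal flow matrix
    F = np.outer(flow_out, flow_out)
    np.fill_diagonal(F, 0.0)
    for _ in range(50_000):
        F *= (flow_out / F.sum(axis=1))[:, None]
        F *= flow_out / F.sum(axis=0)
        if np.abs(F.sum(axis=1) - flow_out).max() < 1e-14:
            break
    if np.abs(F.sum(axis=1) - flow_out).max() > 1e-12:
        raise CalibrationError("flow calibration failed to converge")

    P = F / pi[:, None]
    np.fill_diagonal(P, 1.0 - exit_prob)
    achieved = stationary_distribution(P)
    if np.abs(achieved - pi).max() > 1e-6:
        raise CalibrationError("calibrated matrix missed the stationary target")
    return P


@dataclass
class SimulationConfig:
    """Everything needed to generate a reproducible synthetic study."""

    n_sessions: int = 6
    steps_per_session: int = 250
    transition_matrix: Optional[np.ndarray] = None
    coupling_rule: bool = True
    emissions: EmissionTable = field(default_factory=EmissionTable)
    target_stationary: tuple[float, ...] = DEFAULT_TARGET_STATIONARY
    mean_dwell: tuple[float, ...] = DEFAULT_MEAN_DWELL
    flicker_rate: float = 0.0
    initial_state: Optional[BehaviorState] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = calibrate_transitions(
                self.target_stationary, self.mean_dwell
            )
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)

    def validate(self) -> "SimulationConfig":
        P = self.transition_matrix
        if P.shape != (N_STATES, N_STATES):
            raise ConfigurationError("transition matrix must be 3x3")
        if (P < -1e-12).any():
            raise ConfigurationError("transition matrix has a negative entry")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
            raise ConfigurationError("transition matrix rows must sum to 1")
        pi = np.asarray(self.target_stationary, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ConfigurationError("target stationary must sum to 1")
        if not 0.0 <= self.flicker_rate <= 1.0:
            raise ConfigurationError("flicker_rate must lie in [0, 1]")
        if self.steps_per_session < 0 or self.n_sessions < 0:
            raise ConfigurationError("counts must be nonnegative")
        self.emissions.validate()
        return self


def _sample_chain(
    P: np.ndarray, n_steps: int, rng: np.random.Generator, initial: Optional[int]
) -> np.ndarray:
    if initial is None:
        try:
            pi0 = stationary_distribution(P)
        except CalibrationError:
            pi0 = np.full(N_STATES, 1.0 / N_STATES)
        state = int(rng.choice(N_STATES, p=pi0))
    else:
        state = int(initial)
    out = np.empty(n_steps, dtype=np.int8)
    cum = np.cumsum(P, axis=1)
    for t in range(n_steps):
        out[t] = state
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        state = min(state, N_STATES - 1)
    return out


def _sample_coupled_states(
    config: SimulationConfig, n_steps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Turn-taking construction: an active-role token alternates between
    the dyad; the off-turn participant is WAITING, the on-turn one moves
    between ENGAGED and STRUGGLING with the target conditional mix."""
    pi = np.asarray(config.target_stationary, dtype=float)
    r = pi[_E] / (pi[_E] + pi[_S])  # engaged share of on-turn time
    switch = 1.0 / config.mean_dwell[_W]  # token hand-over probability
    a = 1.0 / config.mean_dwell[_E]  # P(E -> S) while on turn
    b = a * r / (1.0 - r)  # P(S -> E), fixes the E:S ratio

    def fresh_duty() -> int:
        return _E if rng.random() < r else _S

    holder = int(rng.random() < 0.5)  # 0 -> participant a, 1 -> b
    duty = fresh_duty()
    states = np.empty((2, n_steps), dtype=np.int8)
    for t in range(n_steps):
        states[holder, t] = duty
        states[1 - holder, t] = _W
        if rng.random() < switch:
            holder = 1 - holder
            duty = fresh_duty()
        else:
            u = rng.random()
            if duty == _E and u < a:
                duty = _S
            elif duty == _S and u < b:
                duty = _E
    return states[0], states[1]


def _apply_flicker(
    labels: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, emit_states) with ambiguous waiting/struggling rows.

    Flicker episodes model a participant rapidly alternating between
    waiting and struggling: within an episode the label strictly
    alternates between the two states step by step, while the sensors
    see the pause between attempts — waiting-like features regardless
    of the momentary label. Episode rows are therefore irreducibly
    ambiguous to a per-row classifier, which (following its class
    priors) resolves them toward WAITING, flattening the rapid
    alternation out of the predicted track.

    Episodes start at eligible rows (latent state waiting or
    struggling) with probability ``rate / mean_len`` and continue with
    probability ``1 - 1/mean_len`` per step while the latent state
    stays eligible, so about ``rate`` of eligible rows are flickered.
    """
    mean_len = 6.0
    labels = labels.copy()
    emit = labels.copy()
    start_p = rate / mean_len
    cont_p = 1.0 - 1.0 / mean_len
    t, T = 0, len(labels)
    while t < T:
        if labels[t] in (_W, _S) and rng.random() < start_p:
            current = _W if rng.random() < 0.5 else _S
            while t < T and labels[t] in (_W, _S):
                labels[t] = current
                emit[t] = _W
                current = _S if current == _W else _W
                t += 1
                if rng.random() >= cont_p:
                    break
        else:
            t += 1
    return labels, emit


def simulate_session(
    config: SimulationConfig,
    session_seed: int,
    session_id: str = "s0",
    task_kind: str = "furniture",
) -> Session:
    """Generate one dyadic session; label tracks are the latent states.

    Deterministic in ``(config, session_seed)``.
    """
    config.validate()
    rng = np.random.default_rng(session_seed)
    T = config.steps_per_session
    if config.coupling_rule:
        states_a, states_b = _sample_coupled_states(config, T, rng)
    else:
        init = None if config.initial_state is None else int(config.initial_state)
        states_a = _sample_chain(config.transition_matrix, T, rng, init)
        states_b = _sample_chain(config.transition_matrix, T, rng, init)

    if config.flicker_rate > 0:
        labels_a, emit_a = _apply_flicker(states_a, config.flicker_rate, rng)
        labels_b, emit_b = _apply_flicker(states_b, config.flicker_rate, rng)
    else:
        labels_a, emit_a = states_a, states_a
        labels_b, emit_b = states_b, states_b

    features_a = config.emissions.sample(emit_a, rng)
    features_b = config.emissions.sample(emit_b, rng)
    return Session(
        session_id=session_id,
        task_kind=task_kind,
        features_a=features_a,
        features_b=features_b,
        labels_a=labels_a,
        labels_b=labels_b,
    )


def make_study(config: SimulationConfig) -> list[Session]:
    """Generate the full study: ``n_sessions`` dyadic sessions.

    Per-session seeds are spawned deterministically from ``config.seed``.
    The default configuration (6 sessions of 250 steps, two participants
    each) makes any 4-session subset hold about 2000 pooled rows, with
    the remaining 2 sessions providing the holdout.
    """
    config.validate()
    if config.n_sessions < 2:
        raise ConfigurationError(
            "need at least 2 sessions for a session-level train/test split"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_sessions)
    sessions = []
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        sessions.append(
            simulate_session(
                config,
                session_seed=seed,
                session_id=f"s{i}",
                task_kind=TASK_KINDS[i % len(TASK_KINDS)],
            )
        )
    return sessions


def bayes_accuracy(
    emissions: EmissionTable, prior: Sequence[float] = DEFAULT_TARGET_STATIONARY
) -> float:
    """Best achievable per-row accuracy under the known emission model.

    Exhaustive over the feature space: sum over rows of
    ``max_s prior_s * P(row | s)``. Invalid rows have probability zero
    under every state and contribute nothing.
    """
    prior = np.asarray(prior, dtype=float)
    L = emissions.likelihood_matrix()  # (3, 42)
    joint = prior[:, None] * L
    return float(joint.max(axis=0).sum())


def bayes_predict(emissions: EmissionTable, prior: Sequence[float], X: np.ndarray) -> np.ndarray:
    """Bayes-rule predictions for feature rows (used as an oracle in tests)."""
    prior = np.asarray(prior, dtype=float)
    out = np.empty(len(X), dtype=np.int8)
    for i, row in enumerate(np.asarray(X)):
        scores = [prior[s] * emissions.row_probability(s, row) for s in range(N_STATES)]
        out[i] = int(np.argmax(scores))
    return out
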