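"""Four-parameter gain-loss reinforcement-learning model.

The model maintains expectancy values Q[response, stimulus] for each of
the two responses to each of the four stimuli, all initialised to 0.  On
each trial the probability of responding ``A`` is a softmax over the two
expectancies with inverse-gain parameter beta; low beta makes choice
nearly deterministic toward the higher expectancy, high beta makes it
random.  The outcome's reinforcement value R is +1 for reward, -1 for
punishment, and the free parameter R0 for the ambiguous no-feedback
outcome.  The prediction error PE = R - Q[r, s] (r the emitted response,
s the stimulus) updates only the chosen entry, with learning rate
alpha_gain when the outcome is better than expected (PE > 0) and
alpha_loss when worse (PE < 0).

The same machinery runs generatively (sampling choices) and evaluatively
(probability of observed choices, see :mod:`gainloss.fitting`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .task import (
    CATEGORIES,
    Session,
    TrialRecord,
    is_optimal,
    resolve_outcome,
)


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the gain-loss model (plus fixed R+ and R-).

    alpha_gain, alpha_loss : learning rates in [0, 1] for positive and
        negative prediction errors respectively.
    beta : inverse gain in [0, 1]; the greedy limit beta = 0 picks the
        higher expectancy deterministically (ties split 50/50).
    r0 : reinforcement value of the no-feedback outcome, in [r_minus,
        r_plus]; 0 is truly neutral, positive values treat no-feedback as
        reward-like (successful avoidance), negative as punishment-like
        (missed reward).
    """

    alpha_gain: float
    alpha_loss: float
    beta: float
    r0: float
    r_plus: float = 1.0
    r_minus: float = -1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_gain <= 1.0:
            raise ValueError("alpha_gain must lie in [0, 1]")
        if not 0.0 <= self.alpha_loss <= 1.0:
            raise ValueError("alpha_loss must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not self.r_minus <= self.r0 <= self.r_plus:
            raise ValueError("r0 must lie in [r_minus, r_plus]")

    def to_dict(self) -> dict[str, float]:
        return {
            "alpha_gain": self.alpha_gain,
            "alpha_loss": self.alpha_loss,
            "beta": self.beta,
            "r0": self.r0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(
            alpha_gain=float(d["alpha_gain"]),
            alpha_loss=float(d["alpha_loss"]),
            beta=float(d["beta"]),
            r0=float(d["r0"]),
        )


class QTable:
    """Expectancy values Q[response, stimulus], 2 responses x 4 stimuli."""

    def __init__(self, stimuli: tuple[str, ...]):
        self.stimuli = tuple(stimuli)
        self._stim_index = {s: i for i, s in enumerate(self.stimuli)}
        self._resp_index = {r: i for i, r in enumerate(CATEGORIES)}
        self.q = np.zeros((len(CATEGORIES), len(self.stimuli)))

    def __getitem__(self, key: tuple[str, str]) -> float:
        response, stimulus = key
        return float(self.q[self._resp_index[response], self._stim_index[stimulus]])

    def __setitem__(self, key: tuple[str, str], value: float) -> None:
        response, stimulus = key
        self.q[self._resp_index[response], self._stim_index[stimulus]] = value

    def pair(self, stimulus: str) -> tuple[float, float]:
        """(Q[A, s], Q[B, s]) for a stimulus."""
        j = self._stim_index[stimulus]
        return float(self.q[0, j]), float(self.q[1, j])

    def copy(self) -> "QTable":
        new = QTable(self.stimuli)
        new.q = self.q.copy()
        return new


def choice_probabilities(
    q_pair: tuple[float, float], beta: float
) -> tuple[float, float]:
    """Softmax probability of each response given its expectancy.

    Pr(A) = exp(Q_A / beta) / (exp(Q_A / beta) + exp(Q_B / beta)),
    computed through the logistic of the scaled difference so large
    arguments never overflow.  beta = 0 is the greedy limit: probability 1
    for the larger expectancy, 0.5 each on a tie.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    q_a, q_b = q_pair
    if beta == 0.0:
        if q_a > q_b:
            return 1.0, 0.0
        if q_a < q_b:
            return 0.0, 1.0
        return 0.5, 0.5
    # each side through its own logistic: 1 - expit(x) underflows to 0
    # long before expit(-x) does, and Pr must vanish only at beta = 0
    d = (q_a - q_b) / beta
    return float(expit(d)), float(expit(-d))


def reinforcement_value(feedback: str, params: AgentParams) -> float:
    """Reinforcement value R of an outcome: R+, R-, or R0."""
    if feedback == "reward":
        return params.r_plus
    if feedback == "punishment":
        return params.r_minus
    if feedback == "none":
        return params.r0
    raise ValueError(f"unknown feedback kind: {feedback!r}")


def prediction_error(r: float, q_current: float) -> float:
    """PE = R - Q[r, s]: positive when the outcome beats the expectancy."""
    return r - q_current


def apply_update(
    qtable: QTable, stimulus: str, response: str, pe: float, params: AgentParams
) -> QTable:
    """Update the chosen entry in place by alpha_gain*PE or alpha_loss*PE.

    Only Q[response, stimulus] changes; a zero prediction error leaves the
    table untouched.  Returns the same table for chaining.
    """
    if not np.isfinite(pe):
        raise ValueError("prediction error must be finite")
    if pe > 0:
        qtable[response, stimulus] += params.alpha_gain * pe
    elif pe < 0:
        qtable[response, stimulus] += params.alpha_loss * pe
    return qtable


def simulate_agent(schedule: Session, params: AgentParams, seed: int) -> Session:
    """Play a schedule generatively: sample each choice from the model.

    For each trial in order, the response is sampled from the softmax over
    the current expectancies, the outcome is resolved by the task rules,
    and the chosen entry is updated with the sampled response's prediction
    error.  Deterministic for a fixed seed; the input schedule is not
    modified.
    """
    rng = np.random.default_rng(seed)
    config = schedule.config
    qtable = QTable(config.stimuli)
    records: list[TrialRecord] = []
    points = config.initial_points
    for trial in schedule.trials:
        p_a, _ = choice_probabilities(qtable.pair(trial.stimulus), params.beta)
        response = "A" if rng.random() < p_a else "B"
        feedback, delta = resolve_outcome(trial, response, config)
        r = reinforcement_value(feedback, params)
        pe = prediction_error(r, qtable[response, trial.stimulus])
        apply_update(qtable, trial.stimulus, response, pe, params)
        points += delta
        records.append(
            TrialRecord(
                trial=trial,
                response=response,
                correct=response == trial.sampled_category,
                optimal=is_optimal(trial, response),
                feedback=feedback,
                points_delta=delta,
                cumulative_points=points,
            )
        )
    return schedule.with_records(records)
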