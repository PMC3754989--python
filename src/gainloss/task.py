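"""Probabilistic reward/punishment classification task.

The task interleaves two kinds of learning in one session.  On each trial
the participant sees one of four stimuli and classifies it as category
``A`` or ``B``.  Each stimulus belongs to its majority category on 80% of
trials (8 of 10 per block) and to the other category on the remaining 20%.
Two stimuli are *reward* stimuli: a correct classification gains points and
an incorrect one yields no feedback.  The other two are *punishment*
stimuli: an incorrect classification loses points and a correct one yields
no feedback.  The "no feedback" outcome is therefore ambiguous — it can
mean a missed reward or a successfully avoided punishment.

This module builds trial schedules with the exact per-block composition,
resolves feedback and point outcomes for any response, and scores whether a
response is *optimal* (the majority category, regardless of the category
actually sampled on that trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

CATEGORIES = ("A", "B")
TRIAL_TYPES = ("reward", "punishment")
FEEDBACK_KINDS = ("reward", "punishment", "none")

#: default stimulus -> (majority category, trial type) assignment
DEFAULT_STIMULUS_ROLES: dict[str, tuple[str, str]] = {
    "S1": ("A", "reward"),
    "S2": ("B", "reward"),
    "S3": ("A", "punishment"),
    "S4": ("B", "punishment"),
}


class TaskConfigError(ValueError):
    """Raised when a task configuration violates its structural constraints."""


def other_category(category: str) -> str:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category: {category!r}")
    return "B" if category == "A" else "A"


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the classification task.

    Defaults give the standard session: 4 blocks x 4 stimuli x 10 trials
    = 160 trials, 8 of 10 trials per stimulus per block carrying the
    majority category, +/-25 points, 500-point starting tally.
    """

    n_blocks: int = 4
    trials_per_stimulus_per_block: int = 10
    common_per_stimulus_per_block: int = 8
    reward_points: int = 25
    punishment_points: int = -25
    initial_points: int = 500
    stimulus_roles: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_STIMULUS_ROLES)
    )

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise TaskConfigError("n_blocks must be >= 1")
        if self.trials_per_stimulus_per_block < 1:
            raise TaskConfigError("trials_per_stimulus_per_block must be >= 1")
        if not (0 <= self.common_per_stimulus_per_block
                <= self.trials_per_stimulus_per_block):
            raise TaskConfigError(
                "common_per_stimulus_per_block must lie between 0 and "
                "trials_per_stimulus_per_block"
            )
        if len(self.stimulus_roles) != 4:
            raise TaskConfigError("exactly 4 stimuli are required")
        per_type = {"reward": 0, "punishment": 0}
        for stim, (majority, trial_type) in self.stimulus_roles.items():
            if majority not in CATEGORIES:
                raise TaskConfigError(f"bad majority category for {stim}: {majority!r}")
            if trial_type not in TRIAL_TYPES:
                raise TaskConfigError(f"bad trial type for {stim}: {trial_type!r}")
            per_type[trial_type] += 1
        if per_type["reward"] != 2 or per_type["punishment"] != 2:
            raise TaskConfigError("each trial type must cover exactly 2 stimuli")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.stimulus_roles)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * len(self.stimulus_roles) * self.trials_per_stimulus_per_block

    def majority_category(self, stimulus: str) -> str:
        return self.stimulus_roles[stimulus][0]

    def trial_type(self, stimulus: str) -> str:
        return self.stimulus_roles[stimulus][1]


@dataclass(frozen=True)
class Trial:
    """One scheduled trial.

    ``sampled_category`` is the category the stimulus belongs to on this
    particular trial; ``optimal_category`` is the stimulus's majority
    category and defines the optimal response independent of the sample.
    """

    index: int
    block: int
    stimulus: str
    trial_type: str
    sampled_category: str
    optimal_category: str


@dataclass(frozen=True)
class TrialRecord:
    """A played trial: the scheduled trial plus response and outcome."""

    trial: Trial
    response: str
    correct: bool
    optimal: bool
    feedback: str
    points_delta: int
    cumulative_points: int


@dataclass(frozen=True)
class Session:
    """An ordered trial schedule, optionally with responses.

    ``records`` is ``None`` for an unplayed schedule; once played it holds
    one :class:`TrialRecord` per scheduled trial, in order.
    """

    participant_id: str
    config: TaskConfig
    trials: tuple[Trial, ...]
    records: tuple[TrialRecord, ...] | None = None
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def is_complete(self) -> bool:
        return self.records is not None and len(self.records) == len(self.trials)

    def with_records(self, records: Sequence[TrialRecord]) -> "Session":
        if len(records) != len(self.trials):
            raise ValueError("records must cover every scheduled trial")
        return replace(self, records=tuple(records))


def build_session(
    config: TaskConfig,
    seed: int,
    participant_id: str = "agent",
) -> Session:
    """Build a trial schedule with exact per-block composition.

    Within each block every stimulus appears exactly
    ``trials_per_stimulus_per_block`` times, of which exactly
    ``common_per_stimulus_per_block`` carry its majority category; trial
    order is then shuffled uniformly within the block.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for block in range(config.n_blocks):
        block_specs: list[tuple[str, str, str, str]] = []
        for stimulus, (majority, trial_type) in config.stimulus_roles.items():
            minority = other_category(majority)
            n_common = config.common_per_stimulus_per_block
            n_rare = config.trials_per_stimulus_per_block - n_common
            cats = [majority] * n_common + [minority] * n_rare
            block_specs.extend(
                (stimulus, trial_type, cat, majority) for cat in cats
            )
        order = rng.permutation(len(block_specs))
        for pos in order:
            stimulus, trial_type, sampled, majority = block_specs[pos]
            trials.append(
                Trial(
                    index=len(trials),
                    block=block,
                    stimulus=stimulus,
                    trial_type=trial_type,
                    sampled_category=sampled,
                    optimal_category=majority,
                )
            )
    return Session(
        participant_id=participant_id,
        config=config,
        trials=tuple(trials),
        records=None,
        seed=seed,
    )


def resolve_outcome(
    trial: Trial, response: str, config: TaskConfig
) -> tuple[str, int]:
    """Feedback kind and point change for a response on a trial.

    Reward trials: correct -> reward and a point gain, incorrect -> no
    feedback.  Punishment trials: incorrect -> punishment and a point loss,
    correct -> no feedback.
    """
    if response not in CATEGORIES:
        raise ValueError(f"response must be one of {CATEGORIES}, got {response!r}")
    correct = response == trial.sampled_category
    if trial.trial_type == "reward":
        if correct:
            return "reward", config.reward_points
        return "none", 0
    if correct:
        return "none", 0
    return "punishment", config.punishment_points


def is_optimal(trial: Trial, response: str) -> bool:
    """Whether a response matches the stimulus's majority category.

    Scored against the majority category regardless of the category
    sampled on this particular trial.
    """
    if response not in CATEGORIES:
        raise ValueError(f"response must be one of {CATEGORIES}, got {response!r}")
    return response == trial.optimal_category


def play_session(schedule: Session, responses: Sequence[str]) -> Session:
    """Attach a response sequence to a schedule, resolving all outcomes.

    Useful for scripted responders in tests and for reconstructing played
    sessions from logged responses.
    """
    if len(responses) != schedule.n_trials:
        raise ValueError(
            f"got {len(responses)} responses for {schedule.n_trials} trials"
        )
    config = schedule.config
    records: list[TrialRecord] = []
    points = config.initial_points
    for trial, response in zip(schedule.trials, responses):
        feedback, delta = resolve_outcome(trial, response, config)
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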