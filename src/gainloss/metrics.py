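"""Behavioral scoring of played sessions.

Sessions are scored as percent optimal responding separately over the
reward trials and the punishment trials (80 of each in the standard
session), overall and per block.  A participant is a *solver* on a trial
type when their optimal-response count reaches 65% (52 of 80), the level
at which an exact two-tailed binomial test against chance is significant
at p < 0.01; *below-chance* responding on reward trials is strictly less
than 35% optimal (the mirror-image criterion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .stats import exact_binomial_two_tailed
from .task import Session, TRIAL_TYPES

#: solver rule: at least this fraction of optimal responses on a trial type
SOLVER_FRACTION = 0.65
#: below-chance rule: strictly fewer than this fraction optimal (reward trials)
BELOW_CHANCE_FRACTION = 0.35


class IncompleteSessionError(ValueError):
    """Raised when scoring is attempted on a session without responses."""


@dataclass(frozen=True)
class BehaviorSummary:
    participant_id: str
    pct_optimal_reward: float
    pct_optimal_punishment: float
    per_block_pct: pd.DataFrame
    total_points: int
    solver_reward: bool
    solver_punishment: bool
    solver_any: bool
    below_chance_reward: bool

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "pct_optimal_reward": round(self.pct_optimal_reward, 1),
            "pct_optimal_punishment": round(self.pct_optimal_punishment, 1),
            "total_points": self.total_points,
            "solver_reward": self.solver_reward,
            "solver_punishment": self.solver_punishment,
            "solver_any": self.solver_any,
            "below_chance_reward": self.below_chance_reward,
        }
        for (trial_type, block), pct in self.per_block_pct.stack().items():
            d[f"pct_optimal_{trial_type}_block{block + 1}"] = round(pct, 1)
        return d


def summarize(session: Session) -> BehaviorSummary:
    """Score one complete session.

    Solver flags use the inclusive >= 65% count threshold per trial type;
    the below-chance flag on reward trials is strict (< 35%).  Percentages
    are exact count ratios; rounding happens only in exported tables.
    """
    if not session.is_complete:
        raise IncompleteSessionError(
            f"session {session.participant_id!r} has no responses to score"
        )
    counts = {t: 0 for t in TRIAL_TYPES}
    optimal = {t: 0 for t in TRIAL_TYPES}
    per_block_counts: dict[tuple[str, int], list[int]] = {}
    total_delta = 0
    for record in session.records:
        trial = record.trial
        counts[trial.trial_type] += 1
        optimal[trial.trial_type] += record.optimal
        key = (trial.trial_type, trial.block)
        cell = per_block_counts.setdefault(key, [0, 0])
        cell[0] += record.optimal
        cell[1] += 1
        total_delta += record.points_delta

    def pct(trial_type: str) -> float:
        return 100.0 * optimal[trial_type] / counts[trial_type]

    def solver(trial_type: str) -> bool:
        threshold = math.ceil(SOLVER_FRACTION * counts[trial_type])
        return optimal[trial_type] >= threshold

    blocks = sorted({b for (_, b) in per_block_counts})
    per_block = pd.DataFrame(
        [
            [100.0 * per_block_counts[(t, b)][0] / per_block_counts[(t, b)][1]
             for b in blocks]
            for t in TRIAL_TYPES
        ],
        index=list(TRIAL_TYPES),
        columns=blocks,
    )
    pct_reward = pct("reward")
    solver_reward = solver("reward")
    solver_punishment = solver("punishment")
    return BehaviorSummary(
        participant_id=session.participant_id,
        pct_optimal_reward=pct_reward,
        pct_optimal_punishment=pct("punishment"),
        per_block_pct=per_block,
        total_points=session.config.initial_points + total_delta,
        solver_reward=solver_reward,
        solver_punishment=solver_punishment,
        solver_any=solver_reward or solver_punishment,
        below_chance_reward=pct_reward < 100.0 * BELOW_CHANCE_FRACTION,
    )


def summarize_sessions(sessions: list[Session]) -> pd.DataFrame:
    """One summary row per participant."""
    return pd.DataFrame([summarize(s).to_dict() for s in sessions])


def criterion_count(n_trials: int, alpha: float) -> int:
    """Smallest above-chance success count significant at ``alpha``.

    The minimal k >= n/2 such that the exact two-tailed binomial test of k
    successes in ``n_trials`` against 0.5 gives p < alpha.  For 80 trials
    at alpha = 0.01 this is 52 (65%), the solver criterion.  Returns
    ``n_trials + 1`` if even a perfect score is not significant.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    for k in range(math.ceil(n_trials / 2), n_trials + 1):
        if exact_binomial_two_tailed(k, n_trials, 0.5) < alpha:
            return k
    return n_trials + 1
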