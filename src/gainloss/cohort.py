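"""Synthetic cohorts of simulated participants.

Generates groups of gain-loss agents whose parameters are drawn from
group-specific truncated distributions, plays each agent through a fresh
task schedule, and keeps the true parameters for recovery checks.  The
default presets mirror the study population this pipeline was built
around: a control group (n = 39) whose no-feedback valuation R0 centers
near +0.5 (no-feedback felt reward-like) and a PTSS group (n = 48) whose
R0 centers near 0 (no-feedback felt neutral), with learning rates and
inverse gain shared across groups (centered on the cohort-wide estimates
alpha_gain 0.27, alpha_loss 0.23, beta 0.34).  Categorical covariates
(medication, combat history, behavioral-inhibition class) are generated
as labels only, to exercise the contingency-table statistics; they have
no behavioral effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .agent import AgentParams, simulate_agent
from .task import Session, TaskConfig, build_session

PARAM_NAMES = ("alpha_gain", "alpha_loss", "beta", "r0")


@dataclass(frozen=True)
class ParamDist:
    """Truncated sampling distribution for one model parameter."""

    family: str = "truncnorm"  # truncnorm | uniform | point
    center: float = 0.0
    spread: float = 0.1
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must not exceed high")
        if self.family not in ("truncnorm", "uniform", "point"):
            raise ValueError(f"unknown distribution family: {self.family!r}")
        if self.family == "truncnorm" and self.spread <= 0:
            raise ValueError("truncnorm spread must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, float(np.clip(self.center, self.low, self.high)))
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size)
        a = (self.low - self.center) / self.spread
        b = (self.high - self.center) / self.spread
        return truncnorm.rvs(
            a, b, loc=self.center, scale=self.spread, size=size, random_state=rng
        )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, parameter distributions, covariate mix."""

    label: str
    n: int
    param_dists: Mapping[str, ParamDist]
    covariates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        missing = set(PARAM_NAMES) - set(self.param_dists)
        if missing:
            raise ValueError(f"missing parameter distributions: {sorted(missing)}")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    task: TaskConfig = field(default_factory=TaskConfig)
    master_seed: int = 0

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def _shared_learning_dists() -> dict[str, ParamDist]:
    return {
        "alpha_gain": ParamDist("truncnorm", 0.27, 0.32, 0.0, 1.0),
        "alpha_loss": ParamDist("truncnorm", 0.23, 0.34, 0.0, 1.0),
        "beta": ParamDist("truncnorm", 0.34, 0.27, 0.0, 1.0),
    }


def default_presets(master_seed: int = 0) -> CohortSpec:
    """Two-group cohort matching the reference study's composition.

    39 controls and 48 PTSS agents; learning-rate and inverse-gain
    distributions are shared across groups (no group differences were
    found in them), while R0 is truncated-normal centered at +0.5
    (control) vs 0.0 (PTSS) with spread 0.2.  Covariate label frequencies
    follow the reported group tables.
    """
    control = GroupSpec(
        label="control",
        n=39,
        param_dists={
            **_shared_learning_dists(),
            "r0": ParamDist("truncnorm", 0.5, 0.2, -1.0, 1.0),
        },
        covariates={
            "medication": {"no": 28 / 39, "yes": 11 / 39},
            "combat": {"non-combat": 26 / 39, "combat": 13 / 39},
            "bi": {"inhibited": 12 / 39, "uninhibited": 14 / 39,
                   "inconsistent": 13 / 39},
        },
    )
    ptss = GroupSpec(
        label="PTSS",
        n=48,
        param_dists={
            **_shared_learning_dists(),
            "r0": ParamDist("truncnorm", 0.0, 0.2, -1.0, 1.0),
        },
        covariates={
            "medication": {"no": 11 / 48, "yes": 37 / 48},
            "combat": {"non-combat": 26 / 48, "combat": 22 / 48},
            "bi": {"inhibited": 28 / 48, "uninhibited": 6 / 48,
                   "inconsistent": 14 / 48},
        },
    )
    return CohortSpec(groups=(control, ptss), task=TaskConfig(), master_seed=master_seed)


@dataclass(frozen=True)
class Cohort:
    """Simulated sessions plus the manifest of true parameters and labels."""

    spec: CohortSpec
    sessions: tuple[Session, ...]
    manifest: pd.DataFrame  # participant_id, group, true params, covariates, seeds

    @property
    def groups(self) -> pd.Series:
        return self.manifest.set_index("participant_id")["group"]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate one session per agent, reproducibly from the master seed.

    All randomness (parameter draws, covariate labels, per-agent schedule
    and choice seeds) descends from ``spec.master_seed``.
    """
    rng = np.random.default_rng(spec.master_seed)
    sessions: list[Session] = []
    rows: list[dict] = []
    for group in spec.groups:
        draws = {
            name: group.param_dists[name].sample(rng, group.n)
            for name in PARAM_NAMES
        }
        covariate_draws = {
            name: rng.choice(
                list(levels), size=group.n, p=np.asarray(list(levels.values()))
            )
            for name, levels in (
                (n, dict(v)) for n, v in group.covariates.items()
            )
        }
        for i in range(group.n):
            pid = f"{group.label}-{i + 1:03d}"
            params = AgentParams(**{name: float(draws[name][i]) for name in PARAM_NAMES})
            schedule_seed, sim_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
            schedule = build_session(spec.task, schedule_seed, participant_id=pid)
            sessions.append(simulate_agent(schedule, params, sim_seed))
            row = {"participant_id": pid, "group": group.label}
            row.update({f"true_{name}": getattr(params, name) for name in PARAM_NAMES})
            row.update({name: covariate_draws[name][i] for name in covariate_draws})
            row.update({"schedule_seed": schedule_seed, "sim_seed": sim_seed})
            rows.append(row)
    return Cohort(spec=spec, sessions=tuple(sessions), manifest=pd.DataFrame(rows))
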