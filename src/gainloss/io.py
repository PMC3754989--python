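"""Readers, writers, and run configuration.

All tabular formats are plain UTF-8 CSV with a mandatory header and no
index column.  Session logs carry one row per trial with 1-based trial
and block numbers; trial outcomes are recomputed from the task rules on
read, so a log can never smuggle in inconsistent feedback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .cohort import CohortSpec, GroupSpec, ParamDist, default_presets
from .fitting import GridSpec
from .task import (
    CATEGORIES,
    Session,
    TaskConfig,
    Trial,
    play_session,
)

SESSION_COLUMNS = [
    "participant_id", "trial", "block", "stimulus", "trial_type",
    "sampled_category", "optimal_category", "response", "correct",
    "optimal", "feedback", "points_delta", "cumulative_points",
]

FIT_COLUMNS = [
    "participant_id", "alpha_gain", "alpha_loss", "beta", "r0", "lle", "n_ties",
]


class SessionFormatError(ValueError):
    """Raised for malformed session-log rows; the message cites the row."""


def sessions_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """Flatten sessions into the one-row-per-trial log layout."""
    rows = []
    for session in sessions:
        if session.records is not None:
            for rec in session.records:
                t = rec.trial
                rows.append(
                    (session.participant_id, t.index + 1, t.block + 1, t.stimulus,
                     t.trial_type, t.sampled_category, t.optimal_category,
                     rec.response, rec.correct, rec.optimal, rec.feedback,
                     rec.points_delta, rec.cumulative_points)
                )
        else:
            for t in session.trials:
                rows.append(
                    (session.participant_id, t.index + 1, t.block + 1, t.stimulus,
                     t.trial_type, t.sampled_category, t.optimal_category,
                     "", "", "", "", "", "")
                )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions_csv(sessions: list[Session], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(
    path: str | Path, config: TaskConfig | None = None
) -> list[Session]:
    """Load session logs, rebuilding outcomes from trials and responses.

    Raises :class:`SessionFormatError` citing the offending file row for
    malformed input, and an explicit error for an empty file.
    """
    if config is None:
        config = TaskConfig()
    frame = pd.read_csv(Path(path), dtype={"participant_id": str})
    if frame.empty:
        raise SessionFormatError(f"no session rows in {path}")
    missing = set(SESSION_COLUMNS[:8]) - set(frame.columns)
    if missing:
        raise SessionFormatError(f"missing columns in {path}: {sorted(missing)}")
    sessions = []
    for pid, group in frame.groupby("participant_id", sort=False):
        group = group.sort_values("trial")
        trials, responses = [], []
        has_responses = True
        for row_pos, row in group.iterrows():
            csv_row = row_pos + 2  # header + 1-based
            try:
                index = int(row["trial"]) - 1
                block = int(row["block"]) - 1
                stimulus = str(row["stimulus"])
                sampled = str(row["sampled_category"])
            except (TypeError, ValueError) as exc:
                raise SessionFormatError(f"row {csv_row}: {exc}") from exc
            if stimulus not in config.stimulus_roles:
                raise SessionFormatError(
                    f"row {csv_row}: unknown stimulus {stimulus!r}"
                )
            if sampled not in CATEGORIES:
                raise SessionFormatError(
                    f"row {csv_row}: bad sampled_category {sampled!r}"
                )
            trials.append(
                Trial(
                    index=index,
                    block=block,
                    stimulus=stimulus,
                    trial_type=config.trial_type(stimulus),
                    sampled_category=sampled,
                    optimal_category=config.majority_category(stimulus),
                )
            )
            response = row["response"]
            if pd.isna(response) or response == "":
                has_responses = False
            elif response not in CATEGORIES:
                raise SessionFormatError(f"row {csv_row}: bad response {response!r}")
            responses.append(response)
        schedule = Session(
            participant_id=str(pid), config=config, trials=tuple(trials)
        )
        sessions.append(
            play_session(schedule, responses) if has_responses else schedule
        )
    return sessions


def write_fit_table(fits: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fits[FIT_COLUMNS].to_csv(path, index=False)


def read_fit_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), dtype={"participant_id": str})
    missing = set(FIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"fit table {path} is missing columns: {sorted(missing)}")
    return frame


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), dtype={"participant_id": str})


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    grid: GridSpec = field(default_factory=GridSpec.default)
    cohort: CohortSpec | None = None
    out_dir: Path = Path("gainloss_out")
    master_seed: int = 0
    log_level: str = "INFO"


class ConfigError(ValueError):
    """Raised for invalid configuration; the message names the bad key."""


_TASK_KEYS = {
    "n_blocks", "trials_per_stimulus_per_block", "common_per_stimulus_per_block",
    "reward_points", "punishment_points", "initial_points",
}
_GRID_KEYS = {"alpha_step", "beta_step", "r0_step"}
_GROUP_KEYS = {"label", "n", "params", "covariates"}
_PARAM_KEYS = {"family", "center", "spread", "low", "high"}
_TOP_KEYS = {"task", "grid", "cohort", "out_dir", "master_seed", "log_level"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown config key: {where}{key}")


def _parse_group(raw: Mapping[str, Any], where: str, defaults: GroupSpec) -> GroupSpec:
    _check_keys(raw, _GROUP_KEYS, where)
    dists = dict(defaults.param_dists)
    for name, spec in (raw.get("params") or {}).items():
        if name not in dists:
            raise ConfigError(f"unknown config key: {where}params.{name}")
        _check_keys(spec, _PARAM_KEYS, f"{where}params.{name}.")
        base = dists[name]
        dists[name] = ParamDist(
            family=spec.get("family", base.family),
            center=float(spec.get("center", base.center)),
            spread=float(spec.get("spread", base.spread)),
            low=float(spec.get("low", base.low)),
            high=float(spec.get("high", base.high)),
        )
    return GroupSpec(
        label=str(raw.get("label", defaults.label)),
        n=int(raw.get("n", defaults.n)),
        param_dists=dists,
        covariates=raw.get("covariates", defaults.covariates),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration.

    Unknown keys fail loudly with the offending key path; omitted blocks
    fall back to the package defaults (standard task, estimation grid,
    two-group preset cohort).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_KEYS, "")
    task_raw = raw.get("task", {}) or {}
    _check_keys(task_raw, _TASK_KEYS, "task.")
    task = TaskConfig(**{k: int(v) for k, v in task_raw.items()})
    grid_raw = raw.get("grid", {}) or {}
    _check_keys(grid_raw, _GRID_KEYS, "grid.")
    grid = GridSpec.from_steps(
        alpha_step=float(grid_raw.get("alpha_step", 0.05)),
        beta_step=float(grid_raw.get("beta_step", 0.05)),
        r0_step=float(grid_raw.get("r0_step", 0.1)),
    )
    master_seed = int(raw.get("master_seed", 0))
    presets = default_presets(master_seed)
    cohort_raw = raw.get("cohort")
    if cohort_raw is None:
        cohort = CohortSpec(groups=presets.groups, task=task, master_seed=master_seed)
    else:
        _check_keys(cohort_raw, {"groups"}, "cohort.")
        groups_raw = cohort_raw.get("groups") or []
        if not groups_raw:
            raise ConfigError("cohort.groups must list at least one group")
        groups = tuple(
            _parse_group(
                g, f"cohort.groups[{i}].",
                presets.groups[min(i, len(presets.groups) - 1)],
            )
            for i, g in enumerate(groups_raw)
        )
        cohort = CohortSpec(groups=groups, task=task, master_seed=master_seed)
    return PipelineConfig(
        task=task,
        grid=grid,
        cohort=cohort,
        out_dir=Path(raw.get("out_dir", "gainloss_out")),
        master_seed=master_seed,
        log_level=str(raw.get("log_level", "INFO")),
    )
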