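"""Raw trial tables -> accuracy and precision (Weber fraction) matrices.

The pipeline: z-score outlier removal within each (participant, condition,
target) cell, per-cell reproduction statistics on the non-standardized
data, and assembly of the participants x targets Weber-fraction matrix
that every downstream analysis consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "CleaningReport",
    "WfMatrix",
    "remove_outliers",
    "reproduction_stats",
    "build_wf_matrix",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant_id", "condition", "target",
                 "response_count", "response_duration"]

_GROUP_KEYS = ["participant_id", "condition", "target"]


@dataclass
class CleaningReport:
    """Bookkeeping for the outlier-removal pass."""

    n_input_trials: int
    n_removed: int
    per_cell_removed: dict[tuple[str, float], int] = field(default_factory=dict)
    n_zero_sd_groups: int = 0

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input_trials if self.n_input_trials else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input_trials": self.n_input_trials,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            "n_zero_sd_groups": self.n_zero_sd_groups,
            "per_cell_removed": {
                f"{p}|{t:g}": int(c) for (p, t), c in self.per_cell_removed.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class WfMatrix:
    """Participants x targets matrix of Weber fractions.

    ``targets`` are strictly increasing stimulus levels (numerosities, or
    ranked duration levels for the duration task); ``values[i, j]`` is the
    Weber fraction of participant i at target j.  Zero cells (SD = 0 in
    the source trials) are legal but flagged at construction.
    """

    participants: list[str]
    targets: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.participants = list(self.participants)
        if self.values.shape != (len(self.participants), self.targets.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.participants)} participants x {self.targets.size} targets"
            )
        if np.any(np.diff(self.targets) <= 0):
            raise ValueError("targets must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("Wf values must be finite and non-negative")
        n_zero = int(np.sum(self.values == 0))
        if n_zero:
            logger.warning("WfMatrix %r: %d zero Wf cells (zero-SD source cells)",
                           self.condition, n_zero)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_targets(self) -> int:
        return int(self.targets.size)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:g}" for t in self.targets]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "participant_id", self.participants)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "WfMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "participant_id":
            raise ValueError("first column of a WfMatrix CSV must be participant_id")
        targets = np.array([float(c) for c in df.columns[1:]])
        return cls(participants=[str(p) for p in df["participant_id"]],
                   targets=targets,
                   values=df.iloc[:, 1:].to_numpy(dtype=float),
                   condition=condition)


def _validate_trials(trials: pd.DataFrame, response_col: str) -> pd.DataFrame:
    missing = [c for c in _GROUP_KEYS + [response_col] if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    return trials


def remove_outliers(
    trials: pd.DataFrame,
    z_threshold: float = 3.0,
    response_col: str = "response_count",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop trials whose response lies more than ``z_threshold`` SDs from
    its cell mean.

    z-scores are computed once per (participant, condition, target) cell
    with the sample SD — a single pass, no iteration.  Cells with zero SD
    have undefined z-scores; nothing is removed there and the count of such
    cells is logged in the report.
    """
    _validate_trials(trials, response_col)
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    x = trials[response_col].astype(float)
    grp = trials.groupby(_GROUP_KEYS, sort=False)[response_col]
    mu = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    zero_sd = (sd == 0) | sd.isna()
    keep = zero_sd | (z.abs() <= z_threshold)
    removed = trials.loc[~keep]
    per_cell: dict[tuple[str, float], int] = {}
    for (pid, _cond, target), sub in removed.groupby(_GROUP_KEYS, sort=False):
        per_cell[(str(pid), float(target))] = len(sub)
    report = CleaningReport(
        n_input_trials=len(trials),
        n_removed=int((~keep).sum()),
        per_cell_removed=per_cell,
        n_zero_sd_groups=int(trials.loc[zero_sd].groupby(_GROUP_KEYS).ngroups),
    )
    logger.info("outlier removal: %d/%d trials (%.2f%%) removed at |z| > %g",
                report.n_removed, report.n_input_trials,
                100 * report.fraction_removed, z_threshold)
    return trials.loc[keep].copy(), report


def reproduction_stats(
    trials: pd.DataFrame,
    response_col: str = "response_count",
) -> pd.DataFrame:
    """Per-(participant, condition, target) mean, SD and Weber fraction.

    Accuracy is the mean reproduction across trials; precision is the
    Weber fraction, sample SD (n-1) divided by the mean, computed on the
    raw (non-standardized) responses.  Cells with fewer than two trials
    cannot support an SD and are dropped with a log message.
    """
    _validate_trials(trials, response_col)
    g = trials.groupby(_GROUP_KEYS, sort=True)[response_col]
    stats = g.agg(n_trials="count", mean_response="mean", sd_response="std")
    stats = stats.reset_index()
    too_few = stats["n_trials"] < 2
    if too_few.any():
        logger.warning("%d cells with < 2 trials dropped from stats",
                       int(too_few.sum()))
        stats = stats.loc[~too_few]
    stats["wf"] = stats["sd_response"] / stats["mean_response"]
    return stats


def build_wf_matrix(stats: pd.DataFrame, condition: str) -> WfMatrix:
    """Assemble the Weber-fraction matrix for one condition.

    Participants are ordered by identifier, targets ascending.  A
    participant missing any target cell is excluded (the correlation
    analysis needs complete vectors) and logged.
    """
    sub = stats.loc[stats["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"no stats for condition {condition!r}")
    pivot = sub.pivot(index="participant_id", columns="target", values="wf")
    pivot = pivot.sort_index().sort_index(axis=1)
    incomplete = pivot.index[pivot.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("dropping %d participants with missing cells: %s",
                       len(incomplete), list(incomplete))
        pivot = pivot.drop(index=incomplete)
    if len(pivot) == 0:
        raise ValueError("no participant has a complete set of targets")
    return WfMatrix(
        participants=[str(p) for p in pivot.index],
        targets=pivot.columns.to_numpy(dtype=float),
        values=pivot.to_numpy(dtype=float),
        condition=condition,
    )
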