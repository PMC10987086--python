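"""Duration-matching control analysis.

Could the number task be solved by timing rather than counting?  The
control re-presents, for each participant, the eleven average response
durations they produced in the number task as auditory duration targets
to reproduce.  If duration were the stop criterion, duration
reproduction would have to be at least as precise as number
reproduction; the comparison here computes the paired per-participant
Weber fractions that answer that question.

Duration trials reuse the number-task pipeline unchanged (outlier
removal and SD/mean Weber fractions on ``response_duration``), and
cross-task pairing is by the rank of the stimulus level, since duration
targets are participant-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocessing import WfMatrix
from .synthetic_data import as_rng, _draw_counts, _truncated_normal

__all__ = [
    "load_reference_duration_targets",
    "derive_duration_targets",
    "simulate_duration_trials",
    "TaskPrecisionComparison",
    "compare_task_precision",
]

logger = logging.getLogger(__name__)


def load_reference_duration_targets() -> pd.DataFrame:
    """The packaged table of per-participant duration targets (seconds).

    Rows are stimulus ranks 1-11 (ordered by the source number target),
    columns participants S1-S9 of the duration-control subsample.
    """
    ref = resources.files("numchan").joinpath("data/duration_targets.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, index_col="rank")


def derive_duration_targets(number_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant duration targets from the number task.

    For every participant and number target, the mean response duration
    across (cleaned) trials; rows are ranks 1..n_targets ordered by the
    ascending number target, columns participants.  Participants missing
    any number target are dropped with a log message.
    """
    for col in ("participant_id", "target", "response_duration"):
        if col not in number_trials.columns:
            raise ValueError(f"number trial table lacks column {col!r}")
    means = (number_trials
             .groupby(["participant_id", "target"])["response_duration"]
             .mean()
             .unstack("target")
             .sort_index(axis=1))
    incomplete = means.index[means.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("dropping %d participants lacking durations at some "
                       "targets: %s", len(incomplete), list(incomplete))
        means = means.drop(index=incomplete)
    if len(means) == 0:
        raise ValueError("no participant has durations at every target")
    out = means.T.reset_index(drop=True)
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    out.columns.name = None
    return out


def simulate_duration_trials(
    duration_targets: pd.DataFrame,
    mean_wf: float = 0.24,
    observer_sd: float = 0.04,
    n_reps: int = 25,
    seed=None,
    rate_hz: float = 3.5,
) -> pd.DataFrame:
    """Simulate duration-reproduction trials for the control task.

    Each participant gets a duration Wf drawn from
    Normal(mean_wf, observer_sd) truncated positive, applied at every
    duration level (reproduced duration ~ Normal(target, wf * target),
    truncated positive).  The tap count is duration times the tapping
    rate.  Returns a long trial table with condition "duration".
    """
    rng = as_rng(seed)
    rows = []
    for pid in duration_targets.columns:
        wf = float(_truncated_normal(mean_wf, observer_sd, rng.random()))
        for target in duration_targets[pid]:
            dur = _truncated_normal(float(target), wf * float(target),
                                    rng.random(n_reps), lower=0.05)
            for d in dur:
                rows.append((str(pid), "duration", float(target),
                             int(max(1, round(d * rate_hz))), float(d)))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "target",
                                       "response_count", "response_duration"])


@dataclass
class TaskPrecisionComparison:
    """Paired per-participant Wf summary for the number vs duration tasks."""

    per_participant: pd.DataFrame  # participant_id, wf_number, wf_duration, difference
    mean_wf_number: float
    sd_wf_number: float
    mean_wf_duration: float
    sd_wf_duration: float

    @property
    def mean_difference(self) -> float:
        """Mean of (duration - number) Wf; positive means the number task
        is the more precise one."""
        return float(self.per_participant["difference"].mean())

    def to_dict(self) -> dict:
        return {
            "mean_wf_number": self.mean_wf_number,
            "sd_wf_number": self.sd_wf_number,
            "mean_wf_duration": self.mean_wf_duration,
            "sd_wf_duration": self.sd_wf_duration,
            "mean_difference": self.mean_difference,
            "per_participant": self.per_participant.to_dict(orient="records"),
        }


def compare_task_precision(number_wfm: WfMatrix,
                           duration_wfm: WfMatrix) -> TaskPrecisionComparison:
    """Paired precision comparison between the number and duration tasks.

    Each participant's Wf is averaged across stimulus levels (matched by
    rank: the k-th duration level derives from the k-th number target);
    the paired differences (duration - number) feed any external test.
    """
    if set(number_wfm.participants) != set(duration_wfm.participants):
        raise ValueError("participant sets differ between the two matrices")
    if number_wfm.n_targets != duration_wfm.n_targets:
        raise ValueError("the two matrices have different numbers of levels")
    n_by = dict(zip(number_wfm.participants, number_wfm.values.mean(axis=1)))
    d_by = dict(zip(duration_wfm.participants, duration_wfm.values.mean(axis=1)))
    pids = sorted(n_by)
    df = pd.DataFrame({
        "participant_id": pids,
        "wf_number": [n_by[p] for p in pids],
        "wf_duration": [d_by[p] for p in pids],
    })
    df["difference"] = df["wf_duration"] - df["wf_number"]
    return TaskPrecisionComparison(
        per_participant=df,
        mean_wf_number=float(df["wf_number"].mean()),
        sd_wf_number=float(df["wf_number"].std(ddof=1)),
        mean_wf_duration=float(df["wf_duration"].mean()),
        sd_wf_duration=float(df["wf_duration"].std(ddof=1)),
    )
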