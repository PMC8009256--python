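"""Maximal-run statistics over per-trial boolean criteria.

A run is a maximal streak of consecutive criterion-satisfying trials;
sub-runs are not counted (a run of 3 correct trials contributes nothing
to the totals for lengths 1 or 2).  Runs are computed within blocks by
default, since the recalibration pause between blocks breaks a streak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import align_events

__all__ = ["RunTable", "maximal_runs", "trial_flags"]


@dataclass
class RunTable:
    """Counts of maximal runs by length.

    Invariant: sum(length x count) plus the number of criterion-false
    trials equals the total trial count.
    """

    counts: dict  # length -> number of maximal runs of that length
    longest: int
    total_trials: int
    criterion: str = ""

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame(
            {"run_length": lengths, "count": [self.counts[k] for k in lengths]}
        )

    def merge(self, other: "RunTable") -> "RunTable":
        counts = dict(self.counts)
        for k, v in other.counts.items():
            counts[k] = counts.get(k, 0) + v
        return RunTable(
            counts=counts,
            longest=max(self.longest, other.longest),
            total_trials=self.total_trials + other.total_trials,
            criterion=self.criterion or other.criterion,
        )


def maximal_runs(flags, criterion: str = "") -> RunTable:
    """Tabulate maximal runs of True in a boolean sequence.

    An empty sequence (or one with no True) yields an empty table with
    longest run 0.
    """
    flags = np.asarray(flags, dtype=bool)
    counts: dict[int, int] = {}
    streak = 0
    for f in flags:
        if f:
            streak += 1
        elif streak:
            counts[streak] = counts.get(streak, 0) + 1
            streak = 0
    if streak:
        counts[streak] = counts.get(streak, 0) + 1
    return RunTable(
        counts=counts,
        longest=max(counts) if counts else 0,
        total_trials=int(len(flags)),
        criterion=criterion,
    )


def trial_flags(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    criterion: str,
    first_sacc: pd.DataFrame,
    interval: tuple[float, float] = (-200.0, 800.0),
    window_half_deg: float = 1.5,
) -> np.ndarray:
    """Per-trial boolean criterion sequence.

    ``"correct"``: the first saccade after trial onset landed inside the
    3x3-degree window (unresolved trials count as incorrect and should be
    reported in QC).  ``"microsaccade_free"``: no microsaccade onset in the
    trial's anchored (-200, 800) ms interval.
    """
    if criterion == "correct":
        return (
            first_sacc["resolved"].to_numpy() & first_sacc["correct"].to_numpy()
        )
    if criterion == "microsaccade_free":
        raster = align_events(trials, events, "trial_onset", interval)
        flags = np.ones(len(trials), dtype=bool)
        kt = raster.kind_times("microsaccade_start")
        if len(kt):
            flags[np.unique(kt["trial_pos"].to_numpy())] = False
        return flags
    raise ValueError("criterion must be 'correct' or 'microsaccade_free'")


def run_table_per_block(
    trials: pd.DataFrame, flags: np.ndarray, criterion: str = "", span_blocks: bool = False
) -> RunTable:
    """Run table computed within blocks (default) or across the whole session."""
    if span_blocks or "block" not in trials.columns:
        return maximal_runs(flags, criterion)
    table = RunTable({}, 0, 0, criterion)
    for _, idx in trials.groupby(
        ["subject", "block"] if "subject" in trials.columns else "block"
    ).indices.items():
        table = table.merge(maximal_runs(flags[np.sort(idx)], criterion))
    return table
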