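"""Exclusion and trial-filtering rules, and per-participant summaries.

Rules: participants whose average task performance deviates from the group
median by at least three scaled MADs are excluded; the first trial of every
block is dropped; within each participant x condition cell, trials whose
force error is more than three scaled MADs from the cell median are
removed.  The scaled MAD uses the 1.4826 Gaussian-consistency constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Counts logged by the preprocessing stages."""

    excluded_participants: list = field(default_factory=list)
    first_trials_removed: int = 0
    mad_removed: dict = field(default_factory=dict)   # (pid, effort, reward) -> count

    def to_dict(self) -> dict:
        return {
            "excluded_participants": list(self.excluded_participants),
            "first_trials_removed": self.first_trials_removed,
            "mad_removed": {"|".join(map(str, k)): v for k, v in self.mad_removed.items()},
            "mad_removed_total": int(sum(self.mad_removed.values())),
        }


def scaled_mad(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return MAD_SCALE * float(np.median(np.abs(values - np.median(values))))


def exclude_participants(performance: pd.Series, k: float = 3.0,
                         report: PreprocessReport | None = None) -> tuple[list, list]:
    """Split participant ids into (kept, excluded) by the group-level
    scaled-MAD rule on average task performance.

    ``performance`` maps participant id -> mean absolute force error.
    Deviations >= k scaled MADs from the group median are excluded.  A
    degenerate zero MAD disables the rule with a warning.
    """
    if len(performance) < 3:
        raise ValueError("need at least 3 participants for group-level exclusion")
    values = performance.to_numpy(dtype=float)
    mad = scaled_mad(values)
    if mad == 0.0:
        log.warning("group MAD is zero; no participants excluded")
        return list(performance.index), []
    dev = np.abs(values - np.median(values))
    excluded = list(performance.index[dev >= k * mad])
    kept = list(performance.index[dev < k * mad])
    if excluded:
        log.info("excluded %d participants: %s", len(excluded), excluded)
    if report is not None:
        report.excluded_participants = excluded
    return kept, excluded


def participant_mean_abs_force_error(trials: pd.DataFrame) -> pd.Series:
    """Average task performance per participant: mean |force error| (% max
    force) over all trials."""
    return trials.groupby("participant_id")["force_error"].apply(
        lambda s: float(np.mean(np.abs(s))))


def drop_first_trials(trials: pd.DataFrame,
                      report: PreprocessReport | None = None) -> pd.DataFrame:
    """Remove the first trial of every participant x block."""
    if trials.empty:
        return trials.copy()
    mask = trials["trial_in_block"] != 1
    if report is not None:
        report.first_trials_removed = int((~mask).sum())
    return trials.loc[mask].reset_index(drop=True)


def mad_filter_force_errors(trials: pd.DataFrame, k: float = 3.0,
                            report: PreprocessReport | None = None) -> pd.DataFrame:
    """Remove trials whose force error is more than ``k`` scaled MADs from
    the participant x condition median; zero-MAD cells are left untouched."""
    if trials.empty:
        return trials.copy()
    keep = np.ones(len(trials), dtype=bool)
    counts: dict = {}
    for key, idx in trials.groupby(["participant_id", "effort", "reward"]).groups.items():
        errs = trials.loc[idx, "force_error"].to_numpy(dtype=float)
        mad = scaled_mad(errs)
        if mad == 0.0:
            log.warning("zero MAD in cell %s; filter disabled for this cell", key)
            continue
        out = np.abs(errs - np.median(errs)) > k * mad
        keep[trials.index.get_indexer(idx)[out]] = False
        counts[key] = int(out.sum())
    if report is not None:
        report.mad_removed = counts
    return trials.loc[keep].reset_index(drop=True)


def summarize_performance(trials: pd.DataFrame) -> dict:
    """Per-cell accuracy/variability and per-participant performance SD.

    Returns ``{"cells": DataFrame, "participant_sd": Series}`` where cells
    carry the median and interquartile range of force error (% max force)
    per participant x condition (type-7 linear-interpolation quantiles) and
    ``participant_sd`` is the SD of performance error (px) over each
    participant's basic trials, all conditions pooled.
    """
    grouped = trials.groupby(["participant_id", "effort", "reward"])["force_error"]
    cells = grouped.agg(
        median_force_error="median",
        iqr_force_error=lambda s: float(np.quantile(s, 0.75) - np.quantile(s, 0.25)),
        n_trials="size",
    ).reset_index()
    if (cells["n_trials"] == 0).any():
        log.warning("empty participant x condition cell in performance summary")
    basic = trials[trials["trial_type"] == "basic"]
    participant_sd = basic.groupby("participant_id")["performance_error"].std(ddof=1)
    return {"cells": cells, "participant_sd": participant_sd}


def preprocess(trials: pd.DataFrame, k: float = 3.0) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing chain: participant exclusion, first-trial removal,
    per-cell MAD filtering.  Returns the filtered table and a report."""
    report = PreprocessReport()
    perf = participant_mean_abs_force_error(trials)
    kept, _ = exclude_participants(perf, k=k, report=report)
    trials = trials[trials["participant_id"].isin(kept)]
    trials = drop_first_trials(trials, report=report)
    trials = mad_filter_force_errors(trials, k=k, report=report)
    return trials, report
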