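"""Trial scoring and performance summaries.

A sequence execution counts as correct when the buttons were pressed in
exactly the target order *and* the movement time — the interval between the
first and the last press — was strictly shorter than the threshold
(2.5 s by default). Movement time enters the summaries only for correct
trials. Trials with a wrong number of presses are scored incorrect rather
than dropped, so the accuracy denominator is always the number of trials.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import SEQUENCES

logger = logging.getLogger(__name__)


@dataclass
class ScoringRule:
    mt_threshold_s: float = 2.5
    sequence_length: int = 5

    def __post_init__(self):
        if self.mt_threshold_s <= 0:
            raise ValueError("movement-time threshold must be positive")


@dataclass
class TrialScore:
    correct: bool
    movement_time_s: float  # t_last - t_first, also recorded for errors


def score_trial(presses, target, rule: ScoringRule | None = None) -> TrialScore:
    """Score one trial from its ordered (button, time) press events."""
    rule = rule or ScoringRule()
    if not presses:
        raise ValueError("trial has no press events")
    buttons = [b for b, _ in presses]
    times = [t for _, t in presses]
    for b in buttons:
        if not (isinstance(b, (int, np.integer)) and 1 <= b <= 5):
            raise ValueError(f"unparsable button value {b!r}")
    if any(not math.isfinite(t) for t in times):
        raise ValueError("unparsable press time")
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("press times must be nondecreasing")
    movement_time = times[-1] - times[0]
    correct = (
        len(presses) == rule.sequence_length
        and tuple(buttons) == tuple(target)
        and movement_time < rule.mt_threshold_s  # strictly shorter
    )
    return TrialScore(bool(correct), float(movement_time))


def score_log(log: pd.DataFrame, targets: dict | None = None,
              rule: ScoringRule | None = None) -> pd.DataFrame:
    """Score every row of a trial log (press1..5 / t1..5 columns)."""
    rule = rule or ScoringRule()
    targets = targets or SEQUENCES
    n = rule.sequence_length
    out = log[["subject", "run", "trial", "class"]].copy()
    correct = np.empty(len(log), dtype=bool)
    mt = np.empty(len(log))
    for i, row in enumerate(log.to_dict("records")):
        presses = [(int(row[f"press{k+1}"]), float(row[f"t{k+1}"]))
                   for k in range(n)]
        sc = score_trial(presses, targets[int(row["class"])], rule)
        correct[i] = sc.correct
        mt[i] = sc.movement_time_s
    out["correct"] = correct
    out["movement_time_s"] = mt
    return out


def summarize_performance(log: pd.DataFrame, targets: dict | None = None,
                          rule: ScoringRule | None = None) -> pd.DataFrame:
    """Per (subject, run, class): accuracy and mean MT over correct trials.

    The movement-time cell is NaN when a group has no correct trials.
    """
    if log.empty:
        raise ValueError("empty trial log")
    scored = score_log(log, targets, rule)
    rows = []
    for (s, r, c), grp in scored.groupby(["subject", "run", "class"],
                                         sort=True):
        corr = grp["correct"]
        if not corr.any():
            logger.warning("no correct trials for subject %s run %s class %s",
                           s, r, c)
        rows.append({
            "subject": s, "run": r, "class": c,
            "n_trials": len(grp),
            "accuracy": corr.mean(),
            "mean_mt_s": grp.loc[corr, "movement_time_s"].mean()
            if corr.any() else np.nan,
        })
    return pd.DataFrame(rows)


def write_performance_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
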