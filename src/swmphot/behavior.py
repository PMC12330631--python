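"""Scoring of delayed non-match-to-sample (DNMS) training performance.

Mice run 10 T-maze trials per daily session; training continues until a
criterion of three consecutive days at >= 70% correct, capped at 15 days.
These routines score accuracy, days-to-criterion, early/late trial splits
and the correlation of distal-delay calcium scores with overall accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class TrainingRecord:
    """Per-mouse daily trial outcomes (1 = correct, 0 = incorrect)."""

    outcomes: dict                      # mouse_id -> list of per-day lists
    groups: dict = field(default_factory=dict)   # mouse_id -> group label
    trials_per_day: int = 10
    max_days: int = 15

    def validate(self) -> None:
        for m, days in self.outcomes.items():
            if len(days) > self.max_days:
                raise ValueError(f"mouse {m}: more than {self.max_days} days")
            for d, trials in enumerate(days):
                if len(trials) != self.trials_per_day:
                    raise ValueError(
                        f"mouse {m} day {d + 1}: expected "
                        f"{self.trials_per_day} trials, got {len(trials)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "TrainingRecord":
        """Build from a tidy table with mouse_id, day, trial, outcome columns."""
        outcomes = {}
        groups = {}
        for m, sub in df.groupby("mouse_id"):
            days = []
            for _, day_df in sub.sort_values(["day", "trial"]).groupby("day"):
                days.append(day_df["outcome"].astype(int).tolist())
            outcomes[m] = days
            if "group" in df.columns:
                groups[m] = sub["group"].iloc[0]
        return cls(outcomes=outcomes, groups=groups, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, days in self.outcomes.items():
            for d, trials in enumerate(days):
                for t, o in enumerate(trials):
                    rows.append({"mouse_id": m, "day": d + 1, "trial": t + 1,
                                 "outcome": int(o),
                                 "group": self.groups.get(m)})
        return pd.DataFrame(rows)


def accuracy_by_day(day_outcomes) -> np.ndarray:
    """Fraction of correct trials per day."""
    accs = []
    for trials in day_outcomes:
        if len(trials) == 0:
            raise ValueError("empty training day")
        accs.append(float(np.mean(trials)))
    if not accs:
        raise ValueError("no training days")
    return np.array(accs)


def days_to_criterion(accuracies, threshold: float = 0.70,
                      consecutive: int = 3, max_days: int = 15) -> dict:
    """First day (1-based) completing the required run of criterion days.

    A mouse perfect from day 1 scores ``consecutive``. Mice that never reach
    criterion are right-censored at ``max_days`` with ``reached = False``.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size > max_days:
        raise ValueError("more accuracy values than the day cap")
    run = 0
    for d, a in enumerate(accuracies, start=1):
        run = run + 1 if a >= threshold else 0
        if run >= consecutive:
            return {"days": d, "reached": True}
    return {"days": max_days, "reached": False}


def early_late_split(n_trials: int):
    """Indices (0-based) of the first and final thirds of a mouse's trials.

    Both sets have floor(n/3) trials; they are disjoint and order-preserving.
    Mice with fewer than 3 trials cannot be split.
    """
    if n_trials < 3:
        raise ValueError("need at least 3 trials to split early/late")
    k = n_trials // 3
    early = np.arange(k)
    late = np.arange(n_trials - k, n_trials)
    return early, late


def split_trials_early_late(trials_per_mouse: dict):
    """Apply the early/late split per mouse; mice with < 3 trials are
    excluded with a warning. Returns {mouse: (early_idx, late_idx)}."""
    out = {}
    for m, n in trials_per_mouse.items():
        try:
            out[m] = early_late_split(int(n))
        except ValueError:
            warnings.warn(f"mouse {m}: fewer than 3 trials; excluded")
    return out


def correlate_with_accuracy(distal_scores, accuracies) -> dict:
    """Pearson correlation of per-mouse distal-delay scores with overall
    training accuracy. Returns r, r^2, the OLS slope and n."""
    x = np.asarray(distal_scores, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "r2": np.nan, "slope": np.nan, "n": int(x.size)}
    r = float(pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return {"r": r, "r2": r * r, "slope": slope, "n": int(x.size)}
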