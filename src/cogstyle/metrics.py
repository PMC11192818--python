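"""Per-level performance metrics and per-participant summaries.

Four overall performance measures: whether a level was solved (solution
rate), time from level start to the solving attempt, number of attempts,
and thinking time -- the latency to the first attempt and the mean latency
between consecutive attempts.  Group comparisons condition on successfully
solved levels (``solved_only``), since behavior on unsolved levels may
reflect frustration rather than planning; the flag exposes the
all-levels variant as a robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogstyle.logdata import Dataset, LevelPlay, MotorTrial


@dataclass(frozen=True)
class LevelMetrics:
    participant_id: str
    level_id: str
    solved: bool
    n_attempts: int
    time_to_first: float
    time_to_solution: float | None  # defined for solved plays only
    mean_gap: float | None          # defined when n_attempts >= 2


@dataclass(frozen=True)
class MotorSummary:
    """Medians across the ten motor trials (median resists outlier trials)."""
    participant_id: str
    median_rt: float
    median_error: float


def compute_level_metrics(play: LevelPlay) -> LevelMetrics:
    """Metrics of one play.

    ``time_to_solution`` is the timestamp of the solving (last) attempt;
    ``mean_gap`` is the mean of consecutive-attempt time differences,
    equivalently ``(t_last - t_first) / (n_attempts - 1)``.
    """
    if not play.attempts:
        raise ValueError(
            f"{play.participant_id}/{play.level_id}: no attempts recorded")
    ts = [a.t for a in play.attempts]
    n = len(ts)
    return LevelMetrics(
        participant_id=play.participant_id,
        level_id=play.level_id,
        solved=play.solved,
        n_attempts=n,
        time_to_first=ts[0],
        time_to_solution=ts[-1] if play.solved else None,
        mean_gap=(ts[-1] - ts[0]) / (n - 1) if n >= 2 else None,
    )


def level_metrics_frame(dataset: Dataset) -> pd.DataFrame:
    """One row per participant x level, with group labels attached.

    Plays with zero attempts count as unsolved exposures: they enter the
    solution-rate denominator (the time bound guarantees the participant
    saw the level) but carry NaN times.
    """
    rows = []
    for play in dataset.plays:
        prof = dataset.participants[play.participant_id]
        if play.attempts:
            m = compute_level_metrics(play)
            rows.append((m.participant_id, prof.age_group, prof.limb_group,
                         prof.age_years, m.level_id, m.solved, m.n_attempts,
                         m.time_to_first,
                         np.nan if m.time_to_solution is None else m.time_to_solution,
                         np.nan if m.mean_gap is None else m.mean_gap))
        else:
            rows.append((play.participant_id, prof.age_group, prof.limb_group,
                         prof.age_years, play.level_id, False, 0,
                         np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=[
        "participant_id", "age_group", "limb_group", "age_years", "level_id",
        "solved", "n_attempts", "time_to_first", "time_to_solution", "mean_gap"])


def aggregate_participant(metrics, solved_only: bool = True) -> pd.DataFrame:
    """Per-participant summary of level metrics.

    ``solution_rate`` is solved levels over levels played; the remaining
    metrics are averaged over solved levels when ``solved_only`` is true,
    over all levels otherwise.  Accepts a frame from
    :func:`level_metrics_frame` or an iterable of :class:`LevelMetrics`.
    """
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.DataFrame([{
            "participant_id": m.participant_id, "level_id": m.level_id,
            "solved": m.solved, "n_attempts": m.n_attempts,
            "time_to_first": m.time_to_first,
            "time_to_solution": math.nan if m.time_to_solution is None
            else m.time_to_solution,
            "mean_gap": math.nan if m.mean_gap is None else m.mean_gap,
        } for m in metrics])
    if len(metrics) == 0:
        raise ValueError("no level metrics to aggregate")

    out = []
    value_cols = ["n_attempts", "time_to_first", "time_to_solution", "mean_gap"]
    for pid, g in metrics.groupby("participant_id", sort=True):
        sel = g[g["solved"]] if solved_only else g
        row = {"participant_id": pid,
               "n_levels": len(g),
               "solution_rate": float(g["solved"].mean())}
        for col in value_cols:
            row[col] = float(sel[col].mean()) if len(sel) else math.nan
        out.append(row)
    return pd.DataFrame(out)


def motor_summary(trials: list[MotorTrial]) -> MotorSummary:
    """Component-wise medians over exactly ten motor trials."""
    if len(trials) != 10:
        raise ValueError(f"expected 10 motor trials, got {len(trials)}")
    pids = {t.participant_id for t in trials}
    if len(pids) != 1:
        raise ValueError("trials must all belong to one participant")
    return MotorSummary(
        participant_id=next(iter(pids)),
        median_rt=float(np.median([t.rt for t in trials])),
        median_error=float(np.median([t.click_error for t in trials])),
    )


def motor_summary_frame(dataset: Dataset) -> pd.DataFrame:
    """Per-participant motor medians with group labels."""
    by_pid: dict[str, list[MotorTrial]] = {}
    for t in dataset.motor:
        by_pid.setdefault(t.participant_id, []).append(t)
    rows = []
    for pid in sorted(by_pid):
        s = motor_summary(by_pid[pid])
        prof = dataset.participants[pid]
        rows.append((pid, prof.age_group, prof.limb_group, prof.age_years,
                     s.median_rt, s.median_error))
    return pd.DataFrame(rows, columns=[
        "participant_id", "age_group", "limb_group", "age_years",
        "median_rt", "median_error"])
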