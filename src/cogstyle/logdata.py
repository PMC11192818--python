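"""Data model, CSV readers/writers, and validation for game and motor logs.

An *attempt* is a single tool placement: which tool, where in the 600x600 px
play area, and when (seconds since level start).  Attempts are grouped into
:class:`LevelPlay` objects (one participant on one level, ordered by attempt
index, with a solved flag).  The motor pre-test contributes ten speeded
point-and-click trials per participant (five at each of two target
distances).

Coordinates use the screen convention: origin at the top-left of the play
area, ``y`` increasing downward, real-valued pixels.  Timestamps are stored
in seconds relative to level start; files carrying milliseconds (``t_ms`` /
``end_t_ms`` columns) are converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLAY_AREA_PX = 600.0
DEFAULT_TIME_BOUND_S = 60.0

AGE_GROUPS = ("child", "adult")
LIMB_GROUPS = ("LD", "NLD")
MOTOR_DISTANCES = (150, 250)
TRIALS_PER_DISTANCE = 5

ATTEMPT_COLUMNS = [
    "participant_id", "age_group", "limb_group", "age_years", "level_id",
    "attempt_index", "tool_id", "x", "y", "t_s", "solved", "end_t_s",
]
MOTOR_COLUMNS = [
    "participant_id", "trial_index", "distance_px", "rt_s", "click_error_px",
]


class FormatError(ValueError):
    """A file does not have the expected columns or encoding."""


class ValidationError(ValueError):
    """Records violate a domain invariant (names the offending unit)."""


@dataclass(frozen=True)
class Participant:
    participant_id: str
    age_group: str
    limb_group: str
    age_years: float

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"participant {self.participant_id}: age_group must be one of "
                f"{AGE_GROUPS}, got {self.age_group!r}")
        if self.limb_group not in LIMB_GROUPS:
            raise ValidationError(
                f"participant {self.participant_id}: limb_group must be one of "
                f"{LIMB_GROUPS}, got {self.limb_group!r}")
        if not self.age_years > 0:
            raise ValidationError(
                f"participant {self.participant_id}: age_years must be positive")

    @property
    def group(self) -> str:
        """Combined cell label, e.g. ``'adult-NLD'``."""
        return f"{self.age_group}-{self.limb_group}"


@dataclass(frozen=True)
class AttemptRecord:
    """One tool placement: who, which level, which tool, where, when."""

    participant_id: str
    level_id: str
    attempt_index: int
    tool_id: str
    x: float
    y: float
    t: float  # seconds since level start

    def __post_init__(self) -> None:
        if self.attempt_index < 1:
            raise ValidationError(
                f"{self.participant_id}/{self.level_id}: attempt_index must be >= 1")
        if not (0.0 <= self.x <= PLAY_AREA_PX and 0.0 <= self.y <= PLAY_AREA_PX):
            raise ValidationError(
                f"{self.participant_id}/{self.level_id} attempt "
                f"{self.attempt_index}: placement ({self.x}, {self.y}) outside "
                f"the {PLAY_AREA_PX:.0f}x{PLAY_AREA_PX:.0f} px play area")
        if self.t < 0:
            raise ValidationError(
                f"{self.participant_id}/{self.level_id} attempt "
                f"{self.attempt_index}: negative timestamp")


@dataclass(frozen=True)
class LevelPlay:
    """Ordered attempts of one participant on one level."""

    participant_id: str
    level_id: str
    attempts: tuple[AttemptRecord, ...]
    solved: bool
    end_t: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "attempts", tuple(self.attempts))
        who = f"{self.participant_id}/{self.level_id}"
        if self.solved and not self.attempts:
            raise ValidationError(f"{who}: solved play with no attempts")
        idx = [a.attempt_index for a in self.attempts]
        if idx != list(range(1, len(idx) + 1)):
            raise ValidationError(
                f"{who}: attempt_index must run 1..n without gaps, got {idx}")
        ts = [a.t for a in self.attempts]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError(f"{who}: timestamps not strictly increasing: {ts}")
        if self.attempts and self.end_t < self.attempts[-1].t:
            raise ValidationError(f"{who}: end_t precedes last attempt")

    @property
    def n_attempts(self) -> int:
        return len(self.attempts)


@dataclass(frozen=True)
class MotorTrial:
    participant_id: str
    trial_index: int
    distance_px: int
    rt: float
    click_error: float

    def __post_init__(self) -> None:
        who = f"participant {self.participant_id} motor trial {self.trial_index}"
        if not 1 <= self.trial_index <= 10:
            raise ValidationError(f"{who}: trial_index must be in 1..10")
        if self.distance_px not in MOTOR_DISTANCES:
            raise ValidationError(
                f"{who}: distance_px must be one of {MOTOR_DISTANCES}")
        if self.rt <= 0:
            raise ValidationError(f"{who}: rt must be positive")
        if self.click_error < 0:
            raise ValidationError(f"{who}: click_error must be >= 0")


@dataclass
class Dataset:
    """A study: participant profiles plus their plays and motor trials."""

    participants: dict[str, Participant] = field(default_factory=dict)
    plays: list[LevelPlay] = field(default_factory=list)
    motor: list[MotorTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._sort()
        self.validate()

    def _sort(self) -> None:
        self.plays.sort(key=lambda p: (p.participant_id, p.level_id))
        self.motor.sort(key=lambda m: (m.participant_id, m.trial_index))

    def validate(self) -> None:
        for play in self.plays:
            if play.participant_id not in self.participants:
                raise ValidationError(
                    f"play {play.participant_id}/{play.level_id} references "
                    "an unknown participant")
        for trial in self.motor:
            if trial.participant_id not in self.participants:
                raise ValidationError(
                    f"motor trial for unknown participant {trial.participant_id}")
        by_pid: dict[str, list[MotorTrial]] = {}
        for trial in self.motor:
            by_pid.setdefault(trial.participant_id, []).append(trial)
        for pid, trials in by_pid.items():
            if len(trials) != 10:
                raise ValidationError(
                    f"participant {pid}: expected 10 motor trials, got {len(trials)}")
            for d in MOTOR_DISTANCES:
                n = sum(t.distance_px == d for t in trials)
                if n != TRIALS_PER_DISTANCE:
                    raise ValidationError(
                        f"participant {pid}: expected {TRIALS_PER_DISTANCE} "
                        f"trials at {d} px, got {n}")

    # ---- views -----------------------------------------------------------

    def attempts_frame(self) -> pd.DataFrame:
        """All attempts as one row per placement (long format)."""
        rows = []
        for play in self.plays:
            prof = self.participants[play.participant_id]
            for a in play.attempts:
                rows.append((a.participant_id, prof.age_group, prof.limb_group,
                             prof.age_years, a.level_id, a.attempt_index,
                             a.tool_id, a.x, a.y, a.t, play.solved, play.end_t))
        return pd.DataFrame(rows, columns=ATTEMPT_COLUMNS)

    def motor_frame(self) -> pd.DataFrame:
        rows = [(m.participant_id, m.trial_index, m.distance_px, m.rt,
                 m.click_error) for m in self.motor]
        return pd.DataFrame(rows, columns=MOTOR_COLUMNS)

    def merge(self, other: "Dataset") -> "Dataset":
        """Union of two datasets with disjoint participant ids."""
        overlap = self.participants.keys() & other.participants.keys()
        if overlap:
            raise ValidationError(f"participants present in both datasets: {sorted(overlap)}")
        return Dataset(participants={**self.participants, **other.participants},
                       plays=self.plays + other.plays,
                       motor=self.motor + other.motor)

    def subset(self, participant_ids: Iterable[str]) -> "Dataset":
        keep = set(participant_ids)
        return Dataset(
            participants={p: v for p, v in self.participants.items() if p in keep},
            plays=[p for p in self.plays if p.participant_id in keep],
            motor=[m for m in self.motor if m.participant_id in keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (self.participants == other.participants
                and self.plays == other.plays and self.motor == other.motor)


# ---- readers / writers ---------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _to_seconds(df: pd.DataFrame, s_col: str, ms_col: str, path: str) -> pd.Series:
    if s_col in df.columns:
        return df[s_col].astype(float)
    if ms_col in df.columns:
        return df[ms_col].astype(float) / 1000.0
    raise FormatError(f"{path}: missing column(s) ['{s_col}'] (or '{ms_col}')")


def read_attempt_log(path: str | os.PathLike) -> Dataset:
    """Read an attempts CSV into a validated :class:`Dataset` (plays part).

    Row order never matters: records are re-sorted by participant, level and
    attempt index before validation, so a shuffled file yields an identical
    dataset.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    base = [c for c in ATTEMPT_COLUMNS if c not in ("t_s", "end_t_s")]
    _require_columns(df, base, path)
    if len(df) == 0:
        return Dataset()
    df = df.copy()
    df["t_s"] = _to_seconds(df, "t_s", "t_ms", path)
    df["end_t_s"] = _to_seconds(df, "end_t_s", "end_t_ms", path)
    df = df.sort_values(["participant_id", "level_id", "attempt_index"],
                        kind="mergesort")

    participants: dict[str, Participant] = {}
    plays: list[LevelPlay] = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        labels = pdf[["age_group", "limb_group", "age_years"]].drop_duplicates()
        if len(labels) > 1:
            raise ValidationError(
                f"participant {pid}: group labels/age differ across rows")
        participants[str(pid)] = Participant(
            str(pid), str(pdf["age_group"].iloc[0]), str(pdf["limb_group"].iloc[0]),
            float(pdf["age_years"].iloc[0]))
        for lid, ldf in pdf.groupby("level_id", sort=True):
            if ldf["solved"].astype(bool).nunique() > 1 or ldf["end_t_s"].nunique() > 1:
                raise ValidationError(
                    f"{pid}/{lid}: solved/end_t must be constant within a play")
            attempts = tuple(
                AttemptRecord(str(pid), str(lid), int(r.attempt_index),
                              str(r.tool_id), float(r.x), float(r.y), float(r.t_s))
                for r in ldf.itertuples())
            plays.append(LevelPlay(str(pid), str(lid), attempts,
                                   bool(ldf["solved"].iloc[0]),
                                   float(ldf["end_t_s"].iloc[0])))
    return Dataset(participants=participants, plays=plays)


def read_motor_log(path: str | os.PathLike,
                   participants: dict[str, Participant] | None = None) -> Dataset:
    """Read a motor pre-test CSV (10 trials per participant, 5 per distance).

    When ``participants`` is omitted, minimal placeholder profiles are
    created so the fragment validates stand-alone.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    _require_columns(df, [c for c in MOTOR_COLUMNS if c != "rt_s"], path)
    if "rt_s" not in df.columns and "rt_ms" not in df.columns:
        raise FormatError(f"{path}: missing column(s) ['rt_s']")
    if len(df) == 0:
        return Dataset(participants=dict(participants or {}))
    df = df.copy()
    df["rt_s"] = _to_seconds(df, "rt_s", "rt_ms", path)
    trials = [MotorTrial(str(r.participant_id), int(r.trial_index),
                         int(r.distance_px), float(r.rt_s), float(r.click_error_px))
              for r in df.itertuples()]
    if participants is None:
        participants = {t.participant_id: Participant(t.participant_id, "adult", "NLD", 30.0)
                        for t in trials}
    return Dataset(participants=dict(participants), motor=trials)


def read_dataset(directory: str | os.PathLike) -> Dataset:
    """Read ``attempts.csv`` and (if present) ``motor.csv`` from a directory."""
    directory = os.fspath(directory)
    ds = read_attempt_log(os.path.join(directory, "attempts.csv"))
    motor_path = os.path.join(directory, "motor.csv")
    if os.path.exists(motor_path):
        motor = read_motor_log(motor_path, participants=ds.participants)
        ds = Dataset(participants=ds.participants, plays=ds.plays,
                     motor=motor.motor)
    return ds


def write_dataset(dataset: Dataset, directory: str | os.PathLike) -> dict[str, str]:
    """Write ``attempts.csv`` and ``motor.csv``; round-trips exactly.

    Returns a mapping of logical names to the file paths written.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {}
    apath = os.path.join(directory, "attempts.csv")
    # %.17g keeps doubles exact across the round trip
    dataset.attempts_frame().to_csv(apath, index=False, float_format="%.17g")
    paths["attempts"] = apath
    mpath = os.path.join(directory, "motor.csv")
    dataset.motor_frame().to_csv(mpath, index=False, float_format="%.17g")
    paths["motor"] = mpath
    return paths
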