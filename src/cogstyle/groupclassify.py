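"""Leave-one-out classification of first attempts by group likelihood.

For each participant and level, the participant's *first* attempt is scored
by the relative likelihood s = p_own / (p_own + p_other), where p_own is
the attempt's density under a distribution built from the first attempts of
all *other* members of the participant's group, and p_other under the
contrasted group's distribution.  A density factorizes as a Laplace-smoothed
categorical over tool identities times a product-Gaussian kernel density
over (x, y), with per-dimension plug-in bandwidth h_d = sd_d * m^(-1/6)
for m training points.  Scores above 0.5 classify the attempt into the
correct group; 0.5 is chance.  Per-participant mean scores are tested
against 0.5 with a two-sided one-sample t-test across participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cogstyle.logdata import Dataset

_MIN_BANDWIDTH_PX = 1.0     # fallback when training placements are degenerate
_DENSITY_FLOOR = 1e-12      # avoids 0/0 in the relative likelihood


class TooFewContributors(ValueError):
    """A density would be built from fewer than two participants."""


@dataclass
class GroupDensity:
    """Density over (tool, x, y) built from one group's first attempts."""

    level_id: str
    group: str
    tool_probs: dict[str, float]
    train_xy: np.ndarray          # (m, 2)
    bandwidths: np.ndarray        # (2,)
    n_participants: int

    def spatial_density(self, x: float, y: float) -> float:
        """Mean of product Gaussian kernels at (x, y); integrates to 1."""
        hx, hy = self.bandwidths
        zx = (x - self.train_xy[:, 0]) / hx
        zy = (y - self.train_xy[:, 1]) / hy
        k = np.exp(-0.5 * (zx * zx + zy * zy)) / (2.0 * math.pi * hx * hy)
        return float(np.mean(k))

    def logpdf_grid(self, n: int = 80) -> tuple[np.ndarray, float]:
        """Density on an n x n grid over the play area plus the cell area
        (for integration checks)."""
        from cogstyle.logdata import PLAY_AREA_PX
        xs = np.linspace(0, PLAY_AREA_PX, n)
        grid = np.array([[self.spatial_density(x, y) for x in xs] for y in xs])
        cell = (xs[1] - xs[0]) ** 2
        return grid, cell

    def density(self, tool_id: str, x: float, y: float) -> float:
        """Joint density: tool probability times spatial density."""
        return self.tool_probs.get(tool_id, 0.0) * self.spatial_density(x, y)


def _first_attempts(dataset: Dataset) -> pd.DataFrame:
    df = dataset.attempts_frame()
    return df[df["attempt_index"] == 1].reset_index(drop=True)


def build_group_density(level_attempts: pd.DataFrame, level_id: str,
                        group: str = "", exclude: str | None = None,
                        tool_universe: list[str] | None = None,
                        smoothing: float = 1.0) -> GroupDensity:
    """Build a group's density from first attempts on one level.

    ``level_attempts`` carries one row per first attempt (columns
    participant_id, tool_id, x, y).  ``exclude`` removes a participant's
    rows before fitting (the leave-one-out step).  Tool probabilities are
    Laplace-smoothed over ``tool_universe`` (defaults to the tools seen in
    the training rows).
    """
    rows = level_attempts
    if exclude is not None:
        rows = rows[rows["participant_id"] != exclude]
    if rows["participant_id"].nunique() < 2:
        raise TooFewContributors(
            f"level {level_id}, group {group}: fewer than 2 contributing "
            "participants")
    tools = tool_universe if tool_universe is not None else sorted(
        rows["tool_id"].unique())
    counts = rows["tool_id"].value_counts()
    total = len(rows) + smoothing * len(tools)
    tool_probs = {t: (counts.get(t, 0) + smoothing) / total for t in tools}
    xy = rows[["x", "y"]].to_numpy(dtype=float)
    m = len(xy)
    sd = xy.std(axis=0, ddof=0)
    h = np.maximum(sd * m ** (-1.0 / 6.0), _MIN_BANDWIDTH_PX)
    return GroupDensity(level_id=level_id, group=group, tool_probs=tool_probs,
                        train_xy=xy, bandwidths=h,
                        n_participants=int(rows["participant_id"].nunique()))


def relative_likelihood(attempt, own: GroupDensity, other: GroupDensity) -> float:
    """s = p_own / (p_own + p_other) in [0, 1]; 0.5 when both are zero.

    ``attempt`` is anything with ``tool_id``, ``x`` and ``y`` attributes
    (an :class:`~cogstyle.logdata.AttemptRecord` or a frame row).
    """
    if own.level_id != other.level_id:
        raise ValueError(
            f"density level mismatch: {own.level_id} vs {other.level_id}")
    tool, x, y = attempt.tool_id, float(attempt.x), float(attempt.y)
    p_own = max(own.density(tool, x, y), 0.0)
    p_other = max(other.density(tool, x, y), 0.0)
    if p_own <= _DENSITY_FLOOR and p_other <= _DENSITY_FLOOR:
        return 0.5
    p_own = max(p_own, _DENSITY_FLOOR)
    p_other = max(p_other, _DENSITY_FLOOR)
    return p_own / (p_own + p_other)


@dataclass
class ClassificationResult:
    """Leave-one-out classification scores and the test against chance."""

    contrast: str
    groups: tuple[str, str]
    level_scores: pd.DataFrame        # participant_id, group, level_id, score
    participant_scores: pd.DataFrame  # participant_id, group, score, n_levels
    mean_score: float
    t_stat: float
    df: int
    p_value: float
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Leave-one-out group classification ({self.contrast}: "
            f"{self.groups[0]} vs {self.groups[1]})",
            f"  participants scored: {len(self.participant_scores)}"
            f" ({len(self.skipped)} participant-levels skipped)",
            f"  mean relative likelihood: {self.mean_score:.3f} (chance 0.5)",
        ]
        if self.df >= 1:
            lines.append(f"  t({self.df}) = {self.t_stat:.2f}, "
                         f"p = {self.p_value:.3g}")
        else:
            lines.append("  t-test undefined (fewer than 2 participants)")
        return "\n".join(lines)


class LeaveOneOutClassifier:
    """Contrast two participant groups by their first-attempt distributions.

    Parameters
    ----------
    dataset : Dataset
    contrast : str
        Column defining the two groups: ``"limb_group"``, ``"age_group"``
        or ``"group"`` (with explicit ``groups``).
    within : dict, optional
        Restrict the analysis, e.g. ``{"limb_group": "NLD"}`` to contrast
        age groups among participants without limb differences.
    smoothing : float
        Laplace pseudo-count for tool probabilities.
    """

    def __init__(self, dataset: Dataset, contrast: str = "limb_group",
                 within: dict[str, str] | None = None, smoothing: float = 1.0):
        self.dataset = dataset
        self.contrast = contrast
        self.within = dict(within or {})
        self.smoothing = float(smoothing)

    def fit(self) -> ClassificationResult:
        df = _first_attempts(self.dataset)
        for col, val in self.within.items():
            df = df[df[col] == val]
        groups = sorted(df[self.contrast].unique())
        if len(groups) != 2:
            raise ValueError(
                f"contrast {self.contrast!r} must yield exactly 2 groups, "
                f"got {groups}")
        for g in groups:
            n = df.loc[df[self.contrast] == g, "participant_id"].nunique()
            if n < 3:
                raise ValueError(
                    f"group {g!r} has only {n} participants (need >= 3)")

        level_rows = []
        skipped: list[tuple[str, str, str]] = []
        for level_id, ldf in df.groupby("level_id", sort=True):
            tool_universe = sorted(ldf["tool_id"].unique())
            by_group = {g: ldf[ldf[self.contrast] == g] for g in groups}
            # other-group densities never exclude anyone: build once
            full: dict[str, GroupDensity | None] = {}
            for g in groups:
                try:
                    full[g] = build_group_density(
                        by_group[g], level_id, g, exclude=None,
                        tool_universe=tool_universe, smoothing=self.smoothing)
                except TooFewContributors:
                    full[g] = None
            for g, other_g in (groups, groups[::-1]):
                if full[other_g] is None:
                    for pid in by_group[g]["participant_id"].unique():
                        skipped.append((pid, level_id, "other group too small"))
                    continue
                for row in by_group[g].itertuples():
                    try:
                        own = build_group_density(
                            by_group[g], level_id, g,
                            exclude=row.participant_id,
                            tool_universe=tool_universe,
                            smoothing=self.smoothing)
                    except TooFewContributors:
                        skipped.append((row.participant_id, level_id,
                                        "own group too small after exclusion"))
                        continue
                    s = relative_likelihood(row, own, full[other_g])
                    level_rows.append((row.participant_id, g, level_id, s))

        level_scores = pd.DataFrame(
            level_rows, columns=["participant_id", "group", "level_id", "score"])
        if len(level_scores) == 0:
            raise ValueError("no scorable participant-levels")
        participant_scores = (level_scores
                              .groupby(["participant_id", "group"], sort=True)
                              .agg(score=("score", "mean"),
                                   n_levels=("score", "size"))
                              .reset_index())
        scores = participant_scores["score"].to_numpy()
        n = len(scores)
        if n >= 2:
            t_stat, p_value = stats.ttest_1samp(scores, 0.5)
            t_stat, p_value = float(t_stat), float(p_value)
        else:
            t_stat, p_value = math.nan, math.nan
        return ClassificationResult(
            contrast=self.contrast, groups=(groups[0], groups[1]),
            level_scores=level_scores, participant_scores=participant_scores,
            mean_score=float(scores.mean()), t_stat=t_stat, df=n - 1,
            p_value=p_value, skipped=skipped)


def loo_classify(dataset: Dataset, contrast: str = "limb_group",
                 within: dict[str, str] | None = None,
                 smoothing: float = 1.0) -> ClassificationResult:
    """Convenience wrapper around :class:`LeaveOneOutClassifier`."""
    return LeaveOneOutClassifier(dataset, contrast=contrast, within=within,
                                 smoothing=smoothing).fit()
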