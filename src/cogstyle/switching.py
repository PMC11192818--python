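"""Attempt-type switch statistics over cluster-labeled sequences.

Attempts on a level are clustered into "types" with the DP Gaussian mixture
(all attempts, [x, y] positions only, tool identity ignored), with separate
models per participant group but data pooled across that group's
participants.  Two consecutive attempts within a play are a *switch* when
their highest-likelihood cluster labels differ.  Group switch rates are
total switches over total transitions; the group comparison is a 1-df
likelihood-ratio chi-square from a mixed logistic regression of the
transition-level switch indicator on group with random intercepts for
participant and level (a pooled 2x2 chi-square is available as a fallback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cogstyle._glmm import MixedGLM, lr_test
from cogstyle.dpmm import fit_dpmm
from cogstyle.logdata import Dataset

#: supported grouping schemes for cluster fitting
GROUP_SCHEMES = ("cell", "age_group", "limb_group", "pooled")


@dataclass
class SwitchStats:
    """Per-participant switch counts, group rates, and the group test."""

    per_participant: pd.DataFrame   # participant_id, group cols, n_transitions, n_switches
    group_rates: dict[str, float]   # pooled rate per contrasted group
    contrast: str | None = None
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    method: str | None = None
    separation: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def overall_rate(self) -> float:
        t = self.per_participant["n_transitions"].sum()
        return float(self.per_participant["n_switches"].sum() / t) if t else math.nan

    def summary(self) -> str:
        lines = ["Attempt-type switch rates"]
        for g, r in self.group_rates.items():
            lines.append(f"  {g}: {100 * r:.1f}% switches")
        if self.chi2 is not None:
            lines.append(f"  {self.contrast}: chi2({self.df}) = {self.chi2:.2f}, "
                         f"p = {self.p_value:.4g}  [{self.method}]")
        if self.separation:
            lines.append("  warning: separation; no mixed test reported")
        return "\n".join(lines)


def label_sequences(dataset: Dataset, group_scheme: str = "cell",
                    alpha: float = 1.0, n_sweeps: int = 200,
                    burn_in: int = 100, seed: int = 0) -> pd.DataFrame:
    """Attach an attempt-type cluster label to every attempt.

    One DP mixture per (level, participant group) over the [x, y] positions
    of *all* attempts of that group on that level; ``group_scheme``
    chooses the grouping: ``"cell"`` (the four age x limb cells),
    ``"age_group"``, ``"limb_group"``, or ``"pooled"`` (everyone together).
    Labels are the fitted model's highest-responsibility clusters and are
    deterministic given ``seed``.
    """
    if group_scheme not in GROUP_SCHEMES:
        raise ValueError(f"group_scheme must be one of {GROUP_SCHEMES}")
    df = dataset.attempts_frame()
    if len(df) == 0:
        raise ValueError("dataset has no attempts")
    if group_scheme == "pooled":
        df["_grp"] = "all"
    elif group_scheme == "cell":
        df["_grp"] = df["age_group"] + "-" + df["limb_group"]
    else:
        df["_grp"] = df[group_scheme]

    df = df.sort_values(["level_id", "_grp", "participant_id",
                         "attempt_index"], kind="mergesort")
    labels = np.empty(len(df), dtype=int)
    level_ids = sorted(df["level_id"].unique())
    grp_ids = sorted(df["_grp"].unique())
    for li, level in enumerate(level_ids):
        for gi, grp in enumerate(grp_ids):
            mask = (df["level_id"] == level) & (df["_grp"] == grp)
            idx = np.flatnonzero(mask.to_numpy())
            if len(idx) == 0:
                continue
            pts = df.iloc[idx][["x", "y"]].to_numpy(float)
            res = fit_dpmm(pts, alpha=alpha, n_sweeps=n_sweeps,
                           burn_in=burn_in, seed=[seed, li, gi])
            labels[idx] = res.map_labels()
    out = df.drop(columns="_grp").copy()
    out["cluster"] = labels
    return out.sort_values(["participant_id", "level_id", "attempt_index"],
                           kind="mergesort").reset_index(drop=True)


def _transitions(labeled: pd.DataFrame) -> pd.DataFrame:
    """One row per consecutive-attempt pair within a play."""
    labeled = labeled.sort_values(
        ["participant_id", "level_id", "attempt_index"], kind="mergesort")
    prev = labeled.groupby(["participant_id", "level_id"])["cluster"].shift(1)
    rows = labeled[prev.notna()].copy()
    rows["switch"] = (rows["cluster"] != prev[prev.notna()]).astype(int)
    return rows


def switch_rate(labeled: pd.DataFrame,
                group_col: str | None = None) -> SwitchStats:
    """Per-participant switch counts and pooled group rates.

    ``labeled`` is the output of :func:`label_sequences` (needs a
    ``cluster`` column); a play with a single attempt contributes zero
    transitions.  Rates are total switches over total transitions.
    """
    if "cluster" not in labeled.columns:
        raise ValueError("labeled frame must carry a 'cluster' column")
    trans = _transitions(labeled)
    meta_cols = [c for c in ("age_group", "limb_group") if c in labeled.columns]
    per_pid = (labeled[["participant_id"] + meta_cols]
               .drop_duplicates("participant_id").set_index("participant_id"))
    agg = (trans.groupby("participant_id")["switch"]
           .agg(n_transitions="size", n_switches="sum")
           if len(trans) else
           pd.DataFrame(columns=["n_transitions", "n_switches"]))
    per = per_pid.join(agg).fillna({"n_transitions": 0, "n_switches": 0})
    per[["n_transitions", "n_switches"]] = per[
        ["n_transitions", "n_switches"]].astype(int)
    per = per.reset_index()

    rates: dict[str, float] = {}
    if group_col is not None and len(trans):
        for g, gdf in trans.groupby(group_col):
            rates[str(g)] = float(gdf["switch"].mean())
    return SwitchStats(per_participant=per, group_rates=rates,
                       contrast=group_col)


def compare_switch_rates(labeled: pd.DataFrame, contrast: str = "age_group",
                         method: str = "mixed") -> SwitchStats:
    """Test a group difference in switch probability.

    ``method="mixed"``: likelihood-ratio chi-square (1 df) from a mixed
    logistic regression of transition-level switch events on group, with
    random intercepts for participant and level.  ``method="chi2"``:
    pooled 2x2 contingency chi-square.
    """
    trans = _transitions(labeled)
    if len(trans) == 0:
        raise ValueError("no transitions (all plays have a single attempt)")
    groups = sorted(trans[contrast].unique())
    if len(groups) != 2:
        raise ValueError(f"contrast {contrast!r} must yield 2 groups, got {groups}")
    out = switch_rate(labeled, group_col=contrast)
    out.contrast = contrast

    y = trans["switch"].to_numpy(float)
    if y.min() == y.max():
        out.separation = True
        out.method = "none (all outcomes identical)"
        return out

    if method == "mixed":
        X = pd.DataFrame({
            "Intercept": np.ones(len(trans)),
            f"{contrast}[{groups[1]}]":
                (trans[contrast] == groups[1]).astype(float).to_numpy()})
        re = {"participant": trans["participant_id"].to_numpy(),
              "level": trans["level_id"].to_numpy()}
        full = MixedGLM(y, X, re, family="binomial").fit()
        red = MixedGLM(y, X[["Intercept"]], re, family="binomial").fit()
        if full.separation or red.separation:
            out.separation = True
            out.method = "none (separation)"
            return out
        chi2, dof, p = lr_test(full, red, df=1)
        out.chi2, out.df, out.p_value = chi2, dof, p
        out.method = "mixed logistic LRT"
        out.extra["params"] = full.params
        out.extra["re_sd"] = full.re_sd
    elif method == "chi2":
        table = pd.crosstab(trans[contrast], trans["switch"])
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        out.chi2, out.df, out.p_value = float(chi2), int(dof), float(p)
        out.method = "pooled 2x2 chi-square"
    else:
        raise ValueError("method must be 'mixed' or 'chi2'")
    return out
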