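"""End-to-end orchestration: simulate/read -> metrics -> cluster -> classify
-> switch -> infer, with a machine- and human-readable report.

The report collects the group-level quantities the analysis is about:
solution rates per group, additive limb/age timing offsets with CIs, the
multiplicative attempts ratio, leave-one-out classification scores with
their t-test, switch rates with the mixed logistic test, and motor
pre-test contrasts.  JSON keeps full precision; the Markdown report prints
three significant figures.  Reruns with the same seeds are identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

import cogstyle
from cogstyle.logdata import (
    ATTEMPT_COLUMNS,
    Dataset,
    FormatError,
    read_dataset,
    write_dataset,
)
from cogstyle.groupclassify import loo_classify
from cogstyle.inference import (
    fit_attempts_model,
    fit_motor_lm,
    fit_solution_model,
    fit_timing_model,
)
from cogstyle.metrics import level_metrics_frame, motor_summary_frame
from cogstyle.switching import compare_switch_rates, label_sequences, switch_rate
from cogstyle.synthgen import GeneratorConfig, generate_dataset

ALL_STAGES = ("metrics", "cluster", "classify", "switch", "infer")


@dataclass
class RunConfig:
    """What to run, on what input, with which seeds and flags."""

    input_dir: str | None = None          # read data here; None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    output_dir: str = "cogstyle_out"
    solved_only: bool = True
    cluster_scheme: str = "cell"
    cluster_sweeps: int = 200
    cluster_burn_in: int = 100
    classify_contrasts: tuple[tuple[str, dict], ...] = (
        ("limb_group", {}),
        ("age_group", {"limb_group": "NLD"}),
    )
    switch_contrast: str = "age_group"
    attempts_family: str = "lognormal"

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs_cluster = {"switch"} & set(self.stages)
        if needs_cluster and "cluster" not in self.stages:
            raise ValueError("the switch stage requires the cluster stage")


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            _log(f"[{name}] start")
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            _log(f"[{name}] done in {time.time() - t0:.1f} s")
            return out
        return inner
    return wrap


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages and write report.json / report.md.

    Returns the report dict.  Any stage failure aborts with a stage-named
    diagnostic.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    report: dict[str, Any] = {"manifest": {
        "package_version": cogstyle.__version__,
        "seed": config.seed,
        "input": config.input_dir or "synthetic",
        "stages": list(config.stages),
    }}

    if config.input_dir is not None:
        dataset = read_dataset(config.input_dir)
    else:
        dataset = generate_dataset(config.generator, seed=config.seed)
    report["manifest"]["n_participants"] = len(dataset.participants)

    lm = level_metrics_frame(dataset)
    labeled = None

    if "metrics" in config.stages:
        report["metrics"] = _metrics_stage(dataset, lm, config)
    if "cluster" in config.stages:
        labeled = _cluster_stage(dataset, config)
    if "classify" in config.stages:
        report["classification"] = _classify_stage(dataset, config)
    if "switch" in config.stages:
        report["switching"] = _switch_stage(labeled, config)
    if "infer" in config.stages:
        report["inference"] = _inference_stage(dataset, config)

    jpath = os.path.join(config.output_dir, "report.json")
    with open(jpath, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    mpath = os.path.join(config.output_dir, "report.md")
    with open(mpath, "w") as fh:
        fh.write(render_markdown(report))
    _log(f"report written to {jpath} and {mpath}")
    return report


@_stage("metrics")
def _metrics_stage(dataset: Dataset, lm: pd.DataFrame,
                   config: RunConfig) -> dict:
    out: dict[str, Any] = {"solution_rate_by_group": {}}
    for (ag, lg), g in lm.groupby(["age_group", "limb_group"]):
        out["solution_rate_by_group"][f"{ag}-{lg}"] = float(g["solved"].mean())
    for ag, g in lm.groupby("age_group"):
        out["solution_rate_by_group"][ag] = float(g["solved"].mean())
    sel = lm[lm["solved"]] if config.solved_only else lm
    for col in ("n_attempts", "time_to_first", "mean_gap", "time_to_solution"):
        out[f"mean_{col}_by_group"] = {
            f"{ag}-{lg}": float(g[col].mean())
            for (ag, lg), g in sel.groupby(["age_group", "limb_group"])}
    if dataset.motor:
        ms = motor_summary_frame(dataset)
        out["motor_by_group"] = {
            f"{ag}-{lg}": {"median_rt": float(g["median_rt"].mean()),
                           "median_error": float(g["median_error"].mean())}
            for (ag, lg), g in ms.groupby(["age_group", "limb_group"])}
    lm.to_csv(os.path.join(config.output_dir, "level_metrics.csv"), index=False)
    return out


@_stage("cluster")
def _cluster_stage(dataset: Dataset, config: RunConfig) -> pd.DataFrame:
    labeled = label_sequences(dataset, group_scheme=config.cluster_scheme,
                              n_sweeps=config.cluster_sweeps,
                              burn_in=config.cluster_burn_in,
                              seed=config.seed)
    labeled.to_csv(os.path.join(config.output_dir, "clusters.csv"), index=False)
    return labeled


@_stage("classify")
def _classify_stage(dataset: Dataset, config: RunConfig) -> dict:
    out = {}
    for contrast, within in config.classify_contrasts:
        try:
            res = loo_classify(dataset, contrast=contrast, within=within or None)
        except ValueError as exc:
            out[_contrast_key(contrast, within)] = {"skipped": str(exc)}
            continue
        out[_contrast_key(contrast, within)] = {
            "groups": list(res.groups),
            "mean_score": res.mean_score,
            "t": res.t_stat, "df": res.df, "p": res.p_value,
            "n_participants": len(res.participant_scores),
            "n_skipped": len(res.skipped),
        }
    return out


def _contrast_key(contrast: str, within: dict) -> str:
    key = contrast
    for col, val in (within or {}).items():
        key += f"|{col}={val}"
    return key


@_stage("switch")
def _switch_stage(labeled: pd.DataFrame, config: RunConfig) -> dict:
    stats = compare_switch_rates(labeled, contrast=config.switch_contrast)
    out = {
        "contrast": config.switch_contrast,
        "rates": stats.group_rates,
        "overall_rate": stats.overall_rate,
        "chi2": stats.chi2, "df": stats.df, "p": stats.p_value,
        "method": stats.method, "separation": stats.separation,
    }
    stats.per_participant.to_csv(
        os.path.join(config.output_dir, "switch.csv"), index=False)
    return out


@_stage("infer")
def _inference_stage(dataset: Dataset, config: RunConfig) -> dict:
    out: dict[str, Any] = {}
    for response in ("time_to_first", "mean_gap"):
        r = fit_timing_model(dataset, response, solved_only=config.solved_only)
        out[response] = _fitresult_dict(r)
    ra = fit_attempts_model(dataset, solved_only=config.solved_only,
                            family=config.attempts_family)
    d = _fitresult_dict(ra)
    d["ratio"] = ra.extra.get("ratio")
    d["ratio_ci"] = list(ra.extra.get("ratio_ci", ()))
    out["n_attempts"] = d
    out["solved"] = _fitresult_dict(fit_solution_model(dataset))
    if dataset.motor:
        for response in ("median_rt", "median_error"):
            out[f"motor_{response}"] = _fitresult_dict(
                fit_motor_lm(dataset, response))
    return out


def _fitresult_dict(r) -> dict:
    return {
        "method": r.method,
        "params": {k: float(v) for k, v in r.params.items()},
        "conf_int": {k: [float(r.conf_int.loc[k, "lower"]),
                         float(r.conf_int.loc[k, "upper"])]
                     for k in r.params.index},
        "tests": [{"term": t.term, "stat": float(t.stat), "df": float(t.df),
                   "p": float(t.p)} for t in r.lrt.itertuples()],
        "n_obs": int(r.n_obs),
        "converged": bool(r.converged),
    }


def render_markdown(report: dict) -> str:
    """Markdown report with estimates to three significant figures."""
    def sig3(x):
        if x is None or (isinstance(x, float) and not np.isfinite(x)):
            return "NA"
        return f"{x:.3g}"

    lines = ["# Analysis report", ""]
    man = report.get("manifest", {})
    lines += [f"- package version: {man.get('package_version')}",
              f"- input: {man.get('input')}",
              f"- seed: {man.get('seed')}",
              f"- participants: {man.get('n_participants')}", ""]
    if "metrics" in report:
        lines += ["## Performance metrics", "",
                  "| group | solution rate |", "|---|---|"]
        for g, v in report["metrics"]["solution_rate_by_group"].items():
            lines.append(f"| {g} | {sig3(v)} |")
        lines.append("")
    if "classification" in report:
        lines += ["## Leave-one-out classification", "",
                  "| contrast | mean score | t | df | p |", "|---|---|---|---|---|"]
        for key, v in report["classification"].items():
            if "skipped" in v:
                lines.append(f"| {key} | skipped: {v['skipped']} | | | |")
            else:
                lines.append(f"| {key} | {sig3(v['mean_score'])} | "
                             f"{sig3(v['t'])} | {v['df']} | {sig3(v['p'])} |")
        lines.append("")
    if "switching" in report:
        s = report["switching"]
        lines += ["## Attempt-type switching", ""]
        for g, r in s["rates"].items():
            lines.append(f"- {g}: {100 * r:.1f}% switches")
        if s.get("chi2") is not None:
            lines.append(f"- {s['contrast']}: chi2({s['df']}) = "
                         f"{sig3(s['chi2'])}, p = {sig3(s['p'])}")
        lines.append("")
    if "inference" in report:
        lines += ["## Mixed-effects contrasts", "",
                  "| response | limb (LD) effect | 95% CI | tests |",
                  "|---|---|---|---|"]
        for resp, v in report["inference"].items():
            eff = v["params"].get("limb_LD")
            ci = v["conf_int"].get("limb_LD")
            tests = "; ".join(
                f"{t['term']}: stat {sig3(t['stat'])}, p {sig3(t['p'])}"
                for t in v["tests"])
            ci_s = f"[{sig3(ci[0])}, {sig3(ci[1])}]" if ci else "NA"
            extra = f" (ratio {sig3(v['ratio'])})" if v.get("ratio") else ""
            lines.append(f"| {resp} | {sig3(eff)}{extra} | {ci_s} | {tests} |")
        lines.append("")
    return "\n".join(lines)


# ---- archive adapter -----------------------------------------------------

#: best-effort synonyms for the canonical attempt-log schema
_SYNONYMS = {
    "participant_id": ("participant", "subject", "subject_id", "pid", "id"),
    "age_group": ("agegroup", "age_grp", "group_age"),
    "limb_group": ("limbgroup", "limb", "condition", "group_limb"),
    "age_years": ("age", "age_yrs"),
    "level_id": ("level", "trial", "trial_name", "puzzle"),
    "attempt_index": ("attempt", "attempt_num", "attempt_number", "n_attempt"),
    "tool_id": ("tool", "toolname", "tool_name"),
    "x": ("pos_x", "x_px", "xpos"),
    "y": ("pos_y", "y_px", "ypos"),
    "t_s": ("t", "time", "time_s", "timestamp"),
    "solved": ("success", "solved_flag", "is_solved"),
    "end_t_s": ("end_t", "end_time", "level_end_s"),
}


def adapt_archive(path: str | os.PathLike,
                  output_dir: str | os.PathLike | None = None) -> Dataset:
    """Map an archived attempts table onto the canonical schema.

    A canonical CSV passes through unchanged.  Unknown columns are
    preserved in ``sidecar.csv`` when ``output_dir`` is given.  An
    unrecognized layout raises :class:`FormatError` listing the columns
    that were found.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        path = os.path.join(path, "attempts.csv")
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    found = list(df.columns)
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, alts in _SYNONYMS.items():
        if canon in df.columns:
            continue
        for alt in alts:
            if alt in lower:
                rename[lower[alt]] = canon
                break
    df = df.rename(columns=rename)
    missing = [c for c in ATTEMPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: could not map archive layout; missing {missing}; "
            f"found columns {found}")
    extra = [c for c in df.columns if c not in ATTEMPT_COLUMNS]
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        canon_path = os.path.join(tmp, "attempts.csv")
        df[ATTEMPT_COLUMNS].to_csv(canon_path, index=False,
                                   float_format="%.17g")
        from cogstyle.logdata import read_attempt_log

        dataset = read_attempt_log(canon_path)
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        write_dataset(dataset, output_dir)
        if extra:
            df[["participant_id", "level_id", "attempt_index"] + extra].to_csv(
                os.path.join(output_dir, "sidecar.csv"), index=False)
    return dataset


# ---- config loading ------------------------------------------------------


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain dict (e.g. parsed TOML)."""
    fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown generator options: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("cluster_centers", "tool_probs"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    if kwargs.get("group_mixture_weights") is not None:
        kwargs["group_mixture_weights"] = {
            k: np.asarray(v, dtype=float)
            for k, v in kwargs["group_mixture_weights"].items()}
    if "age_ranges" in kwargs:
        kwargs["age_ranges"] = {k: tuple(v)
                                for k, v in kwargs["age_ranges"].items()}
    return GeneratorConfig(**kwargs)


def run_config_from_toml(path: str | os.PathLike) -> RunConfig:
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    gen = generator_config_from_dict(raw.pop("generator", {}))
    if "classify_contrasts" in raw:
        raw["classify_contrasts"] = tuple(
            (c["contrast"], c.get("within", {}))
            for c in raw["classify_contrasts"])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(generator=gen, **raw)
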