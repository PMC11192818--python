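"""Synthetic study generator with known ground truth.

Emulates a four-group study (child/adult x with/without congenital limb
differences, "LD"/"NLD") of a 2D tool-placement game.  Each participant
plays ``n_levels`` levels; on a level, attempt *types* follow a first-order
Markov chain over K Gaussian placement clusters, placements are cluster
centers plus isotropic noise truncated to the play area, first-attempt and
inter-attempt latencies are additive-offset lognormals, and each attempt
solves the level with a per-group geometric probability until a 60 s bound.
The motor pre-test draws ten point-and-click trials per participant.

Group effects default to the study population's point estimates: the LD
group takes 3.79 s longer to the first attempt and 2.80 s longer between
attempts while needing 83.9% of the attempts; children switch attempt types
39% of the time versus 33% for adults; motor medians differ by age group
(error 7.65 vs 2.92 px, RT 3.04 vs 1.91 s) with LD participants 356 ms
faster.  Every quantity is reproducible from ``(config, seed)``; the random
stream is split hierarchically by (group, participant, level) so adding
participants never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from cogstyle.logdata import (
    DEFAULT_TIME_BOUND_S,
    PLAY_AREA_PX,
    AttemptRecord,
    Dataset,
    LevelPlay,
    MotorTrial,
    Participant,
)

GROUP_CELLS = ("child-LD", "child-NLD", "adult-LD", "adult-NLD")

#: study cell sizes: 25 child-LD, 45 child-NLD, 35 adult-LD, 40 adult-NLD
STUDY_N = {"child-LD": 25, "child-NLD": 45, "adult-LD": 35, "adult-NLD": 40}

# Per-attempt solve probabilities for NLD participants, by age group,
# calibrated once by simulation of this generator so that marginal solution
# rates match the study's 85% (adults) and 77% (children).
_SOLVE_P = {"adult": 0.28, "child": 0.32}


def _as_cell_counts(n: int | Mapping[str, int]) -> dict[str, int]:
    if isinstance(n, int):
        return {cell: n for cell in GROUP_CELLS}
    unknown = set(n) - set(GROUP_CELLS)
    if unknown:
        raise ValueError(f"unknown group cells: {sorted(unknown)}")
    return {cell: int(n.get(cell, 0)) for cell in GROUP_CELLS}


@dataclass
class GeneratorConfig:
    """All effect sizes and distributions of the synthetic study.

    ``None`` for :attr:`cluster_centers`, :attr:`group_mixture_weights` or
    :attr:`tool_probs` means "draw deterministically from the seed"; drawn
    structures are shared by all four groups, so group contrasts on
    placements are null by default.
    """

    n_per_group: int | Mapping[str, int] = field(default_factory=lambda: dict(STUDY_N))
    n_levels: int = 14
    clusters_per_level: int = 3
    cluster_centers: np.ndarray | None = None      # (n_levels, K, 2) px
    cluster_sd: float = 40.0                       # px
    group_mixture_weights: Mapping[str, np.ndarray] | None = None  # cell -> (n_levels, K)
    tool_probs: np.ndarray | None = None           # (n_levels, K, 3)
    # latencies (s): lognormal bases plus additive group offsets
    base_first_latency_mu: float = 1.95
    base_first_latency_sigma: float = 0.5
    ld_first_offset: float = 3.79
    child_first_offset: float = 6.1
    base_gap_mu: float = 2.10
    base_gap_sigma: float = 0.5
    ld_gap_offset: float = 2.80
    child_gap_offset: float = 3.5
    participant_latency_sd: float = 1.0            # random intercept, s
    # solving
    per_attempt_solve_p: Mapping[str, float] = field(
        default_factory=lambda: dict(_SOLVE_P))
    ld_attempt_ratio: float = 0.839
    # switching
    switch_p: Mapping[str, float] = field(
        default_factory=lambda: {"child": 0.39, "adult": 0.33})
    # motor pre-test
    motor_error_mean: Mapping[str, float] = field(
        default_factory=lambda: {"child": 7.65, "adult": 2.92})
    motor_error_between_sd: Mapping[str, float] = field(
        default_factory=lambda: {"child": 3.86, "adult": 1.74})
    ld_motor_error_offset: float = 0.79
    motor_rt_mean: Mapping[str, float] = field(
        default_factory=lambda: {"child": 3.04, "adult": 1.91})
    motor_rt_between_sd: Mapping[str, float] = field(
        default_factory=lambda: {"child": 1.58, "adult": 0.79})
    ld_motor_rt_offset: float = -0.356
    motor_rt_trial_sd: float = 0.5
    motor_error_trial_sd: float = 2.0
    # misc
    age_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"child": (5.0, 10.7), "adult": (18.0, 70.0)})
    time_bound: float = DEFAULT_TIME_BOUND_S
    n_tools: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 1 or self.clusters_per_level < 1:
            raise ValueError("n_levels and clusters_per_level must be >= 1")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")
        for name in ("base_first_latency_sigma", "base_gap_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for g, p in self.per_attempt_solve_p.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"per_attempt_solve_p[{g}] must be in (0, 1]")
        for g, p in self.switch_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"switch_p[{g}] must be in [0, 1]")
        if not 0.0 < self.ld_attempt_ratio:
            raise ValueError("ld_attempt_ratio must be positive")
        if self.group_mixture_weights is not None:
            for cell, w in self.group_mixture_weights.items():
                w = np.asarray(w, dtype=float)
                if w.shape != (self.n_levels, self.clusters_per_level):
                    raise ValueError(f"weights for {cell} have shape {w.shape}")
                if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0):
                    raise ValueError(f"weights for {cell} are not on the simplex")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def default_study_config(seed: int = 0) -> GeneratorConfig:
    """Config whose group-effect defaults are the study's point estimates.

    Cluster centers, mixture weights and tool distributions are drawn
    deterministically from the seed at generation time.
    """
    return GeneratorConfig(seed=seed)


# ---- internal draws ------------------------------------------------------


def _shared_structures(config: GeneratorConfig, seed: int):
    """Cluster centers, mixture weights and tool probabilities.

    Drawn once per (config, seed) and shared by all groups unless the
    config pins them explicitly.
    """
    L, K = config.n_levels, config.clusters_per_level
    rng = np.random.default_rng([seed, 7701])
    if config.cluster_centers is not None:
        centers = np.asarray(config.cluster_centers, dtype=float)
        if centers.shape != (L, K, 2):
            raise ValueError(f"cluster_centers must have shape {(L, K, 2)}")
    else:
        # keep centers away from the border so truncation stays mild
        margin = 3.0 * config.cluster_sd
        centers = rng.uniform(margin, PLAY_AREA_PX - margin, size=(L, K, 2))
    if config.group_mixture_weights is not None:
        weights = {cell: np.asarray(config.group_mixture_weights[cell], dtype=float)
                   for cell in GROUP_CELLS}
    else:
        shared = rng.dirichlet(np.full(K, 5.0), size=L)
        weights = {cell: shared for cell in GROUP_CELLS}
    if config.tool_probs is not None:
        tool_probs = np.asarray(config.tool_probs, dtype=float)
        if tool_probs.shape != (L, K, config.n_tools):
            raise ValueError(f"tool_probs must have shape {(L, K, config.n_tools)}")
    else:
        tool_probs = rng.dirichlet(np.full(config.n_tools, 2.0), size=(L, K))
    return centers, weights, tool_probs


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int | None = None, floor: float = 1e-3):
    """Normal draw resampled into the positive half line (<=100 tries, then floor)."""
    x = rng.normal(mean, sd, size=size)
    bad = np.atleast_1d(x) <= 0
    tries = 0
    x = np.atleast_1d(x).astype(float)
    while bad.any() and tries < 100:
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x <= 0
        tries += 1
    x[x <= 0] = floor
    return x if size is not None else float(x[0])


def _truncated_placement(rng: np.random.Generator, center: np.ndarray,
                         sd: float) -> tuple[float, float]:
    """Gaussian placement resampled into the play area (<=100 tries, then clip)."""
    for _ in range(100):
        xy = rng.normal(center, sd)
        if 0.0 <= xy[0] <= PLAY_AREA_PX and 0.0 <= xy[1] <= PLAY_AREA_PX:
            return float(xy[0]), float(xy[1])
    xy = np.clip(rng.normal(center, sd), 0.0, PLAY_AREA_PX)
    return float(xy[0]), float(xy[1])


def _markov_next(rng: np.random.Generator, current: int, weights: np.ndarray,
                 switch_p: float) -> int:
    """Stay with prob 1-switch_p; else move to a different cluster ~ weights."""
    K = len(weights)
    if K == 1:
        return current
    if rng.random() >= switch_p:
        return current
    w = weights.copy()
    w[current] = 0.0
    tot = w.sum()
    if tot <= 0:  # all mass on current cluster: nowhere to move
        return current
    return int(rng.choice(K, p=w / tot))


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> Dataset:
    """Generate a fully synthetic study; reproducible from ``(config, seed)``."""
    return generate_dataset_with_labels(config, seed)[0]


def generate_dataset_with_labels(config: GeneratorConfig,
                                 seed: int | None = None):
    """Like :func:`generate_dataset`, but also return the true attempt-type
    labels as a DataFrame (participant_id, level_id, attempt_index, cluster).

    The labels come from the generator's own Markov chain and serve as the
    ground-truth oracle for label-recovery and switch-rate checks.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    centers, weights, tool_probs = _shared_structures(config, seed)
    counts = _as_cell_counts(config.n_per_group)

    participants: dict[str, Participant] = {}
    plays: list[LevelPlay] = []
    motor: list[MotorTrial] = []
    true_labels: list[tuple[str, str, int, int]] = []

    for gi, cell in enumerate(GROUP_CELLS):
        age_group, limb_group = cell.split("-")
        solve_p = config.per_attempt_solve_p[age_group]
        if limb_group == "LD":
            # expected attempts scale by ld_attempt_ratio (geometric mean 1/p)
            solve_p = min(solve_p / config.ld_attempt_ratio, 0.99)
        sw_p = config.switch_p[age_group]
        first_off = ((config.ld_first_offset if limb_group == "LD" else 0.0)
                     + (config.child_first_offset if age_group == "child" else 0.0))
        gap_off = ((config.ld_gap_offset if limb_group == "LD" else 0.0)
                   + (config.child_gap_offset if age_group == "child" else 0.0))
        lo, hi = config.age_ranges[age_group]
        cell_weights = weights[cell]

        for pi in range(counts[cell]):
            pid = f"{cell}-{pi:03d}"
            rng_p = np.random.default_rng([seed, gi, pi, 5])
            age = float(rng_p.uniform(lo, hi))
            participants[pid] = Participant(pid, age_group, limb_group, age)
            intercept = float(rng_p.normal(0.0, config.participant_latency_sd))

            for li in range(config.n_levels):
                rng = np.random.default_rng([seed, gi, pi, 1000 + li])
                lid = f"L{li + 1:02d}"
                w = cell_weights[li]
                t = max(0.1, float(
                    rng.lognormal(config.base_first_latency_mu,
                                  config.base_first_latency_sigma))
                    + first_off + intercept)
                attempts: list[AttemptRecord] = []
                solved = False
                z = int(rng.choice(config.clusters_per_level, p=w))
                while t <= config.time_bound:
                    x, y = _truncated_placement(rng, centers[li, z], config.cluster_sd)
                    tool = f"T{int(rng.choice(config.n_tools, p=tool_probs[li, z])) + 1}"
                    attempts.append(AttemptRecord(pid, lid, len(attempts) + 1,
                                                  tool, x, y, t))
                    true_labels.append((pid, lid, len(attempts), z))
                    if rng.random() < solve_p:
                        solved = True
                        break
                    z = _markov_next(rng, z, w, sw_p)
                    gap = max(0.1, float(
                        rng.lognormal(config.base_gap_mu, config.base_gap_sigma))
                        + gap_off + intercept)
                    t = t + gap
                end_t = attempts[-1].t if solved else config.time_bound
                plays.append(LevelPlay(pid, lid, tuple(attempts), solved, end_t))

            # motor pre-test: participant-level mean plus symmetric trial noise,
            # so the 10-trial median is an unbiased read of the participant mean
            rng_m = np.random.default_rng([seed, gi, pi, 9999])
            mu_rt = _positive_normal(
                rng_m, config.motor_rt_mean[age_group]
                + (config.ld_motor_rt_offset if limb_group == "LD" else 0.0),
                config.motor_rt_between_sd[age_group])
            mu_err = _positive_normal(
                rng_m, config.motor_error_mean[age_group]
                + (config.ld_motor_error_offset if limb_group == "LD" else 0.0),
                config.motor_error_between_sd[age_group])
            distances = [150] * 5 + [250] * 5
            for ti in range(10):
                rt = _positive_normal(rng_m, mu_rt, config.motor_rt_trial_sd)
                err = max(0.0, float(rng_m.normal(mu_err, config.motor_error_trial_sd)))
                motor.append(MotorTrial(pid, ti + 1, distances[ti], rt, err))

    labels = pd.DataFrame(
        true_labels,
        columns=["participant_id", "level_id", "attempt_index", "cluster"])
    return Dataset(participants=participants, plays=plays, motor=motor), labels


def ground_truth(config: GeneratorConfig, seed: int | None = None) -> dict:
    """The realized parameters of a generated study, JSON-serializable."""
    config.validate()
    if seed is None:
        seed = config.seed
    centers, weights, tool_probs = _shared_structures(config, seed)
    return {
        "seed": int(seed),
        "n_per_group": _as_cell_counts(config.n_per_group),
        "n_levels": config.n_levels,
        "clusters_per_level": config.clusters_per_level,
        "cluster_centers": centers.tolist(),
        "cluster_sd": config.cluster_sd,
        "group_mixture_weights": {c: w.tolist() for c, w in weights.items()},
        "tool_probs": tool_probs.tolist(),
        "ld_first_offset": config.ld_first_offset,
        "ld_gap_offset": config.ld_gap_offset,
        "child_first_offset": config.child_first_offset,
        "child_gap_offset": config.child_gap_offset,
        "ld_attempt_ratio": config.ld_attempt_ratio,
        "per_attempt_solve_p": dict(config.per_attempt_solve_p),
        "switch_p": dict(config.switch_p),
        "motor_rt_mean": dict(config.motor_rt_mean),
        "motor_error_mean": dict(config.motor_error_mean),
        "ld_motor_rt_offset": config.ld_motor_rt_offset,
        "ld_motor_error_offset": config.ld_motor_error_offset,
        "time_bound": config.time_bound,
    }
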