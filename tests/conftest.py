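"""Shared fixtures.

Heavy artifacts (generated studies, mixed-model fits) are session-scoped so
parameter-recovery checks and acceptance-level checks reuse the same
computations.
"""

from __future__ import annotations

import numpy as np
import pytest

from cogstyle.inference import fit_timing_model
from cogstyle.logdata import (
    AttemptRecord,
    Dataset,
    LevelPlay,
    MotorTrial,
    Participant,
)
from cogstyle.synthgen import GeneratorConfig, default_study_config, generate_dataset

RECOVERY_SEEDS = (11, 12, 13)


def make_participant(pid="P1", age_group="adult", limb_group="NLD", age=30.0):
    return Participant(pid, age_group, limb_group, age)


def make_play(pid="P1", level="L1", ts=(5.0, 12.0, 20.0), solved=True,
              end_t=None, xy=(300.0, 300.0), tool="T1"):
    attempts = tuple(
        AttemptRecord(pid, level, i + 1, tool, xy[0], xy[1], t)
        for i, t in enumerate(ts))
    if end_t is None:
        end_t = ts[-1] if solved else 60.0
    return LevelPlay(pid, level, attempts, solved, end_t)


def make_motor(pid="P1", rts=None, errs=None):
    rts = rts if rts is not None else [1.0] * 5 + [2.0] * 5
    errs = errs if errs is not None else [3.0] * 10
    dists = [150] * 5 + [250] * 5
    return [MotorTrial(pid, i + 1, dists[i], rts[i], errs[i])
            for i in range(10)]


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """Two participants, two levels each, with motor trials."""
    participants = {
        "P1": make_participant("P1", "adult", "NLD", 30.0),
        "P2": make_participant("P2", "child", "LD", 8.0),
    }
    plays = [
        make_play("P1", "L1", (5.0, 12.0, 20.0), True),
        make_play("P1", "L2", (10.0, 30.0), False),
        make_play("P2", "L1", (8.0,), True),
        make_play("P2", "L2", (7.0, 15.0, 22.0, 31.0), True),
    ]
    motor = make_motor("P1") + make_motor("P2", rts=[2.0] * 10,
                                          errs=[5.0] * 10)
    return Dataset(participants=participants, plays=plays, motor=motor)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return default_study_config()


@pytest.fixture(scope="session")
def study_dataset(default_config):
    """One study at the population's cell sizes (145 participants)."""
    return generate_dataset(default_config, seed=7)


@pytest.fixture(scope="session")
def large_dataset(default_config):
    """100 participants per cell, for convergence checks."""
    return generate_dataset(default_config.replace(n_per_group=100), seed=21)


@pytest.fixture(scope="session")
def recovery_cfg(default_config):
    return default_config.replace(n_per_group=40)


@pytest.fixture(scope="session")
def recovery_datasets(recovery_cfg):
    return {s: generate_dataset(recovery_cfg, seed=s) for s in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def first_attempt_fits(recovery_datasets):
    """Mixed-model fits of time-to-first-attempt over the recovery seeds."""
    return {s: fit_timing_model(ds, "time_to_first")
            for s, ds in recovery_datasets.items()}


@pytest.fixture(scope="session")
def gap_fits(recovery_datasets):
    """Mixed-model fits of mean inter-attempt time over the recovery seeds."""
    return {s: fit_timing_model(ds, "mean_gap")
            for s, ds in recovery_datasets.items()}


@pytest.fixture(scope="session")
def separated_groups_dataset(default_config):
    """Two limb groups (adults only) with level-wise disjoint cluster
    centers 300 px apart, for the classification separation check."""
    L, K = default_config.n_levels, default_config.clusters_per_level
    rng = np.random.default_rng(5)
    base = rng.uniform(120, 180, size=(L, K, 2))
    centers = base.copy()
    weights = {}
    for cell in ("adult-LD", "adult-NLD", "child-LD", "child-NLD"):
        weights[cell] = np.full((L, K), 1.0 / K)
    cfg = default_config.replace(
        n_per_group={"adult-LD": 20, "adult-NLD": 20,
                     "child-LD": 0, "child-NLD": 0},
        cluster_centers=centers, cluster_sd=25.0,
        group_mixture_weights=weights)
    ds_nld = generate_dataset(cfg, seed=31)
    # shift the LD group's centers by 300 px on both axes
    cfg_ld = cfg.replace(cluster_centers=base + 300.0)
    ds_ld = generate_dataset(cfg_ld, seed=31)
    keep_nld = [p for p, v in ds_nld.participants.items() if v.limb_group == "NLD"]
    keep_ld = [p for p, v in ds_ld.participants.items() if v.limb_group == "LD"]
    return ds_nld.subset(keep_nld).merge(ds_ld.subset(keep_ld))
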