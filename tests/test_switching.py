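"""Switch-rate arithmetic, labeling, and the group comparison test."""

import numpy as np
import pandas as pd
import pytest

from cogstyle.switching import (
    compare_switch_rates,
    label_sequences,
    switch_rate,
)
from cogstyle.synthgen import (
    default_study_config,
    generate_dataset,
    generate_dataset_with_labels,
)


def _labeled(seqs, group="adult"):
    """Build a labeled frame from {(pid, level): [cluster, ...]}."""
    rows = []
    for (pid, level), labels in seqs.items():
        for i, c in enumerate(labels):
            rows.append({"participant_id": pid, "age_group": group,
                         "limb_group": "NLD", "level_id": level,
                         "attempt_index": i + 1, "cluster": c})
    return pd.DataFrame(rows)


class TestSwitchRateArithmetic:
    def test_constant_labels_rate_zero(self):
        stats = switch_rate(_labeled({("P1", "L1"): [1, 1, 1, 1]}))
        row = stats.per_participant.iloc[0]
        assert row["n_transitions"] == 3 and row["n_switches"] == 0

    def test_alternating_labels_rate_one(self):
        stats = switch_rate(_labeled({("P1", "L1"): [1, 2, 1, 2]}))
        row = stats.per_participant.iloc[0]
        assert row["n_transitions"] == 3 and row["n_switches"] == 3

    def test_single_attempt_plays_contribute_nothing(self):
        base = {("P1", "L1"): [1, 2, 2]}
        with_single = dict(base)
        with_single[("P1", "L2")] = [1]
        a = switch_rate(_labeled(base)).per_participant.iloc[0]
        b = switch_rate(_labeled(with_single)).per_participant.iloc[0]
        assert a["n_transitions"] == b["n_transitions"]
        assert a["n_switches"] == b["n_switches"]

    def test_rate_invariant_to_relabeling(self):
        seqs = {("P1", "L1"): [0, 1, 1, 2], ("P1", "L2"): [2, 2, 0]}
        remap = {0: 5, 1: 9, 2: 7}
        relabeled = {k: [remap[c] for c in v] for k, v in seqs.items()}
        a = switch_rate(_labeled(seqs)).per_participant.iloc[0]
        b = switch_rate(_labeled(relabeled)).per_participant.iloc[0]
        assert a["n_switches"] == b["n_switches"]

    def test_doubling_data_doubles_transitions(self):
        seqs = {("P1", "L1"): [1, 2, 1], ("P2", "L1"): [2, 2]}
        doubled = dict(seqs)
        doubled.update({(f"{p}b", l): v for (p, l), v in seqs.items()})
        a = switch_rate(_labeled(seqs))
        b = switch_rate(_labeled(doubled))
        assert (b.per_participant["n_transitions"].sum()
                == 2 * a.per_participant["n_transitions"].sum())


@pytest.fixture(scope="module")
def separated_cfg():
    # well-separated generative clusters so label recovery is clean
    L = 4
    centers = np.array([[[100.0, 100.0], [300.0, 300.0], [500.0, 500.0]]] * L)
    return default_study_config().replace(
        n_per_group={"adult-LD": 0, "adult-NLD": 12,
                     "child-LD": 0, "child-NLD": 0},
        n_levels=L, cluster_centers=centers, cluster_sd=25.0)


class TestLabelSequences:

    def test_two_blob_fixture_matches_nearest_center_oracle(self, separated_cfg):
        ds, truth = generate_dataset_with_labels(separated_cfg, seed=51)
        labeled = label_sequences(ds, group_scheme="pooled", seed=1)
        merged = labeled.merge(
            truth, on=["participant_id", "level_id", "attempt_index"],
            suffixes=("_fit", "_true"))
        # per level, fitted labels must refine the true clustering up to a
        # permutation: check via contingency purity
        for _, g in merged.groupby("level_id"):
            tab = pd.crosstab(g["cluster_true"], g["cluster_fit"])
            purity = tab.max(axis=1).sum() / len(g)
            assert purity > 0.95

    def test_labels_deterministic_given_seed(self, separated_cfg):
        ds = generate_dataset(separated_cfg, seed=52)
        a = label_sequences(ds, group_scheme="pooled", seed=3)
        b = label_sequences(ds, group_scheme="pooled", seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_single_cluster_data_single_label(self):
        # fixed fixture: one generative cluster per level maps to one fitted
        # cluster.  (Not a universal guarantee -- a DP mixture's posterior
        # can split a single Gaussian at small n; see the methods note.)
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 0, "adult-NLD": 20,
                         "child-LD": 0, "child-NLD": 0},
            n_levels=2, clusters_per_level=1, cluster_sd=15.0)
        ds = generate_dataset(cfg, seed=54)
        labeled = label_sequences(ds, group_scheme="pooled", seed=4)
        assert (labeled.groupby("level_id")["cluster"].nunique() == 1).all()


class TestCompareSwitchRates:
    def test_recovers_generator_switch_probability(self):
        # truth-labeled sequences: the estimator is plain binomial, so at
        # >= 2000 transitions it must sit within +-0.03 of switch_p
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 0, "adult-NLD": 80,
                         "child-LD": 0, "child-NLD": 0},
            switch_p={"adult": 0.40, "child": 0.40})
        ds, truth = generate_dataset_with_labels(cfg, seed=61)
        labeled = ds.attempts_frame().merge(
            truth, on=["participant_id", "level_id", "attempt_index"])
        stats = switch_rate(labeled, group_col="age_group")
        n = stats.per_participant["n_transitions"].sum()
        assert n >= 2000
        assert stats.overall_rate == pytest.approx(0.40, abs=0.03)

    def test_group_difference_detected_by_mixed_model(self):
        # study-sized groups with the configured 0.39 vs 0.33 switch rates
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 0, "adult-NLD": 40,
                         "child-LD": 0, "child-NLD": 45})
        ds, truth = generate_dataset_with_labels(cfg, seed=62)
        labeled = ds.attempts_frame().merge(
            truth, on=["participant_id", "level_id", "attempt_index"])
        out = compare_switch_rates(labeled, contrast="age_group")
        assert out.method == "mixed logistic LRT"
        assert out.group_rates["child"] > out.group_rates["adult"]
        assert out.chi2 > 3.84 and out.p_value < 0.05

    def test_power_majority_of_replicates(self):
        # pooled chi-square on truth labels keeps each replicate cheap
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 0, "adult-NLD": 40,
                         "child-LD": 0, "child-NLD": 45})
        hits = 0
        for rep in range(20):
            ds, truth = generate_dataset_with_labels(cfg, seed=700 + rep)
            labeled = ds.attempts_frame().merge(
                truth, on=["participant_id", "level_id", "attempt_index"])
            out = compare_switch_rates(labeled, contrast="age_group",
                                       method="chi2")
            if out.p_value < 0.05:
                hits += 1
        assert hits > 10

    def test_null_difference_not_flagged(self):
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 0, "adult-NLD": 30,
                         "child-LD": 0, "child-NLD": 30},
            switch_p={"adult": 0.35, "child": 0.35})
        ps = []
        for rep in range(20):
            ds, truth = generate_dataset_with_labels(cfg, seed=800 + rep)
            labeled = ds.attempts_frame().merge(
                truth, on=["participant_id", "level_id", "attempt_index"])
            out = compare_switch_rates(labeled, contrast="age_group",
                                       method="chi2")
            ps.append(out.p_value)
        # p roughly uniform under the null
        assert 0.25 <= np.mean(ps) <= 0.75

    def test_degenerate_outcomes_report_separation(self):
        labeled = _labeled({("P1", "L1"): [1, 1, 1], ("P2", "L1"): [2, 2]},
                           group="adult")
        labeled2 = _labeled({("P3", "L1"): [1, 1, 1]}, group="child")
        both = pd.concat([labeled, labeled2], ignore_index=True)
        out = compare_switch_rates(both, contrast="age_group")
        assert out.separation and out.chi2 is None
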