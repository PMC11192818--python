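"""Group densities, relative likelihood, and leave-one-out classification."""

import math

import numpy as np
import pandas as pd
import pytest

from cogstyle.groupclassify import (
    TooFewContributors,
    build_group_density,
    loo_classify,
    relative_likelihood,
)
from cogstyle.synthgen import default_study_config, generate_dataset


def _rows(points, pids=None, tools=None):
    n = len(points)
    return pd.DataFrame({
        "participant_id": pids if pids is not None else [f"P{i}" for i in range(n)],
        "tool_id": tools if tools is not None else ["T1"] * n,
        "x": [p[0] for p in points],
        "y": [p[1] for p in points],
    })


class _Query:
    def __init__(self, tool_id, x, y):
        self.tool_id, self.x, self.y = tool_id, x, y


class TestGroupDensity:
    def test_laplace_smoothing_arithmetic(self):
        rows = _rows([(100, 100)] * 9, tools=["TA"] * 9)
        d = build_group_density(rows, "L1", tool_universe=["TA", "TB", "TC"],
                                smoothing=1.0)
        assert d.tool_probs["TA"] == pytest.approx(10 / 12)
        assert d.tool_probs["TB"] == pytest.approx(1 / 12)
        assert sum(d.tool_probs.values()) == pytest.approx(1.0)

    def test_point_mass_training_peaks_at_kernel_maximum(self):
        rows = _rows([(300, 300)] * 6)
        d = build_group_density(rows, "L1")
        # degenerate spread falls back to the 1 px bandwidth floor
        peak = d.spatial_density(300.0, 300.0)
        assert peak == pytest.approx(1.0 / (2.0 * math.pi), rel=1e-9)
        assert d.spatial_density(310.0, 300.0) < peak

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        rows = _rows(rng.uniform(150, 450, size=(30, 2)))
        d = build_group_density(rows, "L1")
        grid, cell = d.logpdf_grid(n=120)
        assert grid.sum() * cell == pytest.approx(1.0, abs=0.01)

    def test_exclusion_equals_fit_on_reduced_set(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(100, 500, size=(8, 2))
        rows = _rows(pts)
        d_excl = build_group_density(rows, "L1", exclude="P0")
        d_red = build_group_density(rows.iloc[1:], "L1")
        np.testing.assert_array_equal(d_excl.train_xy, d_red.train_xy)
        np.testing.assert_array_equal(d_excl.bandwidths, d_red.bandwidths)

    def test_plugin_bandwidth_rule(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(100, 500, size=(40, 2))
        d = build_group_density(_rows(pts), "L1")
        expected = pts.std(axis=0, ddof=0) * 40 ** (-1.0 / 6.0)
        np.testing.assert_allclose(d.bandwidths, expected)

    def test_too_few_contributors_rejected(self):
        rows = _rows([(1, 1), (2, 2)], pids=["P0", "P0"])
        with pytest.raises(TooFewContributors):
            build_group_density(rows, "L1")


class TestRelativeLikelihood:
    def _pair(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(200, 400, size=(10, 2))
        own = build_group_density(_rows(pts), "L1",
                                  tool_universe=["T1", "T2"])
        other = build_group_density(_rows(pts), "L1",
                                    tool_universe=["T1", "T2"])
        return own, other

    def test_identical_training_sets_give_exact_chance(self):
        own, other = self._pair()
        s = relative_likelihood(_Query("T1", 300.0, 300.0), own, other)
        assert s == pytest.approx(0.5)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        own = build_group_density(_rows(rng.uniform(150, 300, (9, 2))), "L1")
        other = build_group_density(_rows(rng.uniform(300, 450, (9, 2))), "L1")
        q = _Query("T1", 260.0, 260.0)
        s = relative_likelihood(q, own, other)
        assert relative_likelihood(q, other, own) == pytest.approx(1.0 - s)

    def test_disjoint_tool_usage_grows_as_smoothing_shrinks(self):
        pts = [(250.0, 250.0 + 5 * i) for i in range(5)]
        scores = []
        for smoothing in (1.0, 0.1, 0.01):
            own = build_group_density(_rows(pts, tools=["TA"] * 5), "L1",
                                      tool_universe=["TA", "TB"],
                                      smoothing=smoothing)
            other = build_group_density(_rows(pts, tools=["TB"] * 5), "L1",
                                        tool_universe=["TA", "TB"],
                                        smoothing=smoothing)
            scores.append(relative_likelihood(_Query("TA", 250.0, 255.0),
                                              own, other))
        assert all(s > 0.5 for s in scores)
        assert scores == sorted(scores)  # s -> 1 as smoothing -> 0
        assert scores[-1] > 0.97

    def test_level_mismatch_rejected(self):
        own, _ = self._pair()
        other = build_group_density(_rows([(1, 1), (2, 2)]), "L2")
        with pytest.raises(ValueError, match="level mismatch"):
            relative_likelihood(_Query("T1", 0, 0), own, other)


class TestLooClassification:
    def test_exchangeable_groups_score_at_chance(self):
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 40, "adult-NLD": 40,
                         "child-LD": 0, "child-NLD": 0})
        res = loo_classify(generate_dataset(cfg, seed=41),
                           contrast="limb_group")
        assert res.mean_score == pytest.approx(0.5, abs=0.03)
        assert res.df == 79

    def test_separated_groups_classified_almost_perfectly(
            self, separated_groups_dataset):
        res = loo_classify(separated_groups_dataset, contrast="limb_group")
        assert res.mean_score > 0.9

    def test_small_group_refused(self, tiny_dataset):
        with pytest.raises(ValueError, match=">= 3"):
            loo_classify(tiny_dataset, contrast="limb_group")

    def test_within_filter_restricts_population(self):
        cfg = default_study_config().replace(n_per_group=8, n_levels=4)
        ds = generate_dataset(cfg, seed=43)
        res = loo_classify(ds, contrast="age_group",
                           within={"limb_group": "NLD"})
        pids = set(res.participant_scores["participant_id"])
        assert all("NLD" in p for p in pids)
        # df = scored participants - 1, both age groups counted
        assert res.df == len(pids) - 1

    def test_chance_level_centering_under_exchangeability(self):
        # identical generative distributions for both groups: replicate-mean
        # scores center on 0.5.  (The per-replicate t-test itself is
        # anticonservative here because participant scores share training
        # data; see the methods note.)
        cfg = default_study_config().replace(
            n_per_group={"adult-LD": 12, "adult-NLD": 12,
                         "child-LD": 0, "child-NLD": 0},
            n_levels=6)
        means = []
        for rep in range(100):
            ds = generate_dataset(cfg, seed=1000 + rep)
            means.append(loo_classify(ds, contrast="limb_group").mean_score)
        assert np.mean(means) == pytest.approx(0.5, abs=0.01)
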