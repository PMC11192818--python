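"""Parameter recovery and calibration of the mixed-effects analyses."""

import numpy as np
import pandas as pd
import pytest

from cogstyle.inference import (
    fit_attempts_model,
    fit_motor_lm,
    fit_solution_model,
    fit_timing_model,
)
from cogstyle.logdata import Dataset
from cogstyle.synthgen import default_study_config, generate_dataset
from conftest import RECOVERY_SEEDS


class TestTimingRecovery:
    def test_first_attempt_limb_offset_recovered(self, first_attempt_fits):
        """The generator's 3.79 s LD offset is recovered by the mixed model
        (mean over seeds within 0.5 s) and covered by most 95% CIs."""
        estimates = [r.limb_effect for r in first_attempt_fits.values()]
        assert np.mean(estimates) == pytest.approx(3.79, abs=0.5)
        covered = sum(lo <= 3.79 <= hi for lo, hi in
                      (r.limb_effect_ci() for r in first_attempt_fits.values()))
        assert covered >= len(first_attempt_fits) - 1

    def test_gap_limb_offset_recovered(self, gap_fits):
        estimates = [r.limb_effect for r in gap_fits.values()]
        assert np.mean(estimates) == pytest.approx(2.80, abs=0.5)

    def test_null_generator_covers_zero(self):
        cfg = default_study_config().replace(
            n_per_group=30, ld_first_offset=0.0, ld_gap_offset=0.0)
        hits = 0
        for seed in (101, 102):
            r = fit_timing_model(generate_dataset(cfg, seed=seed),
                                 "time_to_first")
            lo, hi = r.limb_effect_ci()
            hits += lo <= 0.0 <= hi
        assert hits >= 1

    def test_estimates_invariant_to_participant_relabeling(self):
        cfg = default_study_config().replace(n_per_group=6, n_levels=5)
        ds = generate_dataset(cfg, seed=103)
        r1 = fit_timing_model(ds, "time_to_first")
        # reverse the participant-id alphabet
        mapping = {p: f"Z{i:03d}" for i, p in
                   enumerate(sorted(ds.participants, reverse=True))}
        renamed = Dataset(
            participants={mapping[p]: type(v)(mapping[p], v.age_group,
                                              v.limb_group, v.age_years)
                          for p, v in ds.participants.items()},
            plays=[type(pl)(mapping[pl.participant_id], pl.level_id,
                            tuple(type(a)(mapping[a.participant_id], a.level_id,
                                          a.attempt_index, a.tool_id, a.x, a.y,
                                          a.t) for a in pl.attempts),
                            pl.solved, pl.end_t) for pl in ds.plays],
            motor=[type(m)(mapping[m.participant_id], m.trial_index,
                           m.distance_px, m.rt, m.click_error)
                   for m in ds.motor])
        r2 = fit_timing_model(renamed, "time_to_first")
        assert r1.limb_effect == pytest.approx(r2.limb_effect, abs=1e-6)

    def test_covariate_free_analysis_keeps_effect_sign(self, recovery_datasets):
        ds = recovery_datasets[RECOVERY_SEEDS[0]]
        with_cov = fit_timing_model(ds, "time_to_first", covariates=True)
        without = fit_timing_model(ds, "time_to_first", covariates=False)
        assert np.sign(with_cov.limb_effect) == np.sign(without.limb_effect)
        assert without.limb_effect == pytest.approx(3.79, abs=1.0)


class TestAttemptsModel:
    def test_attempt_ratio_recovered(self, recovery_datasets):
        r = fit_attempts_model(recovery_datasets[RECOVERY_SEEDS[0]])
        assert 0.75 <= r.extra["ratio"] <= 0.93

    def test_unit_ratio_generator_covers_one(self):
        # a fully limb-null generator: equal solve probability AND equal
        # latencies (otherwise the 60 s bound truncates the slower group's
        # attempts and the true conditional ratio falls below 1)
        cfg = default_study_config().replace(n_per_group=30,
                                             ld_attempt_ratio=1.0,
                                             ld_first_offset=0.0,
                                             ld_gap_offset=0.0)
        r = fit_attempts_model(generate_dataset(cfg, seed=104))
        lo, hi = r.extra["ratio_ci"]
        assert lo <= 1.0 <= hi

    def test_doubling_counts_shifts_only_intercept(self, tiny_dataset):
        # log link: scaling all counts by 2 adds log 2 to the intercept
        cfg = default_study_config().replace(n_per_group=8, n_levels=5)
        ds = generate_dataset(cfg, seed=105)
        r1 = fit_attempts_model(ds, solved_only=False)
        doubled = Dataset(
            participants=dict(ds.participants),
            plays=[type(p)(p.participant_id, p.level_id,
                           tuple(type(a)(a.participant_id, a.level_id, i + 1,
                                         a.tool_id, a.x, a.y, a.t + 100 * (i >= p.n_attempts))
                                 for i, a in enumerate(list(p.attempts) * 2)),
                           p.solved, p.end_t + 200) for p in ds.plays],
            motor=list(ds.motor))
        r2 = fit_attempts_model(doubled, solved_only=False)
        assert (r2.params["Intercept"] - r1.params["Intercept"]
                == pytest.approx(np.log(2.0), abs=1e-4))
        assert r2.params["limb_LD"] == pytest.approx(r1.params["limb_LD"],
                                                     abs=1e-4)


@pytest.fixture(scope="module")
def solution_fit(recovery_datasets):
    return fit_solution_model(recovery_datasets[RECOVERY_SEEDS[0]])


class TestSolutionModel:

    def test_age_gap_in_solve_rates_detected(self, solution_fit):
        # generator: adults solve ~85% of levels, children ~77%
        age = solution_fit.lrt.set_index("term").loc["age"]
        assert age["stat"] > 3.84 and age["p"] < 0.05
        assert solution_fit.params["age_child"] < 0

    def test_predicted_probabilities_strictly_inside_unit_interval(
            self, solution_fit, recovery_datasets):
        mu = solution_fit.extra.get("fitted_mean")
        assert mu is not None
        assert np.all(mu > 0.0) and np.all(mu < 1.0)

    def test_equal_solve_probability_generator_covers_zero(self):
        cfg = default_study_config().replace(
            n_per_group=30,
            per_attempt_solve_p={"adult": 0.3, "child": 0.3},
            ld_attempt_ratio=1.0,
            child_first_offset=0.0, child_gap_offset=0.0,
            ld_first_offset=0.0, ld_gap_offset=0.0)
        r = fit_solution_model(generate_dataset(cfg, seed=106))
        for term in ("limb_LD", "age_child"):
            lo, hi = r.conf_int.loc[term]
            assert lo <= 0.0 <= hi


class TestMotorModel:
    def test_limb_rt_offset_recovered_over_seeds(self):
        """Mean recovered LD reaction-time offset within 0.2 s of the
        configured -0.356 s at the study's sample size, over 20 seeds."""
        cfg = default_study_config()
        est = []
        for seed in range(200, 220):
            r = fit_motor_lm(generate_dataset(cfg, seed=seed), "median_rt")
            est.append(r.limb_effect)
        assert np.mean(est) == pytest.approx(-0.356, abs=0.2)

    def test_type_one_error_near_nominal_under_null(self):
        cfg = default_study_config().replace(ld_motor_rt_offset=0.0)
        rejections = 0
        n_reps = 100
        for seed in range(300, 300 + n_reps):
            r = fit_motor_lm(generate_dataset(cfg, seed=seed), "median_rt")
            p = r.lrt.set_index("term").loc["limb", "p"]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_reps <= 0.11

    def test_residual_df_is_n_minus_coefficients(self, study_dataset):
        r = fit_motor_lm(study_dataset, "median_rt")
        assert r.extra["df_resid"] == r.n_obs - len(r.params)

    def test_error_model_recovers_age_difference(self, study_dataset):
        r = fit_motor_lm(study_dataset, "median_error")
        # children err ~7.65 px vs adults ~2.92 px
        assert r.params["age_child"] == pytest.approx(7.65 - 2.92, abs=1.5)
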