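"""DIF screening by nested ordinal regressions and score-impact checks."""

import numpy as np
import pandas as pd
import pytest

from gradedcat import (
    DIFInjection,
    SimulationDesign,
    detect_dif,
    dif_battery,
    dif_corrected_theta,
    generate_responses,
    score_for_dif,
)
from gradedcat.dif import binarize_covariate
from gradedcat.grm import ResponseMatrix


@pytest.fixture(scope="module")
def dif_cohort(ue_bank):
    """Two equal groups, uniform DIF of 0.5 planted on the high-slope item
    PFB30, n = 1000 per group."""
    design = SimulationDesign(
        n_persons=2000, theta_mean=(0.0, 0.0), theta_sd=(1.0, 1.0),
        group_proportions=(0.5, 0.5),
        dif_injections=(DIFInjection("PFB30", "uniform", 0.5),),
        seed=12,
    )
    matrix, thetas, groups = generate_responses(ue_bank, design)
    theta_hat = score_for_dif(matrix, ue_bank)
    return matrix, thetas, groups, theta_hat


class TestDetect:
    def test_duplicated_sample_shows_no_group_effect(self, ue_bank):
        matrix, _, _ = generate_responses(
            ue_bank.subset(ue_bank.item_ids[:8]),
            SimulationDesign(n_persons=400, seed=14),
        )
        doubled = ResponseMatrix(
            [f"a{p}" for p in matrix.persons] + [f"b{p}" for p in matrix.persons],
            list(matrix.item_ids),
            np.vstack([matrix.codes, matrix.codes]),
            n_categories=matrix.n_categories,
        )
        bank8 = ue_bank.subset(ue_bank.item_ids[:8])
        theta = score_for_dif(doubled, bank8)
        group = np.r_[np.zeros(400, int), np.ones(400, int)]
        res = detect_dif(doubled, theta, group)
        assert all(r.flag == "none" for r in res)
        assert all(r.delta_total < 1e-4 for r in res)

    def test_nested_r2_increase_and_flag_consistency(self, dif_cohort):
        matrix, _, groups, theta_hat = dif_cohort
        res = detect_dif(matrix.subset_items(matrix.item_ids[:6] + ["PFB30"]),
                         theta_hat, groups)
        for r in res:
            assert r.r2_m1 <= r.r2_m2 + 1e-6 <= r.r2_m3 + 2e-6
            assert 0 <= r.r2_m1 < 1
            assert (r.flag in ("uniform", "nonuniform")) == (r.delta_total >= 0.02)

    def test_planted_uniform_dif_is_flagged_uniform(self, dif_cohort):
        matrix, _, groups, theta_hat = dif_cohort
        res = detect_dif(matrix.subset_items(["PFB30"]), theta_hat, groups)
        assert res[0].flag == "uniform"
        assert res[0].delta_uniform >= res[0].delta_nonuniform

    def test_planted_slope_change_is_flagged_nonuniform(self, ue_bank):
        design = SimulationDesign(
            n_persons=4000, theta_mean=(0.0, 0.0), theta_sd=(1.0, 1.0),
            group_proportions=(0.5, 0.5),
            dif_injections=(DIFInjection("PFB30", "nonuniform", -0.8),),
            seed=15,
        )
        matrix, _, groups = generate_responses(ue_bank, design)
        theta_hat = score_for_dif(matrix, ue_bank)
        res = detect_dif(matrix.subset_items(["PFB30"]), theta_hat, groups)
        assert res[0].flag == "nonuniform"
        assert res[0].delta_nonuniform > res[0].delta_uniform

    def test_bad_inputs_rejected(self, dif_cohort):
        matrix, _, groups, theta_hat = dif_cohort
        with pytest.raises(ValueError, match="two levels"):
            detect_dif(matrix, theta_hat, np.zeros(matrix.n_persons, int))
        with pytest.raises(ValueError, match="finite"):
            detect_dif(matrix, np.full(matrix.n_persons, np.nan), groups)


class TestImpact:
    def test_no_flags_means_zero_differences(self, ue_bank, dif_cohort):
        matrix, _, groups, theta_hat = dif_cohort
        clean = detect_dif(matrix.subset_items(matrix.item_ids[:5]),
                           theta_hat, groups)
        impact = dif_corrected_theta(matrix, ue_bank, clean, groups)
        assert np.all(impact.differences == 0.0)
        assert impact.quartiles == {"q25": 0.0, "q50": 0.0, "q75": 0.0}

    def test_single_mild_flag_has_small_central_impact(self, ue_bank, dif_cohort):
        matrix, _, groups, theta_hat = dif_cohort
        res = detect_dif(matrix, theta_hat, groups)
        impact = dif_corrected_theta(matrix, ue_bank, res, groups)
        # one mildly DIF-flagged item of 46: central mass of differences
        # stays an order of magnitude below the score SE (~0.15)
        assert impact.quartiles["q25"] > -0.1
        assert impact.quartiles["q75"] < 0.1

    def test_corrected_scores_closer_to_truth_under_large_dif(self, ue_bank):
        design = SimulationDesign(
            n_persons=1500, theta_mean=(0.0, 0.0), theta_sd=(1.0, 1.0),
            group_proportions=(0.5, 0.5),
            dif_injections=(
                DIFInjection("PFB30", "uniform", 1.2),
                DIFInjection("PFA28", "uniform", 1.2),
                DIFInjection("PFA18", "uniform", 1.2),
            ),
            seed=16,
        )
        matrix, truth, groups = generate_responses(ue_bank, design)
        theta_hat = score_for_dif(matrix, ue_bank)
        res = detect_dif(matrix, theta_hat, groups)
        flagged = [r.item_id for r in res if r.flag != "none"]
        assert set(flagged) >= {"PFB30", "PFA28", "PFA18"}
        impact = dif_corrected_theta(matrix, ue_bank, res, groups)
        mse_init = np.mean((impact.theta_initial - truth) ** 2)
        mse_corr = np.mean((impact.theta_corrected - truth) ** 2)
        assert mse_corr < mse_init

    def test_all_items_flagged_leaves_no_anchor(self, ue_bank, dif_cohort):
        matrix, _, groups, _ = dif_cohort
        from gradedcat.dif import DIFResult

        fake = [
            DIFResult(iid, 0, 0.1, 0.1, 0.1, 0.0, 0.1, "uniform")
            for iid in matrix.item_ids
        ]
        with pytest.raises(ValueError, match="anchor"):
            dif_corrected_theta(matrix, ue_bank, fake, groups)


class TestBattery:
    def test_five_covariates_five_tables(self, ue_bank):
        small = ue_bank.subset(ue_bank.item_ids[:6])
        matrix, thetas, _ = generate_responses(
            small, SimulationDesign(n_persons=400, seed=18)
        )
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {
                "age": rng.normal(53, 15, 400),
                "gender": rng.integers(0, 2, 400),
                "duration": rng.integers(0, 2, 400),
                "center": rng.integers(0, 2, 400),
                "location": rng.integers(0, 2, 400),
            }
        )
        tables = dif_battery(matrix, small, cov)
        assert set(tables) == set(cov.columns)
        assert all(len(t) == 6 for t in tables.values())

    def test_single_level_covariate_skipped_with_warning(self, ue_bank):
        small = ue_bank.subset(ue_bank.item_ids[:4])
        matrix, _, _ = generate_responses(
            small, SimulationDesign(n_persons=200, seed=19)
        )
        cov = pd.DataFrame({"constant": np.ones(200, int)})
        with pytest.warns(UserWarning, match="single level"):
            tables = dif_battery(matrix, small, cov)
        assert tables == {}

    def test_median_split_of_continuous_covariate(self):
        vals = pd.Series([30, 40, 50, 53, 60, 70])
        g, desc = binarize_covariate(vals)
        assert np.array_equal(g, np.array([0, 0, 0, 1, 1, 1]))
        assert "51.5" in desc

    def test_two_sample_language_style_design_runs(self, ue_bank):
        """Two cohorts with different trait means plus collapsed sparse
        categories, screened end-to-end."""
        from gradedcat import collapse_categories, suggest_collapse_plan

        design = SimulationDesign(
            n_persons=800, theta_mean=(0.0, -0.5), theta_sd=(1.0, 1.0),
            group_proportions=(0.6, 0.4), seed=20,
        )
        matrix, _, groups = generate_responses(ue_bank, design)
        plan = {
            iid: {0: 0, 1: 1, 2: 2, 3: 3, 4: 3}
            for iid in ("PFA43r1", "PFB16r1", "PFB19r1")
        }
        collapsed = collapse_categories(matrix, plan)
        theta_hat = score_for_dif(matrix, ue_bank)
        res = detect_dif(collapsed, theta_hat, groups)
        assert len(res) == 46
        assert sum(r.flag == "unstable" for r in res) <= 2
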