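"""Core GRM mathematics: category curves, information, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradedcat import (
    ItemParameters,
    Metric,
    Quadrature,
    bank_information,
    category_probabilities,
    eap_score,
    eap_score_matrix,
    item_information,
    reliability_from_se,
    t_score,
)
from gradedcat import test_information_and_se as information_and_se
from gradedcat.simulate import SimulationDesign, generate_responses


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@st.composite
def grm_items(draw):
    slope = draw(st.floats(0.2, 5.0))
    k = draw(st.integers(2, 6))
    base = draw(st.floats(-3.0, 1.0))
    gaps = draw(
        st.lists(st.floats(0.05, 1.5), min_size=k - 2, max_size=k - 2)
    )
    thr = tuple(np.concatenate([[base], base + np.cumsum(gaps)])) if k > 2 else (base,)
    return ItemParameters("h", slope, thr)


class TestCategoryProbabilities:
    def test_cumulative_curve_is_half_at_its_threshold(self, ue_bank):
        for item in list(ue_bank)[:5]:
            for j, b in enumerate(item.thresholds):
                p = category_probabilities(b, item)
                # P(X >= j+1) = 1 - cumulative sum through category j
                assert np.cumsum(p)[j] == pytest.approx(0.5, abs=1e-12)

    def test_published_item_cumulative_at_average_trait(self, ue_bank):
        # a = 1.862, b1 = -0.613: direct evaluation of the logistic curve
        item = ue_bank["PFA14r1"]
        p = category_probabilities(0.0, item)
        p_ge_1 = 1.0 - p[0]
        assert p_ge_1 == pytest.approx(logistic(1.862 * 0.613), abs=1e-12)
        assert p_ge_1 == pytest.approx(0.758, abs=5e-4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(item=grm_items(), theta=st.floats(-6, 6))
    def test_probabilities_sum_to_one_and_are_proper(self, item, theta):
        p = category_probabilities(theta, item)
        assert p.shape == (item.n_categories,)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert abs(p.sum() - 1.0) < 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(item=grm_items())
    def test_cumulative_curves_strictly_increase_in_theta(self, item):
        grid = np.linspace(-5, 5, 41)
        p = np.array([category_probabilities(t, item) for t in grid])
        cum_ge = 1.0 - np.cumsum(p, axis=1)[:, :-1]  # P(X >= k), k = 1..K-1
        diffs = np.diff(cum_ge, axis=0)
        assert np.all(diffs >= 0)
        # strictly increasing wherever the curve is not saturated
        interior = (cum_ge[:-1] > 1e-9) & (cum_ge[:-1] < 1 - 1e-9)
        assert np.all(diffs[interior] > 0)

    def test_invalid_inputs_rejected(self):
        item = ItemParameters("ok", 1.5, (-1.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            category_probabilities(np.nan, item)
        with pytest.raises(ValueError):
            ItemParameters("bad", 1.5, (0.5, -0.5))
        with pytest.raises(ValueError):
            ItemParameters("bad", -1.0, (-0.5, 0.5))


class TestInformation:
    def test_information_vanishes_in_the_tails(self, toy_bank):
        for item in toy_bank:
            assert item_information(25.0, item) < 1e-6
            assert item_information(-25.0, item) < 1e-6
            assert item_information(0.0, item) > 0.0

    def test_higher_slope_gives_more_information_at_a_threshold(self):
        thr = (-0.8, -0.2, 0.4, 1.0)
        lo = ItemParameters("lo", 1.5, thr)
        hi = ItemParameters("hi", 3.0, thr)
        assert item_information(thr[1], hi) > item_information(thr[1], lo)

    def test_information_matches_expected_curvature_oracle(self, toy_bank):
        """I(theta) is the expected negative second derivative of the
        category log-likelihood; check against a finite-difference oracle."""
        eps = 1e-4
        for item in toy_bank:
            for theta in (-1.0, 0.0, 1.3):
                p0 = category_probabilities(theta, item)
                lp_m = np.log(category_probabilities(theta - eps, item))
                lp_0 = np.log(p0)
                lp_p = np.log(category_probabilities(theta + eps, item))
                d2 = (lp_p - 2 * lp_0 + lp_m) / eps**2
                oracle = float(-(p0 * d2).sum())
                assert item_information(theta, item) == pytest.approx(
                    oracle, rel=1e-5
                )

    def test_most_informative_items_at_average_trait(self, ue_bank):
        info = bank_information(ue_bank, 0.0)
        top3 = [ue_bank.item_ids[i] for i in np.argsort(-info)[:3]]
        assert top3 == ["PFB30", "PFA28", "PFA18"]

    def test_test_information_is_additive_and_se_consistent(self, toy_bank):
        infos = [item_information(0.4, it) for it in toy_bank]
        pair_info, se, se_t = information_and_se(
            0.4, toy_bank, item_ids=["t1", "t2"]
        )
        assert pair_info == pytest.approx(infos[0] + infos[1], abs=1e-12)
        assert se == pytest.approx(1.0 / np.sqrt(pair_info), abs=1e-12)
        assert se_t == pytest.approx(10.0 * se, abs=1e-12)

    def test_se_curve_matches_brute_force_summation(self, ue_bank):
        grid = np.linspace(-4, 4, 33)
        for theta in grid:
            brute = sum(item_information(theta, it) for it in ue_bank)
            info, se, se_t = information_and_se(theta, ue_bank)
            assert se_t == pytest.approx(10.0 / np.sqrt(brute), abs=1e-10)


class TestMetric:
    def test_t_score_map(self):
        m = Metric()
        assert t_score(0.0, m) == 50.0
        assert t_score(1.0, m) == 60.0
        assert t_score(-1.61, m) == pytest.approx(33.9)

    def test_reliability_from_se(self):
        m = Metric()
        assert reliability_from_se(3.0, m) == pytest.approx(0.91)
        assert reliability_from_se(10.0, m) == 0.0
        assert reliability_from_se(12.0, m) == 0.0  # clamped
        assert reliability_from_se(10 * np.sqrt(0.1), m) == pytest.approx(0.900)

    def test_reliability_increases_with_information(self):
        m = Metric()
        infos = np.linspace(1.5, 20, 30)
        rel = [reliability_from_se(10.0 / np.sqrt(i), m) for i in infos]
        assert np.all(np.diff(rel) > 0)


class TestEAP:
    def test_no_answers_returns_the_prior(self, ue_bank):
        est = eap_score({}, ue_bank)
        assert est.theta == 0.0
        assert est.se_theta == 1.0
        assert est.n_items_used == 0
        assert est.t_score == 50.0

    def test_top_category_pattern_scores_positive(self, toy_bank):
        est = eap_score([4, 4, 4, 4, 4], toy_bank)
        assert est.theta > 0.5
        bottom = eap_score([0, 0, 0, 0, 0], toy_bank)
        assert bottom.theta < -0.5

    def test_matches_dense_grid_oracle(self, toy_bank):
        """Default 61-node quadrature against a 10,001-point trapezoid
        posterior over [-6, 6]."""
        dense = np.linspace(-6, 6, 10001)
        prior = np.exp(-0.5 * dense**2)
        for pattern in ([0, 1, 2, 3, 4], [4, 4, 0, 1, 2], [2, 2, 2, 2, 2]):
            like = np.ones_like(dense)
            for item, code in zip(toy_bank, pattern):
                like *= np.array(
                    [category_probabilities(t, item)[code] for t in dense]
                )
            post = prior * like
            post /= np.trapezoid(post, dense)
            mean = np.trapezoid(dense * post, dense)
            sd = np.sqrt(np.trapezoid((dense - mean) ** 2 * post, dense))
            est = eap_score(pattern, toy_bank, Quadrature.default(201, -6, 6))
            assert est.theta == pytest.approx(mean, abs=1e-4)
            assert est.se_theta == pytest.approx(sd, abs=1e-4)

    def test_posterior_sd_never_exceeds_prior_sd(self, ue_bank, cohort):
        matrix, _, _ = cohort
        ests = eap_score_matrix(matrix.codes[:200], ue_bank)
        assert all(e.se_theta <= 1.0 + 1e-9 for e in ests)

    def test_se_t_is_metric_scaled(self, ue_bank, cohort):
        matrix, _, _ = cohort
        ests = eap_score_matrix(matrix.codes[:50], ue_bank)
        for e in ests:
            assert e.se_t == pytest.approx(10.0 * e.se_theta, abs=1e-12)

    def test_full_bank_scoring_recovers_truth_with_small_bias(self, ue_bank, cohort):
        matrix, thetas, _ = cohort
        ests = eap_score_matrix(matrix.codes, ue_bank)
        est_theta = np.array([e.theta for e in ests])
        assert abs(np.mean(est_theta - thetas)) < 0.05

    def test_out_of_range_code_rejected(self, toy_bank):
        with pytest.raises(ValueError):
            eap_score([5, 0, 0, 0, 0], toy_bank)
        with pytest.raises(KeyError):
            eap_score({"nope": 1}, toy_bank)
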