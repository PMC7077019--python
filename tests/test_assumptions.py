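"""Assumption screening: polychorics, factor criteria, local dependence,
Mokken scalability."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gradedcat import (
    MinorFactor,
    SimulationDesign,
    assumption_report,
    bifactor_indices,
    efa_criteria,
    forced_two_factor_varimax,
    generate_responses,
    mokken_scalability,
    polychoric_matrix,
    residual_analysis,
)
from gradedcat.assumptions import _principal_axis, bvn_cdf
from gradedcat.grm import ResponseMatrix


@pytest.fixture(scope="module")
def cohort_corr(cohort):
    matrix, _, _ = cohort
    return polychoric_matrix(matrix)


class TestBivariateNormal:
    def test_matches_scipy_cdf(self, rng):
        for rho in (-0.9, -0.4, 0.0, 0.25, 0.7, 0.95):
            pts = rng.normal(scale=1.8, size=(40, 2))
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf(pts)
            mine = bvn_cdf(pts[:, 0], pts[:, 1], rho)
            assert np.abs(ref - mine).max() < 1e-10

    def test_infinite_limits(self):
        assert bvn_cdf(np.inf, 0.0, 0.5) == pytest.approx(0.5, abs=1e-12)
        assert bvn_cdf(-np.inf, 0.0, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert bvn_cdf(np.inf, np.inf, -0.3) == pytest.approx(1.0, abs=1e-12)


class TestPolychoric:
    def test_recovers_latent_correlation(self, rng):
        n = 20_000
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        cuts = [-1.0, -0.3, 0.4, 1.1]
        codes = np.column_stack(
            [np.digitize(z[:, 0], cuts), np.digitize(z[:, 1], cuts)]
        )
        m = ResponseMatrix([str(i) for i in range(n)], ["x", "y"], codes)
        r = polychoric_matrix(m)
        assert r[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_independent_items_near_zero(self, rng):
        n = 5000
        codes = rng.integers(0, 5, size=(n, 3))
        m = ResponseMatrix([str(i) for i in range(n)], ["a", "b", "c"], codes)
        r = polychoric_matrix(m)
        off = r[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 3 * (1.5 / np.sqrt(n))

    def test_symmetry_and_unit_diagonal(self, cohort):
        matrix, _, _ = cohort
        sub = matrix.subset_items(matrix.item_ids[:8])
        r = polychoric_matrix(sub)
        assert np.array_equal(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.linalg.eigvalsh(r).min() > -1e-8

    def test_zero_variance_item_named_in_error(self):
        codes = np.column_stack([np.zeros(50, int), np.arange(50) % 5])
        m = ResponseMatrix([str(i) for i in range(50)], ["flat", "ok"], codes)
        with pytest.raises(ValueError, match="flat"):
            polychoric_matrix(m)


class TestEFACriteria:
    def test_identity_matrix_fails_both_rules(self):
        eig, pct, ratio, flags = efa_criteria(np.eye(12))
        assert np.allclose(eig, 1.0)
        assert ratio == pytest.approx(1.0)
        assert not flags["first_factor_pct"]
        assert not flags["first_to_second_ratio"]

    def test_one_factor_closed_form(self):
        p, lam = 20, 0.8
        corr = np.full((p, p), lam * lam)
        np.fill_diagonal(corr, 1.0)
        eig, pct, ratio, flags = efa_criteria(corr)
        assert eig[0] == pytest.approx(1 + (p - 1) * lam**2, abs=1e-9)
        assert eig[1] == pytest.approx(1 - lam**2, abs=1e-9)
        assert ratio > 4 and flags["first_to_second_ratio"]
        assert pct == pytest.approx((1 + (p - 1) * 0.64) / p, abs=1e-9)

    def test_strongly_unidimensional_scale_pattern(self, cohort_corr):
        eig, pct, ratio, flags = efa_criteria(cohort_corr)
        assert pct > 0.20 and ratio > 4
        assert flags["first_factor_pct"] and flags["first_to_second_ratio"]
        assert eig[0] > 20  # same order as the published 30.1


class TestTwoFactorEFA:
    def test_planted_subset_loads_on_one_factor(self, ue_bank):
        sub = tuple(ue_bank.item_ids[:20])
        matrix, _, _ = generate_responses(
            ue_bank,
            SimulationDesign(n_persons=2000, seed=8,
                             minor_factor=MinorFactor(sub, 0.5)),
        )
        r = polychoric_matrix(matrix)
        loadings = forced_two_factor_varimax(r)
        dom = np.abs(loadings[:, 0]) > np.abs(loadings[:, 1])
        in_subset = np.array([iid in sub for iid in matrix.item_ids])
        # the planted block loads dominantly on a single rotated factor
        agreement = max((dom == in_subset).mean(), (dom == ~in_subset).mean())
        assert agreement > 0.9

    def test_rotation_preserves_communalities(self, cohort):
        matrix, _, _ = cohort
        r = polychoric_matrix(matrix.subset_items(matrix.item_ids[:12]))
        unrot = _principal_axis(r, 2)
        rot = forced_two_factor_varimax(r)
        assert np.allclose(
            (unrot**2).sum(axis=1), (rot**2).sum(axis=1), atol=1e-8
        )

    def test_single_factor_data_has_small_second_extraction(self, cohort_corr):
        unrot = _principal_axis(cohort_corr, 2)
        ss = (unrot**2).sum(axis=0)
        assert ss[1] / ss.sum() < 0.10


class TestBifactor:
    def test_pure_one_factor_gives_full_ecv(self):
        lam = np.full(20, 0.8)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        omega_h, ecv, general, group = bifactor_indices(corr)
        assert ecv == pytest.approx(1.0)
        assert np.allclose(group, 0.0)
        # omega_h equals omega_total when there is no group variance
        num = general.sum() ** 2
        assert omega_h == pytest.approx(num / (num + (1 - general**2).sum()), abs=1e-6)

    def test_correlated_block_structure_recovers_factor_correlation(self):
        lam = np.zeros((20, 2))
        lam[:10, 0] = lam[10:, 1] = 0.75
        phi = np.array([[1.0, 0.9], [0.9, 1.0]])
        corr = lam @ phi @ lam.T
        np.fill_diagonal(corr, 1.0)
        omega_h, ecv, _, _ = bifactor_indices(corr)
        # equal second-order loadings: ECV equals the factor correlation
        assert ecv == pytest.approx(0.9, abs=0.02)
        assert omega_h > 0.85

    @pytest.mark.parametrize("share,seed,low", [(0.7, 21, True), (0.1, 22, False)])
    def test_minor_factor_strength_moves_indices(self, ue_bank, share, seed, low):
        sub = tuple(ue_bank.item_ids[:20])
        matrix, _, _ = generate_responses(
            ue_bank,
            SimulationDesign(n_persons=2000, seed=seed,
                             minor_factor=MinorFactor(sub, share)),
        )
        r = polychoric_matrix(matrix)
        omega_h, ecv, _, _ = bifactor_indices(r)
        if low:
            assert ecv < 0.60
        else:
            assert ecv > 0.60 and omega_h > 0.80


class TestResiduals:
    def test_perfect_one_factor_matrix_has_zero_residuals(self):
        lam = np.linspace(0.5, 0.9, 15)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        rep = residual_analysis(corr)
        assert np.abs(rep.residuals).max() < 1e-6
        assert rep.srmr < 1e-6
        assert rep.flagged_pairs == []

    def test_pair_count_and_critical_offset(self, cohort_corr):
        rep = residual_analysis(cohort_corr)
        assert rep.n_pairs == 46 * 45 // 2 == 1035
        assert rep.critical - rep.mean == pytest.approx(0.20, abs=1e-15)
        for i, j, v in rep.flagged_pairs:
            assert v > rep.critical

    def test_locally_dependent_pair_is_flagged(self):
        lam = np.full(12, 0.7)
        corr = np.outer(lam, lam)
        corr[0, 1] = corr[1, 0] = 0.95  # a redundant item pair
        np.fill_diagonal(corr, 1.0)
        rep = residual_analysis(corr)
        assert any({i, j} == {0, 1} for i, j, _ in rep.flagged_pairs)
        assert rep.srmr > 0


class TestMokken:
    def test_comonotone_items_scale_perfectly(self):
        x = np.tile(np.arange(5), 40)
        codes = np.column_stack([x, x, x])
        m = ResponseMatrix([str(i) for i in range(x.size)], ["a", "b", "c"], codes)
        h, h_i, h_ij = mokken_scalability(m)
        assert h == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(h_i, 1.0)

    def test_independent_items_scale_near_zero(self, rng):
        codes = rng.integers(0, 5, size=(4000, 4))
        m = ResponseMatrix([str(i) for i in range(4000)], list("abcd"), codes)
        h, h_i, _ = mokken_scalability(m)
        assert abs(h) < 0.05

    def test_reference_bank_data_meet_monotonicity_rules(self, cohort):
        matrix, _, _ = cohort
        h, h_i, h_ij = mokken_scalability(matrix)
        assert h >= 0.50
        assert np.all(h_i >= 0.30)
        assert np.nanmax(h_ij) <= 1.0 + 1e-12

    def test_constant_item_excluded_with_warning(self):
        codes = np.column_stack(
            [np.zeros(100, int), np.arange(100) % 5, (np.arange(100) // 2) % 5]
        )
        m = ResponseMatrix([str(i) for i in range(100)], ["flat", "a", "b"], codes)
        with pytest.warns(UserWarning, match="flat"):
            h, h_i, _ = mokken_scalability(m)
        assert h_i.size == 2


def test_combined_report_on_reference_cohort(cohort):
    matrix, _, _ = cohort
    rep = assumption_report(matrix)
    assert rep.residual_critical - rep.residual_mean == pytest.approx(0.20)
    assert rep.criteria_met["first_factor_pct"]
    assert rep.criteria_met["mokken_scale"]
    assert rep.criteria_met["ecv"] and rep.criteria_met["omega_h"]
    assert 0 <= rep.ecv <= 1 and 0 <= rep.omega_h <= 1
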