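"""Univariate liability-threshold model: cells, likelihood, fit, tetrachoric."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from kinliab import (
    DEFAULT_RELATEDNESS,
    RelatednessMap,
    VarianceComponents,
    cell_probabilities,
    delta_method_ci,
    expected_pair_correlation,
    fit_univariate,
    loglik_univariate,
    tabulate_pairs,
    tetrachoric,
)
from kinliab.liability_model import _canonical_strata
from kinliab._mvnorm import bvn_upper


class TestPairCorrelation:
    @pytest.mark.parametrize("vc,pt,expected", [
        ((1.0, 0.0), "MZ", 1.0),
        ((0.65, 0.03), "FS", 0.355),          # 0.5*0.65 + 1.0*0.03
        ((0.0, 1.0), "PHS", 0.03),
        ((0.73, 0.0), "MHS", 0.1825),
    ])
    def test_expected_correlation(self, vc, pt, expected):
        comps = VarianceComponents(vc[0], vc[1], 1 - vc[0] - vc[1])
        assert expected_pair_correlation(comps, pt) == pytest.approx(expected)

    def test_unknown_pair_type_raises(self):
        vc = VarianceComponents(0.5, 0.0, 0.5)
        with pytest.raises(ValueError, match="unknown pair type"):
            expected_pair_correlation(vc, "COUSIN")

    def test_relmap_validates_range(self):
        with pytest.raises(ValueError):
            RelatednessMap(r_a={"FS": 1.5}, r_c={"FS": 1.0})


class TestCellProbabilities:
    def test_independence_at_median(self):
        np.testing.assert_allclose(cell_probabilities(0.0, 0.0, 0.0),
                                   [0.25, 0.25, 0.25, 0.25], atol=1e-12)

    def test_perfect_correlation_degenerate(self):
        t = 0.7
        p = cell_probabilities(1.0, t, t)
        np.testing.assert_allclose(
            p, [norm.sf(t), 0.0, 0.0, norm.cdf(t)], atol=1e-12)

    def test_frozen_quadrature_value(self):
        # dense Gauss-Legendre oracle, computed independently
        p = cell_probabilities(0.355, 1.2265, 1.2265)
        assert p[0] == pytest.approx(0.0281783858, abs=1e-8)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            cell_probabilities(1.2, 0.0, 0.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(r=st.floats(-0.99, 0.99), t1=st.floats(-3, 3), t2=st.floats(-3, 3))
    def test_cells_form_distribution(self, r, t1, t2):
        p = cell_probabilities(r, t1, t2)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-8

    def test_concordance_increases_with_correlation(self):
        for t in (-1.0, 0.5, 2.0):
            p11 = [bvn_upper(r, t, t) for r in np.linspace(-0.95, 0.95, 20)]
            assert np.all(np.diff(p11) > 0)


class TestLoglik:
    def test_single_cell_independent(self):
        counts = {"FS": np.array([1.0, 0, 0, 0])}
        ll = loglik_univariate(np.array([0.0, 0.0, 0.0]), counts)
        assert ll == pytest.approx(math.log(0.25))

    def test_linear_in_counts(self):
        counts = {"FS": np.array([30.0, 20, 25, 400]),
                  "PHS": np.array([3.0, 12, 15, 150])}
        params = np.array([0.8, 0.3, 1.0, 1.1])
        ll1 = loglik_univariate(params, counts)
        ll2 = loglik_univariate(params, {k: 2 * v for k, v in counts.items()})
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_aggregated_equals_per_pair_sum(self, sibling_cohort_small):
        df = sibling_cohort_small.records.sample(1000, random_state=5)
        counts = tabulate_pairs(df)
        params = np.concatenate([[0.9, 0.4],
                                 0.84 * np.ones(len(counts))])
        agg = loglik_univariate(params, counts)
        strata = _canonical_strata(counts)
        tidx = {s: i for i, s in enumerate(strata)}
        brute = 0.0
        for _, row in df.iterrows():
            t = params[2 + tidx[row["pair_type"]]]
            vc = VarianceComponents(*_vc_from_internal(0.9, 0.4))
            r = expected_pair_correlation(vc, row["pair_type"])
            p = cell_probabilities(r, t, t)
            cell = (1 - row["trait1_m1"]) * 2 + (1 - row["trait1_m2"])
            brute += math.log(p[cell])
        assert agg == pytest.approx(brute, abs=1e-9)

    def test_member_swap_invariance(self, sibling_cohort_small):
        df = sibling_cohort_small.records.groupby("pair_type").head(1500)
        swapped = df.rename(columns={"trait1_m1": "trait1_m2",
                                     "trait1_m2": "trait1_m1"})
        params = np.array([0.7, 0.2, 0.8, 0.9, 1.0])
        assert loglik_univariate(params, tabulate_pairs(df)) == pytest.approx(
            loglik_univariate(params, tabulate_pairs(swapped)), rel=1e-12)

    def test_impossible_cell_gives_neg_inf(self):
        counts = {"MZ": np.array([0.0, 1.0, 0, 0])}  # discordant MZ pair
        # a2=1 => r=1 => discordant cell has probability zero
        params = np.array([1e8, 0.0, 0.5])
        assert loglik_univariate(params, counts) == -np.inf


def _vc_from_internal(z_a, z_c):
    D = 1 + z_a ** 2 + z_c ** 2
    return z_a ** 2 / D, z_c ** 2 / D, 1 / D


class TestFit:
    def test_recovers_generating_components(self, sibling_cohort_small):
        fit = fit_univariate(sibling_cohort_small.records)
        assert fit.components.a2 == pytest.approx(0.5, abs=0.06)
        assert fit.components.c2 == pytest.approx(0.2, abs=0.04)
        assert fit.convergence["success"]
        lo, hi = fit.ci95["a2"]
        assert lo < fit.components.a2 < hi

    def test_null_model_estimates_near_zero(self):
        from kinliab import GeneratingModel, simulate_univariate_pairs
        model = GeneratingModel.univariate(0.0, 0.0, 0.15)
        cohort = simulate_univariate_pairs(
            model, n_by_pair_type={"FS": 30000, "PHS": 15000}, seed=3)
        fit = fit_univariate(cohort.records)
        assert fit.components.a2 < 0.05
        assert fit.components.c2 < 0.05

    def test_single_stratum_fixes_c2(self):
        counts = {"FS": np.array([300.0, 700, 700, 8300])}
        with pytest.warns(UserWarning, match="not\\s+jointly identifiable"):
            fit = fit_univariate(counts)
        assert fit.c2_fixed
        assert fit.components.c2 == 0.0

    def test_covariate_threshold_regression_recovers_slope(self):
        from kinliab import GeneratingModel, simulate_univariate_pairs
        model = GeneratingModel(a2=0.5, c2=0.2, e2=0.3,
                                prevalence_by_stratum={"FS": 0.2, "PHS": 0.2},
                                covariate_effects={"sex": 0.3})
        cohort = simulate_univariate_pairs(
            model, n_by_pair_type={"FS": 40000, "PHS": 20000}, seed=8)
        fit = fit_univariate(cohort.records, covariates=("sex",),
                             compute_ci=False)
        assert fit.thresholds.covariate_slopes["sex"] == pytest.approx(
            0.3, abs=0.05)
        assert fit.components.a2 == pytest.approx(0.5, abs=0.08)

    def test_thresholds_match_stratum_prevalence(self, sibling_cohort_small):
        fit = fit_univariate(sibling_cohort_small.records, compute_ci=False)
        for s in fit.strata:
            assert fit.thresholds.thresholds[s] == pytest.approx(
                norm.isf(0.2), abs=0.05)


class TestDeltaMethod:
    def test_identity_transform(self):
        lo, hi = delta_method_ci(None, lambda p: p[0], clip=None,
                                 params=np.array([0.4]),
                                 vcov=np.array([[0.01]]))
        assert lo == pytest.approx(0.4 - 1.959964 * 0.1, abs=1e-5)
        assert hi == pytest.approx(0.4 + 1.959964 * 0.1, abs=1e-5)

    def test_zero_gradient_gives_zero_width(self):
        lo, hi = delta_method_ci(None, lambda p: p[0] ** 2, clip=None,
                                 params=np.array([0.0]),
                                 vcov=np.array([[4.0]]))
        assert lo == hi == 0.0

    def test_missing_vcov_raises(self):
        with pytest.raises(ValueError, match="profile-likelihood"):
            delta_method_ci(None, lambda p: p[0], params=np.array([0.4]),
                            vcov=None)


class TestTetrachoric:
    def test_independent_table(self):
        res = tetrachoric(np.array([[25, 25], [25, 25]]))
        assert res.r == pytest.approx(0.0, abs=1e-6)
        assert res.t1 == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_table_closed_form(self):
        # margins 50/50 force t=0; r then solves P(both above) = 0.4
        res = tetrachoric(np.array([[40, 10], [10, 40]]))
        assert res.r == pytest.approx(math.sin(0.3 * math.pi), abs=1e-3)
        assert res.t1 == pytest.approx(0.0, abs=1e-4)
        assert res.t2 == pytest.approx(0.0, abs=1e-4)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            tetrachoric(np.array([[0, 0], [30, 50]]))

    def test_zero_off_diagonal_warns_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            res = tetrachoric(np.array([[40, 0], [10, 40]]))
        assert res.boundary
        assert res.r > 0.9

    def test_matches_grid_search_oracle(self, rng):
        # the 3-parameter model saturates a 2x2 table, so ML thresholds come
        # from the margins exactly and r can be found by brute-force search
        for _ in range(8):
            n = rng.multinomial(400, rng.dirichlet(np.ones(4))).reshape(2, 2)
            if (n.sum(axis=0) == 0).any() or (n.sum(axis=1) == 0).any() \
                    or n[0, 1] == 0 or n[1, 0] == 0:
                continue
            t1 = norm.isf(n[0].sum() / n.sum())
            t2 = norm.isf(n[:, 0].sum() / n.sum())
            grid = np.arange(-0.999, 0.9991, 5e-4)
            lls = []
            for r in grid:
                p = cell_probabilities(r, t1, t2)
                if p.min() <= 0:
                    lls.append(-np.inf)
                    continue
                lls.append(float((n.ravel() * np.log(p)).sum()))
            r_grid = grid[int(np.argmax(lls))]
            res = tetrachoric(n)
            assert res.r == pytest.approx(r_grid, abs=1e-3)
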