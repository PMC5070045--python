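"""Simulators: prevalence matching, correlation structure, determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, norm

from kinliab import (
    CholeskyPaths,
    GeneratingModel,
    deprivation_binarize,
    read_pair_table,
    select_pairs,
    simulate_bivariate_pairs,
    simulate_prs_cohort,
    simulate_univariate_pairs,
    tetrachoric,
    threshold_from_prevalence,
    write_pair_table,
)
from kinliab.liability_model import tabulate_pairs


class TestThreshold:
    @pytest.mark.parametrize("K,t", [
        (0.5, 0.0),
        (0.11, 1.2265),       # standard-normal quantile table
        (0.003, 2.7478),      # rare-disorder prevalence regime
    ])
    def test_quantile_values(self, K, t):
        assert threshold_from_prevalence(K) == pytest.approx(t, abs=1e-4)

    def test_round_trip_prevalence(self):
        for K in (0.01, 0.25, 0.9):
            assert norm.sf(threshold_from_prevalence(K)) == pytest.approx(K)

    @pytest.mark.parametrize("K", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, K):
        with pytest.raises(ValueError):
            threshold_from_prevalence(K)


class TestUnivariateSimulation:
    def test_prevalence_and_tetrachoric_converge(self):
        model = GeneratingModel.univariate(0.65, 0.03, 0.11)
        cohort = simulate_univariate_pairs(model, n_by_pair_type={"FS": 150000},
                                           seed=42)
        df = cohort.records
        prev = (df["trait1_m1"].mean() + df["trait1_m2"].mean()) / 2
        assert prev == pytest.approx(0.11, abs=0.004)
        counts = tabulate_pairs(df)["FS"]
        res = tetrachoric(counts.reshape(2, 2))
        # generating FS correlation 0.5*0.65 + 1.0*0.03
        assert res.r == pytest.approx(0.355, abs=0.015)

    def test_perfect_familial_correlation_mz(self):
        model = GeneratingModel.univariate(1.0, 0.0, 0.3)
        cohort = simulate_univariate_pairs(model, n_by_pair_type={"MZ": 5000},
                                           seed=1)
        df = cohort.records
        assert (df["trait1_m1"] == df["trait1_m2"]).all()

    def test_independent_members_without_a_and_c(self):
        model = GeneratingModel.univariate(0.0, 0.0, 0.3)
        cohort = simulate_univariate_pairs(model, n_by_pair_type={"FS": 100000},
                                           seed=2)
        df = cohort.records
        cov = np.cov(df["trait1_m1"], df["trait1_m2"])[0, 1]
        assert cov == pytest.approx(0.0, abs=0.002)

    def test_seed_reproducibility(self):
        model = GeneratingModel.univariate(0.5, 0.1, 0.2)
        n = {"FS": 2000, "MHS": 500}
        a = simulate_univariate_pairs(model, n_by_pair_type=n, seed=7)
        b = simulate_univariate_pairs(model, n_by_pair_type=n, seed=7)
        c = simulate_univariate_pairs(model, n_by_pair_type=n, seed=8)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert not a.records.equals(c.records)

    def test_unknown_pair_type_raises(self):
        model = GeneratingModel.univariate(0.5, 0.1, 0.2)
        with pytest.raises(ValueError, match="unknown pair type"):
            simulate_univariate_pairs(model, n_by_pair_type={"XX": 10}, seed=0)

    def test_counts_invariant(self):
        model = GeneratingModel.univariate(0.5, 0.1, 0.2)
        cohort = simulate_univariate_pairs(
            model, n_by_pair_type={"FS": 100, "PHS": 50}, seed=0)
        assert sum(cohort.counts_by_pair_type.values()) == len(cohort.records)

    def test_generating_model_invariants(self):
        with pytest.raises(ValueError, match="must equal 1"):
            GeneratingModel(a2=0.5, c2=0.2, e2=0.2,
                            prevalence_by_stratum={"FS": 0.1})
        with pytest.raises(ValueError, match="prevalence"):
            GeneratingModel(a2=0.5, c2=0.2, e2=0.3,
                            prevalence_by_stratum={"FS": 1.2})


class TestBivariateSimulation:
    PATHS = CholeskyPaths.from_variance_components(0.65, 0.03, 0.73, 0.0,
                                                   r_g=0.32)

    def test_marginals_match_univariate_in_distribution(self):
        n = {"FS": 40000}
        model2 = GeneratingModel.bivariate(self.PATHS, 0.11, 0.05)
        biv = simulate_bivariate_pairs(model2, n_by_pair_type=n, seed=9)
        model1 = GeneratingModel.univariate(0.65, 0.03, 0.11)
        uni = simulate_univariate_pairs(model1, n_by_pair_type=n, seed=10)
        c_biv = tabulate_pairs(biv.records, trait=1)["FS"]
        c_uni = tabulate_pairs(uni.records, trait=1)["FS"]
        stat, p, *_ = chi2_contingency(np.vstack([c_biv, c_uni]))
        assert p > 0.001

    def test_zero_cross_paths_give_independent_traits(self):
        paths = CholeskyPaths.from_variance_components(0.6, 0.0, 0.5, 0.2)
        model = GeneratingModel.bivariate(paths, 0.2, 0.3)
        cohort = simulate_bivariate_pairs(model, n_by_pair_type={"FS": 80000},
                                          seed=3)
        df = cohort.records
        cov = np.cov(df["trait1_m1"], df["trait2_m1"])[0, 1]
        assert cov == pytest.approx(0.0, abs=0.003)

    def test_genetic_cross_path_induces_cross_member_covariance(self):
        model = GeneratingModel.bivariate(self.PATHS, 0.2, 0.2)
        cohort = simulate_bivariate_pairs(model, n_by_pair_type={"FS": 80000},
                                          seed=4)
        df = cohort.records
        cov = np.cov(df["trait1_m1"], df["trait2_m2"])[0, 1]
        assert cov > 0.005

    def test_within_person_cross_trait_correlation(self):
        model = GeneratingModel.bivariate(self.PATHS, 0.11, 0.11)
        cohort = simulate_bivariate_pairs(model, n_by_pair_type={"FS": 120000},
                                          seed=5)
        df = cohort.records
        tbl = np.array([
            [((df.trait1_m1 == 1) & (df.trait2_m1 == 1)).sum(),
             ((df.trait1_m1 == 1) & (df.trait2_m1 == 0)).sum()],
            [((df.trait1_m1 == 0) & (df.trait2_m1 == 1)).sum(),
             ((df.trait1_m1 == 0) & (df.trait2_m1 == 0)).sum()]])
        res = tetrachoric(tbl)
        assert res.r == pytest.approx(0.2204, abs=0.02)

    def test_requires_paths_and_second_prevalence(self):
        model = GeneratingModel.univariate(0.5, 0.1, 0.2)
        with pytest.raises(ValueError, match="paths"):
            simulate_bivariate_pairs(model, n_by_pair_type={"FS": 10}, seed=0)


class TestDeprivationBinarize:
    def test_distinct_scores_95th(self):
        flags = deprivation_binarize(np.arange(100.0), 0.95)
        assert flags.sum() == 5

    def test_distinct_scores_75th(self):
        flags = deprivation_binarize(np.arange(1000.0), 0.75)
        assert flags.sum() == 250

    def test_ties_never_flagged(self):
        # cutoff is sorted[4] = 5; only strictly greater values flagged
        scores = np.array([1, 2, 3, 4, 5, 5, 5, 8, 9, 10], float)
        flags = deprivation_binarize(scores, 0.5)
        assert flags.sum() == 3
        assert set(scores[flags == 1]) == {8, 9, 10}

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            deprivation_binarize(np.array([]), 0.95)
        with pytest.raises(ValueError, match="percentile"):
            deprivation_binarize(np.ones(5), 1.5)


class TestSelectPairs:
    @staticmethod
    def _family(fam, births, mothers=None, fathers=None):
        n = len(births)
        return pd.DataFrame({
            "person_id": [f"{fam}-{i}" for i in range(n)],
            "family_id": fam,
            "birth_year": births,
            "mother_id": mothers or [f"m{fam}"] * n,
            "father_id": fathers or [f"f{fam}"] * n,
        })

    def test_oldest_two_within_five_years(self):
        fam = self._family(1, [1953, 1951, 1960])
        pairs = select_pairs(fam)
        assert len(pairs) == 1
        assert (pairs.loc[0, "birth_year_m1"],
                pairs.loc[0, "birth_year_m2"]) == (1951, 1953)
        assert pairs.loc[0, "pair_type"] == "FS"

    def test_wide_gap_yields_no_pair(self):
        assert select_pairs(self._family(1, [1951, 1958])).empty

    def test_singleton_family_yields_no_pair(self):
        assert select_pairs(self._family(1, [1955])).empty

    def test_half_sibling_classification(self):
        mhs = self._family(1, [1951, 1953], fathers=["fA", "fB"])
        phs = self._family(2, [1951, 1953], mothers=["mA", "mB"])
        assert select_pairs(mhs).loc[0, "pair_type"] == "MHS"
        assert select_pairs(phs).loc[0, "pair_type"] == "PHS"

    def test_unrelated_members_raise(self):
        fam = self._family(1, [1951, 1953], mothers=["mA", "mB"],
                           fathers=["fA", "fB"])
        with pytest.raises(ValueError, match="parent"):
            select_pairs(fam)

    def test_missing_parent_raises(self):
        fam = self._family(1, [1951, 1953])
        fam.loc[0, "mother_id"] = np.nan
        with pytest.raises(ValueError, match="missing parent"):
            select_pairs(fam)


class TestPrsCohort:
    def test_null_target_gives_zero_weights(self):
        cohort = simulate_prs_cohort(n=100, m=50, target_r2=0.0, seed=0)
        assert (cohort.weights.table["beta"] == 0).all()

    def test_every_threshold_nonempty(self):
        cohort = simulate_prs_cohort(n=50, m=30, target_r2=0.01, seed=1)
        p = cohort.weights.table["pvalue"]
        for pt in (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0):
            assert (p <= pt).sum() > 0

    def test_true_score_variance_matches_target(self):
        cohort = simulate_prs_cohort(n=20000, m=1000, target_r2=0.05, seed=2)
        w = cohort.weights.table
        score = cohort.genotypes.dosages @ w["beta"].to_numpy()
        assert np.var(cohort.outcome) == pytest.approx(1.0, abs=0.05)
        assert np.var(score) == pytest.approx(0.05, abs=0.01)

    def test_reproducible(self):
        a = simulate_prs_cohort(n=200, m=100, target_r2=0.01, seed=5)
        b = simulate_prs_cohort(n=200, m=100, target_r2=0.01, seed=5)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.outcome, b.outcome)

    def test_invalid_target_r2(self):
        with pytest.raises(ValueError):
            simulate_prs_cohort(n=10, m=10, target_r2=1.0, seed=0)


class TestPairTableIO:
    def test_round_trip(self, tmp_path, toy_pairs):
        path = tmp_path / "pairs.tsv"
        write_pair_table(toy_pairs, path)
        back = read_pair_table(path)
        pd.testing.assert_frame_equal(back, toy_pairs)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"pair_id": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            read_pair_table(path)
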