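import math

import numpy as np
import pandas as pd
import pytest

from illdeath.prep import (DataConsistencyError, DegenerateCovariateError,
                           build_transition_datasets, descriptive_compare,
                           impute_chained, pool_estimates, standardize)
from illdeath.synthetic import (Cohort, inject_missingness, paper_like_config,
                                simulate_illness_death)


class TestStandardize:
    def test_two_point_column(self):
        # mean 5, sd sqrt(50) = 7.0711, so (10-5)/(2 sd) = 0.353553...
        z, (mean, sd) = standardize([0.0, 10.0])
        assert mean == 5.0 and sd == pytest.approx(math.sqrt(50))
        assert z[0] == pytest.approx(-5 / (2 * math.sqrt(50)), abs=1e-12)
        assert z[1] == pytest.approx(0.35355339, abs=1e-8)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            standardize([3.0, 3.0, 3.0])

    def test_output_scale(self):
        rng = np.random.default_rng(0)
        z, _ = standardize(rng.normal(10, 3, 500))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-10)
        assert np.std(z, ddof=1) == pytest.approx(0.5, abs=1e-10)

    def test_inverse_transform(self):
        x = np.array([1.0, 4.0, 9.0, 2.5])
        z, (mean, sd) = standardize(x)
        assert np.allclose(mean + 2 * sd * z, x)


def _mini_patients(rows):
    cols = ["hospital_id", "patient_id", "sex_female", "age", "kps_ge90",
            "solitary", "n_treated_mets", "site", "chemo", "max_volume_ccm",
            "time_death", "event_death", "time_relapse", "relapse_observed"]
    return pd.DataFrame(rows, columns=cols)


def _mini_lesions(rows):
    cols = ["hospital_id", "patient_id", "lesion_id", "site", "volume_ccm",
            "ptv_volume_ccm", "chemo", "motion_advanced", "algo_advanced",
            "bed_iso", "time_lc", "event_lc"]
    return pd.DataFrame(rows, columns=cols)


class TestTransitionDatasets:
    def _tiny_cohort(self, relapse=5.0, death=8.0, event_death=1, relapse_obs=1):
        patients = _mini_patients([
            [1, 1, 0, 60.0, 1, 1, 1, "liver", 1, 20.0, death, event_death,
             relapse if relapse_obs else np.nan, relapse_obs],
            [1, 2, 1, 70.0, 0, 0, 2, "lung", 0, 5.0, 12.0, 0, np.nan, 0],
        ])
        lesions = _mini_lesions([
            [1, 1, 1, "liver", 20.0, 25.0, 1, 0, 1, 150.0,
             relapse if relapse_obs else death, relapse_obs],
            [1, 2, 2, "lung", 5.0, 6.0, 0, 1, 0, 100.0, 12.0, 0],
            [1, 2, 3, "lung", 3.0, 4.0, 0, 1, 0, 120.0, 12.0, 0],
        ])
        return Cohort(lesions, patients)

    def test_relapse_then_death_rows(self):
        ds = build_transition_datasets(*self._tiny_cohort())
        f2 = ds[2].frame
        # patient 1: censored for transition 2 at the relapse time
        row = f2[f2.index == 0].iloc[0]
        assert (row["entry"], row["exit"], row["event"]) == (0.0, 5.0, 0)
        f3 = ds[3].frame
        assert len(f3) == 1
        assert (f3.iloc[0]["entry"], f3.iloc[0]["exit"], f3.iloc[0]["event"]) == (5.0, 8.0, 1)

    def test_censored_alive_no_transition3_row(self):
        ds = build_transition_datasets(*self._tiny_cohort())
        f2, f3 = ds[2].frame, ds[3].frame
        assert (f2.iloc[1]["exit"], f2.iloc[1]["event"]) == (12.0, 0)
        assert len(f3) == 1  # only the relapsed patient

    def test_relapse_after_death_rejected(self):
        coh = self._tiny_cohort(relapse=9.0, death=8.0)
        with pytest.raises(DataConsistencyError):
            build_transition_datasets(*coh)

    def test_partition_invariants(self, cohort, datasets):
        """Each patient has one transition-2 row; a transition-3 row iff
        relapsed; the rows partition follow-up at the relapse time; the
        events across transitions 2+3 count every death exactly once."""
        p = cohort.patients
        assert len(datasets[2].frame) == len(p)
        assert len(datasets[3].frame) == int(p["relapse_observed"].sum())
        total_deaths = int(p["event_death"].sum())
        assert datasets[2].n_events + datasets[3].n_events == total_deaths
        rel = p[p["relapse_observed"] == 1].reset_index()
        f2 = datasets[2].frame
        f3 = datasets[3].frame
        assert np.allclose(np.sort(f3["entry"]), np.sort(rel["time_relapse"]))
        # exits of transition-2 rows for relapsed patients equal entries of 3
        assert np.allclose(np.sort(f2.loc[rel["index"], "exit"]), np.sort(f3["entry"]))

    def test_standardized_columns_scale(self, datasets):
        z = datasets[1].frame["bed_std"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(0.5, abs=1e-10)

    def test_cross_tally_with_simulator(self, cohort, datasets):
        deaths_after_relapse = int(((cohort.patients["relapse_observed"] == 1)
                                    & (cohort.patients["event_death"] == 1)).sum())
        assert datasets[3].n_events == deaths_after_relapse


class TestImputation:
    @pytest.fixture(scope="class")
    def masked(self):
        coh = simulate_illness_death(paper_like_config(seed=77))
        return coh, inject_missingness(coh, seed=78)

    @pytest.fixture(scope="class")
    def masked_large(self):
        """Bigger cohort so marginal means are stable against which cells
        happen to be masked (registry volumes are heavily right-skewed)."""
        coh = simulate_illness_death(paper_like_config(seed=77, n_hospitals=300))
        return coh, inject_missingness(coh, seed=78)

    def test_no_missing_passthrough(self, cohort):
        imp = impute_chained(cohort, m=2, seed=1)
        assert imp.copies[0].lesions.equals(cohort.lesions)
        assert imp.copies[1].patients.equals(cohort.patients)

    def test_determinism(self, masked):
        _, miss = masked
        a = impute_chained(miss, m=2, seed=9)
        b = impute_chained(miss, m=2, seed=9)
        for ca, cb in zip(a.copies, b.copies):
            assert ca.lesions.equals(cb.lesions)
            assert ca.patients.equals(cb.patients)

    def test_observed_cells_identical_across_copies(self, masked):
        _, miss = masked
        imp = impute_chained(miss, m=3, seed=4)
        obs = miss.lesions["volume_ccm"].notna()
        base = imp.copies[0].lesions.loc[obs, "volume_ccm"]
        for c in imp.copies[1:]:
            assert c.lesions.loc[obs, "volume_ccm"].equals(base)

    def test_mcar_mean_recovered(self, masked_large):
        full, miss = masked_large
        imp = impute_chained(miss, m=2, seed=5)
        true_mean = full.lesions["volume_ccm"].mean()
        imp_means = [c.lesions["volume_ccm"].mean() for c in imp.copies]
        assert np.mean(imp_means) == pytest.approx(true_mean, rel=0.05)
        # binary covariate prevalence likewise preserved
        true_p = full.patients["kps_ge90"].mean()
        imp_p = np.mean([c.patients["kps_ge90"].mean() for c in imp.copies])
        assert imp_p == pytest.approx(true_p, abs=0.05)

    def test_marginal_fallback_warns(self):
        # every candidate predictor is constant, so the screen finds none
        patients = _mini_patients([
            [1, i, 1, 60.0, v, 1, 1, "liver", 1, 20.0, 10.0, 0, np.nan, 0]
            for i, v in enumerate([1, 0, np.nan] * 10)
        ])
        lesions = _mini_lesions([
            [1, i, i, "liver", 10.0, 12.0, 1, 0, 1, 150.0, 10.0, 0]
            for i in range(30)
        ])
        with pytest.warns(UserWarning, match="marginal fallback"):
            imp = impute_chained(Cohort(lesions, patients), m=1, seed=3)
        assert imp.copies[0].patients["kps_ge90"].notna().all()


class TestRubinPooling:
    def test_identical_copies_keep_se(self):
        P = pd.DataFrame({"b": [1.5, 1.5, 1.5]})
        V = pd.DataFrame({"b": [0.04, 0.04, 0.04]})
        point, se = pool_estimates(P, V)
        assert point["b"] == 1.5
        assert se["b"] == pytest.approx(0.2)

    def test_hand_computed_example(self):
        # two copies, estimates 1 and 3, variances 1 and 1:
        # point 2; variance 1 + (1 + 1/2) * 2 = 4
        point, se = pool_estimates(np.array([[1.0], [3.0]]), np.array([[1.0], [1.0]]))
        assert point[0] == pytest.approx(2.0)
        assert se[0] ** 2 == pytest.approx(4.0)

    def test_mismatched_covariates_rejected(self):
        P = pd.DataFrame({"a": [1.0, 2.0]})
        V = pd.DataFrame({"b": [1.0, 1.0]})
        with pytest.raises(ValueError):
            pool_estimates(P, V)

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            pool_estimates(np.array([[1.0]]), np.array([[1.0]]))


def _fisher_2x2_oracle(table):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-12))


class TestDescriptiveCompare:
    def test_fisher_matches_enumeration(self):
        table = [[1, 9], [11, 3]]
        res = descriptive_compare([0] * 1 + [1] * 9, [0] * 11 + [1] * 3,
                                  kind="categorical")
        assert res["p_value"] == pytest.approx(_fisher_2x2_oracle(table), rel=1e-9)
        assert res["p_value"] == pytest.approx(0.002759, abs=2e-6)

    def test_wilcoxon_exact_small_sample(self):
        # (1,2,3) vs (4,5,6): 2 of the C(6,3)=20 assignments are as extreme
        res = descriptive_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], kind="continuous")
        assert res["p_value"] == pytest.approx(0.1, abs=1e-9)

    def test_identical_groups(self):
        res = descriptive_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="continuous")
        assert res["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            descriptive_compare([], [1, 2], kind="continuous")

    def test_multilevel_fisher_mc(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 5, 80)
        b = rng.integers(1, 5, 90)
        res = descriptive_compare(a, b, kind="categorical")
        assert res["test"] == "fisher-exact-mc"
        assert 0.0 < res["p_value"] <= 1.0
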