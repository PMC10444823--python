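import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subhealth.cohort import (
    chisq_test,
    cluster_by_grade,
    grade_percentages,
    impute_column,
    rank_test_ordinal,
    symptom_frequencies,
    ttest_ind,
)

# subhealthy vs healthy grade counts for the three morphology dimensions
TORTUOSITY = [[196, 269, 162], [9, 22, 39]]
TRUNK = [[427, 109, 91], [25, 13, 32]]
WIDTH = [[80, 71, 476], [10, 10, 50]]


class TestImputation:
    def test_no_missing_identity(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert impute_column(s).equals(s)

    def test_skewed_sample_gets_median(self):
        rng = np.random.default_rng(30)
        vals = pd.Series(np.exp(rng.normal(size=100)))
        vals.iloc[10] = np.nan
        filled = impute_column(vals)
        assert filled.iloc[10] == pytest.approx(vals.dropna().median())

    def test_normal_sample_gets_mean(self):
        rng = np.random.default_rng(31)
        vals = pd.Series(rng.normal(10, 2, size=100))
        vals.iloc[5] = np.nan
        filled = impute_column(vals)
        assert filled.iloc[5] == pytest.approx(vals.dropna().mean())
        # observed values untouched
        assert filled.drop(index=5).equals(vals.drop(index=5))

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            impute_column(pd.Series([np.nan, np.nan]))


class TestTTest:
    def test_sv_redness_summary_contrast(self):
        t, p = ttest_ind((14.01, 3.11, 627), (17.75, 3.39, 70))
        assert p < 0.001

    def test_identical_groups(self):
        t, p = ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_summary_entry_equals_raw_entry(self):
        rng = np.random.default_rng(32)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 55)
        raw = ttest_ind(a, b)
        summ = ttest_ind(
            (a.mean(), a.std(ddof=1), len(a)), (b.mean(), b.std(ddof=1), len(b))
        )
        assert raw == pytest.approx(summ, rel=1e-10)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            ttest_ind([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_sex_table_yates(self):
        chi2, p = chisq_test([[316, 311], [22, 48]])
        # hand check: n(|ad-bc|-n/2)^2 / (row and column products)
        a, b, c, d = 316, 311, 22, 48
        n = a + b + c + d
        hand = n * (abs(a * d - b * c) - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(hand, rel=1e-12)
        assert p == pytest.approx(0.004, abs=5e-4)

    def test_identical_rows(self):
        chi2, p = chisq_test([[10, 20], [10, 20]])
        assert chi2 == 0.0 and p == 1.0

    def test_rxc_matches_expected_count_loop(self):
        rng = np.random.default_rng(33)
        table = rng.integers(5, 40, size=(3, 4)).astype(float)
        chi2, _ = chisq_test(table)
        total = table.sum()
        acc = 0.0
        for i in range(3):
            for j in range(4):
                exp = table[i].sum() * table[:, j].sum() / total
                acc += (table[i, j] - exp) ** 2 / exp
        assert chi2 == pytest.approx(acc, rel=1e-12)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chisq_test([[0, 0], [3, 4]])


class TestRankTest:
    @pytest.mark.parametrize(
        "table, expected",
        [(TORTUOSITY, 25.114), (TRUNK, 37.304), (WIDTH, 0.611)],
    )
    def test_printed_statistics(self, table, expected):
        H, p = rank_test_ordinal(table)
        assert H == pytest.approx(expected, abs=5e-4)
        assert (p < 0.001) == (expected > 10)

    @pytest.mark.parametrize("table", [TORTUOSITY, TRUNK, WIDTH])
    def test_equals_kruskal_on_expanded_vectors(self, table):
        """Count-table computation matches scipy's tie-corrected Kruskal-Wallis
        on the expanded raw ordinal observations."""
        counts = np.asarray(table)
        groups = [np.repeat(np.arange(counts.shape[1]), row) for row in counts]
        ref = stats.kruskal(*groups)
        H, p = rank_test_ordinal(table)
        assert H == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_rows_give_zero(self):
        H, p = rank_test_ordinal([[5, 7, 3], [5, 7, 3]])
        assert H == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_group_errors(self):
        with pytest.raises(ValueError):
            rank_test_ordinal([[0, 0, 0], [1, 2, 3]])


class TestPercentages:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (TORTUOSITY, [[31.3, 42.9, 25.8], [12.9, 31.4, 55.7]]),
            (TRUNK, [[68.1, 17.4, 14.5], [35.7, 18.6, 45.7]]),
            (WIDTH, [[12.8, 11.3, 75.9], [14.3, 14.3, 71.4]]),
        ],
    )
    def test_printed_percentages_reproduce(self, table, expected):
        assert grade_percentages(table).to_numpy().tolist() == expected


class TestSymptoms:
    def make_records(self, positives, n, symptom="limb soreness"):
        rows = [
            {"subject": i, "symptom": symptom, "severity": 1 if i < positives else 0}
            for i in range(n)
        ]
        return pd.DataFrame(rows)

    def test_prevalence_matches_printed_value(self):
        out = symptom_frequencies(self.make_records(236, 627), 627)
        assert out.loc[0, "percent"] == pytest.approx(37.6, abs=0.05)

    def test_no_positive_subjects(self):
        out = symptom_frequencies(self.make_records(0, 10), 10)
        assert len(out) == 0

    def test_severity_two_counted_once(self):
        records = pd.DataFrame(
            {"subject": [0, 0], "symptom": ["fatigue", "fatigue"], "severity": [2, 2]}
        )
        out = symptom_frequencies(records, 4)
        assert out.loc[0, "n_positive"] == 1
        assert out.loc[0, "percent"] == pytest.approx(25.0)

    def test_ties_broken_alphabetically(self):
        records = pd.DataFrame(
            {
                "subject": [0, 1, 2, 3],
                "symptom": ["zzz", "aaa", "zzz", "aaa"],
                "severity": [1, 1, 1, 1],
            }
        )
        out = symptom_frequencies(records, 4)
        assert out["symptom"].tolist() == ["aaa", "zzz"]

    def test_zero_subjects_errors(self):
        with pytest.raises(ValueError):
            symptom_frequencies(self.make_records(1, 2), 0)


class TestClusterByGrade:
    def test_single_subject_single_symptom(self):
        records = pd.DataFrame({"subject": [0], "symptom": ["back pain"], "severity": [1]})
        grades = pd.DataFrame({"width": ["W3"]}, index=[0])
        out = cluster_by_grade(records, {"back pain": "pain"}, grades)
        assert out.loc["pain", "W3"] == 1
        assert out.to_numpy().sum() == 1

    def test_additivity_over_disjoint_subject_sets(self, population):
        from subhealth import sample_cohort

        cohort = sample_cohort(population, n=200, seed=55)
        cmap = population.symptom_clusters
        full = cluster_by_grade(cohort.symptoms, cmap, cohort.sv_grades)
        lo = cohort.symptoms[cohort.symptoms["subject"] < 100]
        hi = cohort.symptoms[cohort.symptoms["subject"] >= 100]
        part = cluster_by_grade(lo, cmap, cohort.sv_grades).add(
            cluster_by_grade(hi, cmap, cohort.sv_grades), fill_value=0
        )
        assert full.astype(float).equals(part.loc[full.index, full.columns].astype(float))

    def test_matches_bruteforce_loop(self, population):
        from subhealth import sample_cohort

        cohort = sample_cohort(population, n=60, seed=56)
        cmap = population.symptom_clusters
        out = cluster_by_grade(cohort.symptoms, cmap, cohort.sv_grades)
        for cluster in out.index:
            for grade in out.columns:
                dim = {"T": "tortuosity", "L": "trunk_length", "W": "width"}[grade[0]]
                count = 0
                for _, row in cohort.symptoms.iterrows():
                    if (
                        row["severity"] >= 1
                        and cmap[row["symptom"]] == cluster
                        and cohort.sv_grades.loc[row["subject"], dim] == grade
                    ):
                        count += 1
                assert out.loc[cluster, grade] == count

    def test_unmapped_symptom_warns_and_buckets(self):
        records = pd.DataFrame({"subject": [0], "symptom": ["mystery"], "severity": [1]})
        grades = pd.DataFrame({"width": ["W1"]}, index=[0])
        with pytest.warns(UserWarning, match="mystery"):
            out = cluster_by_grade(records, {}, grades)
        assert out.loc["unmapped", "W1"] == 1
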