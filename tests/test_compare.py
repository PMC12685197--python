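"""Hypothesis tests, test selection, p-value rendering and the
characterization tables."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neodose.compare import (
    DegenerateTableError,
    build_comparison_table,
    chi_square,
    choose_test,
    fisher_exact,
    format_pvalue,
    kruskal_wallis,
    regimen_table,
)
from neodose.trajectories import RegimenSummary


def fisher_2x2_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p for a 2x2 table by full
    hypergeometric enumeration over the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestChooseTest:
    def test_continuous_gets_kruskal_wallis(self):
        assert choose_test("continuous", [[1.0, 2.0], [3.0], [4.0, 5.0]]) == "kruskal-wallis"

    def test_large_expected_counts_get_chi_square(self):
        assert choose_test("categorical", [[20, 30, 25], [25, 20, 30]]) == "chi-square"

    def test_small_expected_counts_get_fisher(self):
        assert choose_test("categorical", [[3, 1], [1, 3]]) == "fisher"

    def test_zero_row_gets_none(self):
        # e.g. a flag false everywhere: no testable contrast
        assert choose_test("categorical", [[0, 0, 0], [5, 3, 2]]) == "none"

    def test_single_group_continuous_none(self):
        assert choose_test("continuous", [[1.0, 2.0], []]) == "none"


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        h, p = kruskal_wallis([[1, 2], [1, 2], [1, 2]])
        assert h == 0.0 and p == 1.0

    def test_matches_rank_formula_oracle(self):
        # groups {1,2,3} and {4,5,6}: no ties, H from the direct formula
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        n, r1, r2 = 6, 1 + 2 + 3, 4 + 5 + 6
        h_oracle = 12.0 / (n * (n + 1)) * (r1**2 / 3 + r2**2 / 3) - 3 * (n + 1)
        assert h == pytest.approx(h_oracle, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(h_oracle, 1), abs=1e-12)

    def test_empty_group_dropped_reducing_df(self):
        h2, p2 = kruskal_wallis([[1, 2, 3], [4, 5, 6], []])
        h_ref, p_ref = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert (h2, p2) == (h_ref, p_ref)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.5, 3.0], [4.0, 0.5], [2.0, 6.0, 7.0]]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3], []])


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        assert fisher_exact([[3, 1], [1, 3]]).p_value == pytest.approx(
            34 / 70, abs=1e-10
        )

    def test_extreme_diagonal_table(self):
        assert fisher_exact([[0, 5], [5, 0]]).p_value == pytest.approx(
            2 / comb(10, 5), abs=1e-12
        )

    def test_single_row_degenerate_p_one(self):
        assert fisher_exact([[4, 7]]).p_value == 1.0

    def test_agrees_with_rational_oracle_on_2x2_grid(self):
        for a in range(0, 5):
            for b in range(0, 5):
                for c in range(0, 5):
                    for d in range(0, 5):
                        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                            continue
                        got = fisher_exact([[a, b], [c, d]]).p_value
                        want = fisher_2x2_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-7), (a, b, c, d)

    def test_rxc_enumeration_matches_scipy_2xc_collapsed_case(self):
        # independent check of the r x c path: compare a 2x3 table against
        # a direct rational enumeration
        table = np.array([[3, 1, 2], [1, 3, 0]])
        got = fisher_exact(table).p_value

        def log_prob(t):
            from math import lgamma

            def lf(x):
                return lgamma(x + 1)

            r = t.sum(1)
            c = t.sum(0)
            return (
                sum(lf(x) for x in r) + sum(lf(x) for x in c)
                - lf(t.sum()) - sum(lf(x) for x in t.flat)
            )

        # enumerate all 2x3 tables with the same margins
        r1 = 6
        c_sums = table.sum(0)
        p_obs = log_prob(table)
        total = 0.0
        for x in range(c_sums[0] + 1):
            for y in range(c_sums[1] + 1):
                z = r1 - x - y
                if 0 <= z <= c_sums[2]:
                    t = np.array([[x, y, z], [c_sums[0] - x, c_sums[1] - y, c_sums[2] - z]])
                    lp = log_prob(t)
                    if lp <= p_obs + 1e-9:
                        total += np.exp(lp)
        assert got == pytest.approx(total, abs=1e-7)

    def test_large_table_falls_back_to_simulation_flagged(self):
        t = np.full((4, 4), 30)
        res = fisher_exact(t, max_tables=100, seed=1, n_sim=2000)
        assert res.simulated
        assert 0.0 <= res.p_value <= 1.0

    def test_simulated_p_deterministic_for_seed(self):
        t = np.full((3, 4), 12)
        a = fisher_exact(t, max_tables=10, seed=42, n_sim=2000).p_value
        b = fisher_exact(t, max_tables=10, seed=42, n_sim=2000).p_value
        assert a == b


class TestChiSquare:
    def test_table_equal_to_expected_gives_zero(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_gender_by_cluster_counts_render_point_two(self):
        """2x3 gender-by-cluster counts whose chi-square p prints as 0.2."""
        _, p = chi_square([[12, 12, 7], [23, 9, 6]])
        assert format_pvalue(p) == "0.2"

    def test_row_column_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 11]])
        s0, _ = chi_square(t)
        s1, _ = chi_square(t[::-1])
        s2, _ = chi_square(t[:, [2, 0, 1]])
        assert s0 == pytest.approx(s1) == pytest.approx(s2)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square([[0, 0], [3, 4]])


class TestFormatPvalue:
    @pytest.mark.parametrize(
        "p,text",
        [
            (0.95, ">0.9"), (0.1934, "0.2"), (0.6, "0.6"), (0.23, "0.2"),
            (0.14, "0.14"), (0.0703, "0.070"), (0.029, "0.029"),
            (0.013, "0.013"), (0.0005, "<0.001"), (1.0, ">0.9"),
        ],
    )
    def test_rendering(self, p, text):
        assert format_pvalue(p) == text


def _covariates(index, **columns):
    return pd.DataFrame(columns, index=pd.Index(index, name="course_id"))


class TestComparisonTable:
    def test_identical_covariates_render_above_point_nine(self):
        ids = [f"c{i}" for i in range(12)]
        assign = pd.Series(["A"] * 6 + ["B"] * 6, index=pd.Index(ids, name="course_id"))
        cov = _covariates(ids, ga_birth_weeks=[30.0] * 12, sex=["Male"] * 12)
        tbl = build_comparison_table(
            assign, cov,
            variables=[("ga_birth_weeks", "GA", "continuous"), ("sex", "Sex", "categorical")],
        )
        ga = tbl.frame[tbl.frame["variable"] == "GA"].iloc[0]
        assert ga["p_rendered"] == ">0.9"
        sex = tbl.frame[tbl.frame["variable"] == "Sex"].iloc[0]
        assert sex["test"] == "none"  # a single level has no contrast

    def test_planted_shift_detected_by_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        ids = [f"c{i}" for i in range(60)]
        assign = pd.Series(
            ["A"] * 20 + ["B"] * 20 + ["C"] * 20, index=pd.Index(ids, name="course_id")
        )
        ga = np.concatenate(
            [rng.normal(34, 1, 20), rng.normal(33.5, 1, 20), rng.normal(29, 1, 20)]
        )
        cov = _covariates(ids, ga_birth_weeks=ga)
        tbl = build_comparison_table(
            assign, cov, variables=[("ga_birth_weeks", "GA", "continuous")]
        )
        row = tbl.frame.iloc[0]
        assert row["test"] == "Kruskal-Wallis rank sum test"
        assert row["p_value"] < 0.05
        # direction: cluster C medians lowest, mirroring the planted shift
        assert float(row["cluster_C"].split(" ")[0]) < float(row["cluster_A"].split(" ")[0])

    def test_fully_missing_covariate_gets_no_test(self):
        ids = ["a", "b", "c", "d"]
        assign = pd.Series(["A", "A", "B", "B"], index=pd.Index(ids, name="course_id"))
        cov = _covariates(ids, birthweight_g=[np.nan] * 4)
        tbl = build_comparison_table(
            assign, cov, variables=[("birthweight_g", "BW", "continuous")]
        )
        row = tbl.frame.iloc[0]
        assert row["test"] == "none" and row["p_rendered"] == "N/A"
        assert row["missing_A"] == 2 and row["missing_B"] == 2

    def test_all_false_flag_rendered_na(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        assign = pd.Series(
            ["A", "A", "B", "B", "C", "C"], index=pd.Index(ids, name="course_id")
        )
        cov = _covariates(ids, pulmonary_hypertension=pd.array([False] * 6, dtype="boolean"))
        tbl = build_comparison_table(
            assign, cov,
            variables=[("pulmonary_hypertension", "Pulmonary hypertension", "categorical")],
        )
        row = tbl.frame.iloc[0]
        assert row["test"] == "none" and row["p_rendered"] == "N/A"
        assert row["cluster_A"] == "0 (0)"

    def test_label_permutation_leaves_p_unchanged(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(30)]
        labels = np.array(["A", "B", "C"])[rng.integers(0, 3, 30)]
        assign = pd.Series(labels, index=pd.Index(ids, name="course_id"))
        cov = _covariates(ids, ga_birth_weeks=rng.normal(32, 2, 30))
        p1 = build_comparison_table(
            assign, cov, variables=[("ga_birth_weeks", "GA", "continuous")]
        ).frame.iloc[0]["p_value"]
        swap = {"A": "C", "B": "A", "C": "B"}
        assign2 = assign.map(swap)
        p2 = build_comparison_table(
            assign2, cov, variables=[("ga_birth_weeks", "GA", "continuous")]
        ).frame.iloc[0]["p_value"]
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRegimenTable:
    def _summary(self, cid, drug="propranolol", duration=10.0, inc=None, t_inc=None):
        return RegimenSummary(
            course_id=cid, drug=drug, route="oral",
            postnatal_age_first_admin=5.0, min_dose=1.0, max_dose=2.0,
            duration=duration, mean_time_to_increase=t_inc, mean_dose_increase=inc,
        )

    def test_single_course_medians_equal_values(self):
        tbl = regimen_table([self._summary("c1", duration=42.0)])
        row = tbl[tbl["variable"] == "Duration of treatment (hours)"].iloc[0]
        assert row["median"] == 42.0 and row["q1"] == 42.0

    def test_all_constant_mass_courses_missing_increase_rows(self):
        tbl = regimen_table([self._summary(f"c{i}") for i in range(4)])
        row = tbl[tbl["variable"] == "Mean dose increase (mg)"].iloc[0]
        assert row["missing"] == 4 and row["summary"] == ""

    def test_duration_quartiles(self):
        tbl = regimen_table(
            [self._summary(f"c{i}", duration=d) for i, d in enumerate([10, 20, 40])]
        )
        row = tbl[tbl["variable"] == "Duration of treatment (hours)"].iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (20.0, 15.0, 30.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            regimen_table([])
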