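"""Inclusion/exclusion rules, ICD flag derivation, prevalence and
descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from neodose.cohort import (
    ReferentialIntegrityError,
    apply_inclusion,
    derive_flags,
    derive_flags_table,
    drug_prevalence,
    quartiles,
    select_top_agents,
    summarize_cohort,
)
from neodose.codes import normalize_code

from conftest import make_oral_admins, make_visit_row


def _visits(*rows):
    return pd.DataFrame([make_visit_row(**r) for r in rows])


def _admin(visit_id, drug="propranolol", route="oral"):
    return {
        "visit_id": visit_id, "drug": drug, "route": route,
        "time_min": 0.0, "mass_mg": 1.0, "rate_mg_min": np.nan,
    }


class TestApplyInclusion:
    def test_term_birth_excluded_with_ga_rule(self):
        visits = _visits({"visit_id": "V1", "ga": 38.0}, {"visit_id": "V2", "ga": 30.0})
        admins = pd.DataFrame([_admin("V1"), _admin("V2")])
        included, ledger = apply_inclusion(visits, admins)
        assert list(included["visit_id"]) == ["V2"]
        assert list(ledger.records["rule_id"]) == ["GA_GE_37"]

    def test_pma_44_excluded(self):
        visits = _visits({"visit_id": "V1", "pma": 44.0})
        admins = pd.DataFrame([_admin("V1")])
        _, ledger = apply_inclusion(visits, admins)
        assert list(ledger.records["rule_id"]) == ["PMA_GE_44"]

    def test_no_study_drug_excluded(self):
        visits = _visits({"visit_id": "V1"})
        admins = pd.DataFrame([_admin("V1", drug="caffeine")])
        _, ledger = apply_inclusion(visits, admins)
        assert list(ledger.records["rule_id"]) == ["NO_STUDY_DRUG"]

    def test_iv_propranolol_excluded(self):
        visits = _visits({"visit_id": "V1"})
        admins = pd.DataFrame([_admin("V1", route="IV")])
        _, ledger = apply_inclusion(visits, admins)
        assert list(ledger.records["rule_id"]) == ["IV_PROPRANOLOL"]

    def test_oral_propranolol_not_excluded_by_route_rule(self):
        visits = _visits({"visit_id": "V1"})
        admins = pd.DataFrame([_admin("V1", route="oral")])
        included, _ = apply_inclusion(visits, admins)
        assert len(included) == 1

    def test_hemangioma_code_excluded(self):
        visits = _visits({"visit_id": "V1", "dx": "D18.01;P27.1"})
        admins = pd.DataFrame([_admin("V1")])
        _, ledger = apply_inclusion(visits, admins)
        assert list(ledger.records["rule_id"]) == ["HEMANGIOMA"]

    def test_first_failing_rule_attributed(self):
        # GA failure comes before the hemangioma rule
        visits = _visits({"visit_id": "V1", "ga": 39.0, "dx": "D18.01"})
        admins = pd.DataFrame([_admin("V1")])
        _, ledger = apply_inclusion(visits, admins)
        assert list(ledger.records["rule_id"]) == ["GA_GE_37"]

    def test_partition_and_counts_reconcile(self, small_cohort):
        visits, admins, _, _ = small_cohort
        included, ledger = apply_inclusion(visits, admins)
        assert len(included) + ledger.n_excluded == len(visits)
        assert ledger.counts.sum() == ledger.n_excluded
        assert set(included["visit_id"]).isdisjoint(set(ledger.records["visit_id"]))

    def test_unknown_visit_reference_raises(self):
        visits = _visits({"visit_id": "V1"})
        admins = pd.DataFrame([_admin("V999")])
        with pytest.raises(ReferentialIntegrityError):
            apply_inclusion(visits, admins)


class TestDeriveFlags:
    def test_single_codes_set_single_flags(self):
        f = derive_flags({"P27.1"})
        assert f["bronchopulmonary_dysplasia"] is True
        assert sum(bool(v) for v in f.values()) == 1
        f = derive_flags({"I10"})
        assert f["neonatal_hypertension"] is True

    def test_empty_codes_all_false(self):
        f = derive_flags(set())
        assert all(v is False for v in f.values())

    def test_unavailable_dx_gives_missing(self):
        f = derive_flags({"I10"}, available=False)
        assert all(v is pd.NA for v in f.values())

    def test_trailing_zero_and_case_insensitive(self):
        assert derive_flags({"745.60"})["congenital_heart_disease"] is True
        assert derive_flags({"745.6"})["congenital_heart_disease"] is True
        assert derive_flags({"q21.0"})["congenital_heart_disease"] is True
        assert derive_flags({"P29.30"})["pulmonary_hypertension"] is True
        assert derive_flags({"P29.3"})["pulmonary_hypertension"] is True

    def test_normalization_examples(self):
        assert normalize_code("745.60") == "745.6"
        assert normalize_code("Q20.0") == "Q20"
        assert normalize_code(" i10 ") == "I10"
        assert normalize_code("401.9") == "401.9"

    def test_order_independent_and_idempotent(self):
        codes = ["P27.1", "I10", "747.0"]
        f1 = derive_flags(codes)
        f2 = derive_flags(list(reversed(codes)))
        assert f1 == f2 == derive_flags(set(codes))

    def test_flags_table_uses_dx_missing_column(self):
        visits = pd.DataFrame(
            [make_visit_row(visit_id="V1", dx="P27.1"),
             make_visit_row(visit_id="V2", dx="", dx_missing=True)]
        )
        tbl = derive_flags_table(visits)
        assert tbl.loc["V1", "bronchopulmonary_dysplasia"] == True  # noqa: E712
        assert pd.isna(tbl.loc["V2", "bronchopulmonary_dysplasia"])


class TestPrevalence:
    def _setup(self):
        visits = _visits(*[{"visit_id": f"V{i}"} for i in range(10)])
        rows = [_admin(f"V{i}", drug="propranolol") for i in range(6)]
        rows += [_admin("V0", drug="captopril"), _admin("V1", drug="captopril")]
        # duplicate administrations must not double-count a visit
        rows += [_admin("V0", drug="propranolol")]
        return visits, pd.DataFrame(rows)

    def test_counts_and_percentages(self):
        visits, admins = self._setup()
        prev = drug_prevalence(visits, admins)
        row = prev[prev["drug"] == "propranolol"].iloc[0]
        assert row["n_visits"] == 6 and row["pct"] == pytest.approx(60.0)
        assert prev[prev["drug"] == "captopril"].iloc[0]["n_visits"] == 2

    def test_multi_drug_visit_counts_for_each(self):
        visits, admins = self._setup()
        prev = drug_prevalence(visits, admins)
        assert prev["n_visits"].sum() == 8  # 6 + 2 > distinct visits with drug

    def test_absent_drug_not_in_table(self):
        visits, admins = self._setup()
        prev = drug_prevalence(visits, admins)
        assert "esmolol" not in set(prev["drug"])

    def test_zero_visits_empty_table(self):
        prev = drug_prevalence(_visits().iloc[0:0] if False else pd.DataFrame(columns=["visit_id"]), pd.DataFrame(columns=["visit_id", "drug"]))
        assert len(prev) == 0


class TestTopAgents:
    def _prev(self, d):
        return pd.DataFrame(
            {"drug": list(d), "n_visits": list(d.values()),
             "pct": [v * 10.0 for v in d.values()]}
        )

    def test_top_three(self):
        prev = self._prev({"A": 61, "B": 12, "C": 9, "D": 2})
        assert select_top_agents(prev, 3) == ["A", "B", "C"]

    def test_top_one(self):
        prev = self._prev({"A": 61, "B": 12})
        assert select_top_agents(prev, 1) == ["A"]

    def test_tie_breaks_alphabetically(self):
        prev = self._prev({"zeta": 10, "alpha": 10})
        assert select_top_agents(prev, 1) == ["alpha"]

    def test_n_exceeding_table_returns_all(self, caplog):
        prev = self._prev({"A": 5, "B": 3})
        with caplog.at_level("WARNING"):
            out = select_top_agents(prev, 5)
        assert out == ["A", "B"]
        assert any("only 2" in r.message for r in caplog.records)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            select_top_agents(pd.DataFrame(columns=["drug", "n_visits", "pct"]), 3)


class TestSummaries:
    def test_median_quartiles_odd_n(self):
        assert quartiles([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_quartiles_linear_interpolation(self):
        assert quartiles([890, 1620, 2310]) == (1620.0, 1255.0, 1965.0)

    def test_all_missing_continuous_blank(self):
        visits = pd.DataFrame([make_visit_row(birthweight=np.nan) for _ in range(4)])
        tbl = summarize_cohort(visits)
        row = tbl[tbl["variable"] == "Birthweight (g)"].iloc[0]
        assert row["summary"] == "" and row["missing"] == 4

    def test_categorical_percentages_sum_to_100_over_nonmissing(self):
        visits = pd.DataFrame(
            [make_visit_row(sex="Female"), make_visit_row(sex="Male"),
             make_visit_row(sex="Male"), make_visit_row(sex="")]
        )
        tbl = summarize_cohort(visits)
        sex = tbl[(tbl["variable"] == "Gender") & (tbl["level"] != "")]
        assert sex["pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert (sex["missing"] == 1).all()

    def test_flag_rows_included(self):
        visits = pd.DataFrame([make_visit_row(visit_id="V1", dx="P27.1")])
        flags = derive_flags_table(visits)
        tbl = summarize_cohort(visits, flags)
        assert "bronchopulmonary_dysplasia" in set(tbl["variable"])
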