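"""Cohort selection, comorbidity flags, agent prevalence and Table-1-style
descriptive summaries.

Inclusion requires a preterm birth (GA < 37 weeks), a neonatal visit
(postmenstrual age at discharge < 44 weeks) and at least one
administration of a study antihypertensive; visits are then excluded for
any IV propranolol administration (oral and IV propranolol exposures are
not comparable because of oral bioavailability) and for a hemangioma
discharge diagnosis in any position (an alternative propranolol
indication). Each excluded visit is attributed to its first failing rule
in an exclusion ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codes import (
    FLAG_CODES,
    FLAG_NAMES,
    HEMANGIOMA_PREFIXES,
    STUDY_DRUGS,
    is_hemangioma,
    normalize_codes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionLedger",
    "ReferentialIntegrityError",
    "apply_inclusion",
    "derive_flags",
    "derive_flags_table",
    "drug_prevalence",
    "select_top_agents",
    "summarize_cohort",
    "quartiles",
]

#: (rule_id, rule_text) in evaluation order: eligibility first, then
#: drug-route and diagnosis exclusions.
EXCLUSION_RULES = (
    ("GA_GE_37", "gestational age at birth >= 37 weeks"),
    ("PMA_GE_44", "postmenstrual age at discharge >= 44 weeks"),
    ("NO_STUDY_DRUG", "no administration of a study antihypertensive"),
    ("IV_PROPRANOLOL", "received intravenous propranolol"),
    ("HEMANGIOMA", "hemangioma discharge diagnosis in any position"),
)


class ReferentialIntegrityError(ValueError):
    """An administration references a visit absent from the visits table."""


@dataclass
class ExclusionLedger:
    """Ordered record of exclusions: each visit with its first failing rule."""

    records: pd.DataFrame  # columns visit_id, rule_id, rule_text

    @property
    def counts(self) -> pd.Series:
        rule_ids = [r[0] for r in EXCLUSION_RULES]
        c = self.records["rule_id"].value_counts()
        return c.reindex(rule_ids, fill_value=0).astype(int)

    @property
    def n_excluded(self) -> int:
        return len(self.records)


def parse_dx(dx_codes) -> set[str]:
    """Split a semicolon-delimited dx string into a set of raw codes."""
    if dx_codes is None or (isinstance(dx_codes, float) and np.isnan(dx_codes)):
        return set()
    if isinstance(dx_codes, str):
        return {c.strip() for c in dx_codes.split(";") if c.strip()}
    return set(dx_codes)


def apply_inclusion(
    visits: pd.DataFrame,
    administrations: pd.DataFrame,
    drug_list=STUDY_DRUGS,
    hemangioma_prefixes=HEMANGIOMA_PREFIXES,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the inclusion/exclusion rules; return included visits and ledger."""
    known = set(visits["visit_id"])
    unknown = set(administrations["visit_id"]) - known
    if unknown:
        raise ReferentialIntegrityError(
            f"administrations reference unknown visit_ids: {sorted(unknown)[:5]}"
        )
    drug_set = {d.lower() for d in drug_list}
    ad = administrations
    study_admins = ad[ad["drug"].str.lower().isin(drug_set)]
    visits_with_drug = set(study_admins["visit_id"])
    iv_prop = set(
        ad[(ad["drug"].str.lower() == "propranolol") & (ad["route"] == "IV")]["visit_id"]
    )

    ledger_rows, keep = [], []
    for row in visits.itertuples(index=False):
        rule = None
        if float(row.ga_birth_weeks) >= 37.0:
            rule = EXCLUSION_RULES[0]
        elif float(row.pma_discharge_weeks) >= 44.0:
            rule = EXCLUSION_RULES[1]
        elif row.visit_id not in visits_with_drug:
            rule = EXCLUSION_RULES[2]
        elif row.visit_id in iv_prop:
            rule = EXCLUSION_RULES[3]
        elif any(is_hemangioma(c, hemangioma_prefixes) for c in parse_dx(row.dx_codes)):
            rule = EXCLUSION_RULES[4]
        if rule is None:
            keep.append(True)
        else:
            keep.append(False)
            ledger_rows.append((row.visit_id, rule[0], rule[1]))

    included = visits[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    ledger = ExclusionLedger(
        pd.DataFrame(ledger_rows, columns=["visit_id", "rule_id", "rule_text"])
    )
    return included, ledger


def derive_flags(dx_codes, available: bool = True, code_map=FLAG_CODES) -> dict:
    """Comorbidity flags from a set of discharge codes.

    Matching is exact on the normalized code text (case- and
    trailing-zero-insensitive); unknown codes are ignored. When dx
    availability is flagged absent, every flag is missing (pd.NA).
    """
    if not available:
        return {flag: pd.NA for flag in code_map}
    codes = normalize_codes(parse_dx(dx_codes))
    return {
        flag: bool(codes & normalize_codes(wanted)) for flag, wanted in code_map.items()
    }


def derive_flags_table(visits: pd.DataFrame, code_map=FLAG_CODES) -> pd.DataFrame:
    """Per-visit flag frame (boolean dtype with NA), indexed by visit_id."""
    missing_col = visits["dx_missing"] if "dx_missing" in visits else pd.Series(False, index=visits.index)
    rows = [
        derive_flags(dx, available=not bool(m), code_map=code_map)
        for dx, m in zip(visits["dx_codes"], missing_col)
    ]
    out = pd.DataFrame(rows, index=visits["visit_id"]).astype("boolean")
    return out


def drug_prevalence(
    included_visits: pd.DataFrame, administrations: pd.DataFrame
) -> pd.DataFrame:
    """Per-drug visit counts and percentage of included visits.

    A visit counts once per drug it received; a visit on several agents
    contributes to each, so counts may sum past the visit total.
    """
    n_total = len(included_visits)
    if n_total == 0:
        return pd.DataFrame(columns=["drug", "n_visits", "pct"])
    keep = administrations["visit_id"].isin(set(included_visits["visit_id"]))
    pairs = administrations[keep][["visit_id", "drug"]].drop_duplicates()
    counts = pairs.groupby("drug").size().rename("n_visits").reset_index()
    counts["pct"] = counts["n_visits"] / n_total * 100.0
    counts = counts.sort_values(
        ["n_visits", "drug"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return counts


def select_top_agents(prevalence: pd.DataFrame, n: int = 3) -> list[str]:
    """Top-n agents by prevalence, ties broken alphabetically."""
    if len(prevalence) == 0:
        raise ValueError("prevalence table is empty")
    if n > len(prevalence):
        logger.warning(
            "requested top %d agents but only %d present; returning all", n, len(prevalence)
        )
        n = len(prevalence)
    ordered = prevalence.sort_values(
        ["n_visits", "drug"], ascending=[False, True], kind="stable"
    )
    return list(ordered["drug"].head(n))


def quartiles(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    return (
        float(np.quantile(v, 0.5)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
    )


_CONTINUOUS = [
    ("ga_birth_weeks", "Gestational age at birth (weeks)"),
    ("birthweight_g", "Birthweight (g)"),
    ("age_discharge_days", "Age at discharge (days)"),
]
_CATEGORICAL = [("sex", "Gender"), ("race", "Race"), ("ethnicity", "Ethnicity")]


def summarize_cohort(visits: pd.DataFrame, flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy descriptive table: continuous variables as median (Q1, Q3),
    categorical as n (%) over non-missing denominators, plus missing counts."""
    rows = []
    n = len(visits)

    def _blank(label):
        rows.append(
            {"variable": label, "level": "", "kind": "continuous", "n": np.nan,
             "pct": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan,
             "missing": n, "summary": ""}
        )

    for col, label in _CONTINUOUS:
        vals = pd.to_numeric(visits[col], errors="coerce") if n else pd.Series(dtype=float)
        nonmiss = vals.dropna()
        if len(nonmiss) == 0:
            _blank(label)
            continue
        med, q1, q3 = quartiles(nonmiss)
        rows.append(
            {"variable": label, "level": "", "kind": "continuous", "n": len(nonmiss),
             "pct": np.nan, "median": med, "q1": q1, "q3": q3,
             "missing": int(vals.isna().sum()),
             "summary": f"{med:g} ({q1:g}, {q3:g})"}
        )

    def _cat_rows(series: pd.Series, label: str) -> None:
        s = series.replace("", pd.NA) if series.dtype == object else series
        nonmiss = s.dropna()
        denom = len(nonmiss)
        counts = nonmiss.value_counts().sort_index()
        for level, c in counts.items():
            pct = c / denom * 100.0 if denom else np.nan
            rows.append(
                {"variable": label, "level": str(level), "kind": "categorical",
                 "n": int(c), "pct": pct, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "missing": int(s.isna().sum()),
                 "summary": f"{int(c)} ({pct:.3g})"}
            )
        if denom == 0:
            rows.append(
                {"variable": label, "level": "", "kind": "categorical", "n": np.nan,
                 "pct": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan,
                 "missing": int(len(s)), "summary": ""}
            )

    for col, label in _CATEGORICAL:
        _cat_rows(visits[col] if n else pd.Series(dtype=object), label)

    if flags is not None and len(flags):
        aligned = flags.reindex(visits["visit_id"])
        for flag in flags.columns:
            s = aligned[flag].map({True: "yes", False: "no"}, na_action="ignore")
            _cat_rows(s, flag)

    return pd.DataFrame(rows)
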