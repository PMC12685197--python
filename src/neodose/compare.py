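"""Among-cluster comparison tables and the supporting hypothesis tests.

Continuous covariates are compared across clusters with the
Kruskal-Wallis rank-sum test; categorical covariates with Pearson's
chi-square unless any expected cell count falls below 5, in which case
Fisher's exact test is used (two-sided by the minimum-likelihood
criterion). Variables that are constant, or whose contingency table has
an empty margin after dropping missing values, get no test (rendered
N/A). Missing values are dropped per variable, with missing counts
displayed. No multiple-testing correction is applied.

p-values are rendered in the compact journal style (">0.9" cap,
"<0.001" floor, one decimal at or above 0.2, two significant figures
below) with the full-precision value always carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cohort import quartiles

__all__ = [
    "DegenerateTableError",
    "choose_test",
    "kruskal_wallis",
    "fisher_exact",
    "FisherResult",
    "chi_square",
    "format_pvalue",
    "build_comparison_table",
    "regimen_table",
    "ClusterComparisonTable",
]


class DegenerateTableError(ValueError):
    """Contingency table with a zero margin passed to a chi-square test."""


def format_pvalue(p: float) -> str:
    """Compact journal rendering: ">0.9" cap and "<0.001" floor; one
    decimal when p rounds to 0.2 or more; otherwise two significant
    figures keeping trailing zeros (0.1934 -> "0.2", 0.14 -> "0.14",
    0.0703 -> "0.070")."""
    if not np.isfinite(p):
        return "N/A"
    if p > 0.9:
        return ">0.9"
    if round(p, 1) >= 0.2:
        return f"{p:.1f}"
    if p >= 0.001:
        decimals = 1 - int(np.floor(np.log10(p)))
        return f"{p:.{decimals}f}"
    return "<0.001"


def _clean_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    return np.round(t).astype(np.int64)


def choose_test(kind: str, data) -> str:
    """Test-selection rule for one table row.

    ``kind`` is "continuous" (data = list of per-cluster samples) or
    "categorical" (data = contingency counts, levels x clusters).
    """
    if kind == "continuous":
        groups = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in data]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2:
            return "none"
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]) and len(groups) < 2:
            return "none"
        return "kruskal-wallis"
    t = _clean_table(data)
    t = t[t.sum(axis=1) > 0]
    if t.size:
        t = t[:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return "none"
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return "fisher" if (expected < 5).any() else "chi-square"


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference on
    (groups - 1) degrees of freedom; empty groups (after dropping
    missing values) are excluded, reducing the df."""
    clean = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in groups]
    clean = [g for g in clean if len(g)]
    if len(clean) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(clean)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*clean)
    return float(h), float(p)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    simulated: bool = False
    n_tables: int | None = None

    def __float__(self) -> float:
        return self.p_value


def _log_table_prob(t: np.ndarray, logfact_r, logfact_c, logfact_n) -> float:
    return float(logfact_r + logfact_c - logfact_n - gammaln(t + 1.0).sum())


def _enumerate_tables(row_sums, col_sums, cap):
    """Yield all nonnegative integer tables with the given margins;
    raises StopIteration-like None when the cap is exceeded."""
    r, c = len(row_sums), len(col_sums)
    tables = []

    def rec(i, remaining_cols, current):
        if len(tables) > cap:
            raise OverflowError
        if i == r - 1:
            last = remaining_cols
            if (last >= 0).all():
                tables.append(np.vstack(current + [last]))
            return
        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]), current + [np.array(row + [left])])
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, row_sums[i], [])

    rec(0, np.asarray(col_sums, dtype=np.int64), [])
    return tables


def fisher_exact(table, max_tables: int = 200_000, seed: int = 0,
                 n_sim: int = 100_000) -> FisherResult:
    """Two-sided Fisher's exact test by the minimum-likelihood criterion.

    The two-sided p is the total probability of all tables with the
    observed margins whose hypergeometric probability is at most that of
    the observed table (within a 1e-7 relative tolerance). 2x2 tables go
    through scipy; larger tables are enumerated exhaustively up to
    ``max_tables`` tables, beyond which a seeded Monte Carlo estimate
    (scipy's fixed-margin table sampler) is returned and flagged.
    """
    t = _clean_table(table)
    # degenerate margins: a single effective row or column
    nz_r, nz_c = (t.sum(axis=1) > 0).sum(), (t.sum(axis=0) > 0).sum()
    if nz_r < 2 or nz_c < 2:
        return FisherResult(1.0)
    if t.shape == (2, 2):
        return FisherResult(float(stats.fisher_exact(t)[1]))

    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    logfact_r = gammaln(row_sums + 1.0).sum()
    logfact_c = gammaln(col_sums + 1.0).sum()
    logfact_n = gammaln(t.sum() + 1.0)
    logp_obs = _log_table_prob(t, logfact_r, logfact_c, logfact_n)
    cutoff = logp_obs + np.log1p(1e-7)

    try:
        tables = _enumerate_tables(row_sums, col_sums, max_tables)
    except OverflowError:
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(row_sums, col_sums)
        draws = sampler.rvs(n_sim, random_state=rng)
        logps = np.array(
            [_log_table_prob(d, logfact_r, logfact_c, logfact_n) for d in draws]
        )
        return FisherResult(float(np.mean(logps <= cutoff)), simulated=True)

    logps = np.array([_log_table_prob(x, logfact_r, logfact_c, logfact_n) for x in tables])
    p = float(np.exp(logps[logps <= cutoff]).sum())
    return FisherResult(min(p, 1.0), n_tables=len(tables))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = (r-1)(c-1)."""
    t = _clean_table(table)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# table builders

DEFAULT_COVARIATES = [
    ("sex", "Gender", "categorical"),
    ("race", "Race", "categorical"),
    ("ethnicity", "Ethnicity", "categorical"),
    ("ga_birth_weeks", "Gestational age at birth (weeks)", "continuous"),
    ("birthweight_g", "Birthweight (g)", "continuous"),
    ("age_discharge_days", "Age at discharge (days)", "continuous"),
    ("neonatal_hypertension", "Neonatal hypertension", "categorical"),
    ("bronchopulmonary_dysplasia", "Bronchopulmonary dysplasia", "categorical"),
    ("patent_ductus_arteriosus", "Patent ductus arteriosus", "categorical"),
    ("acute_kidney_injury", "Acute kidney injury", "categorical"),
    ("congenital_heart_disease", "Congenital heart disease", "categorical"),
    ("pulmonary_hypertension", "Pulmonary hypertension", "categorical"),
]

_TEST_DISPLAY = {
    "kruskal-wallis": "Kruskal-Wallis rank sum test",
    "chi-square": "Pearson chi-square",
    "fisher": "Fisher exact",
    "none": "none",
}


@dataclass
class ClusterComparisonTable:
    """Per-cluster covariate summaries with the chosen test per row."""

    frame: pd.DataFrame
    clusters: list[str]

    def to_text(self) -> str:
        cols = ["variable", "level"] + [f"cluster_{c}" for c in self.clusters] + [
            "test", "p_rendered"
        ]
        return self.frame[cols].to_string(index=False)


def _series_by_cluster(values: pd.Series, labels: pd.Series, clusters) -> dict:
    return {c: values[labels == c] for c in clusters}


def build_comparison_table(
    assignments: pd.Series,
    covariates: pd.DataFrame,
    variables=DEFAULT_COVARIATES,
) -> ClusterComparisonTable:
    """Tables 3-5-style summary: one block per covariate, per-cluster
    median (Q1, Q3) or n (%), missing counts, the selected test and its
    p-value (full precision and rendered).

    ``assignments`` maps course_id -> cluster letter; ``covariates`` is
    indexed by course_id (visit covariates joined to courses, plus
    comorbidity flags).
    """
    clusters = sorted(assignments.unique())
    if any((assignments == c).sum() == 0 for c in clusters):
        raise ValueError("every cluster must have at least one member")
    cov = covariates.reindex(assignments.index)
    rows = []

    for col, label, kind in variables:
        if col not in cov.columns:
            continue
        values = cov[col]
        if kind == "continuous":
            values = pd.to_numeric(values, errors="coerce")
            groups = [values[assignments == c].dropna() for c in clusters]
            if all(len(g) == 0 for g in groups):
                test, p = "none", np.nan
            else:
                test = choose_test("continuous", groups)
                if test == "kruskal-wallis":
                    try:
                        _, p = kruskal_wallis(groups)
                    except ValueError:
                        test, p = "none", np.nan
                else:
                    p = np.nan
            cells = {}
            for c, g in zip(clusters, groups):
                if len(g):
                    med, q1, q3 = quartiles(g)
                    cells[f"cluster_{c}"] = f"{med:g} ({q1:g}, {q3:g})"
                else:
                    cells[f"cluster_{c}"] = "NA (NA, NA)"
            miss = {
                f"missing_{c}": int(values[assignments == c].isna().sum())
                for c in clusters
            }
            rows.append(
                {"variable": label, "level": "", **cells, **miss,
                 "test": _TEST_DISPLAY[test], "p_value": p,
                 "p_rendered": format_pvalue(p) if np.isfinite(p) else "N/A"}
            )
        else:
            s = values
            if s.dtype == object:
                s = s.replace("", pd.NA)
            if s.dtype == "boolean" or s.dtype == bool:
                s = s.map({True: "yes", False: "no"}, na_action="ignore")
            levels = sorted(pd.Series(s.dropna().unique()).astype(str))
            counts = np.zeros((len(levels), len(clusters)), dtype=int)
            denoms = {}
            for jc, c in enumerate(clusters):
                sub = s[assignments == c].dropna().astype(str)
                denoms[c] = len(sub)
                for il, lev in enumerate(levels):
                    counts[il, jc] = int((sub == lev).sum())
            if len(levels) == 0:
                test, p = "none", np.nan
            else:
                test = choose_test("categorical", counts)
                reduced = counts[counts.sum(axis=1) > 0]
                if reduced.size:
                    reduced = reduced[:, reduced.sum(axis=0) > 0]
                if test == "chi-square":
                    _, p = chi_square(reduced)
                elif test == "fisher":
                    p = fisher_exact(reduced).p_value
                else:
                    p = np.nan
            # boolean flags print a single "yes" row, like the source tables
            print_levels = ["yes"] if levels and set(levels) <= {"yes", "no"} else levels
            header_cells = {f"cluster_{c}": "" for c in clusters}
            miss = {
                f"missing_{c}": int(s[assignments == c].isna().sum()) for c in clusters
            }
            if print_levels == ["yes"]:
                il = levels.index("yes") if "yes" in levels else None
                for jc, c in enumerate(clusters):
                    nc = counts[il, jc] if il is not None else 0
                    d = denoms[c]
                    pct = nc / d * 100 if d else np.nan
                    header_cells[f"cluster_{c}"] = (
                        f"{nc} ({pct:.3g})" if d else "NA"
                    )
                rows.append(
                    {"variable": label, "level": "", **header_cells, **miss,
                     "test": _TEST_DISPLAY[test], "p_value": p,
                     "p_rendered": format_pvalue(p) if np.isfinite(p) else "N/A"}
                )
            else:
                rows.append(
                    {"variable": label, "level": "", **header_cells, **miss,
                     "test": _TEST_DISPLAY[test], "p_value": p,
                     "p_rendered": format_pvalue(p) if np.isfinite(p) else "N/A"}
                )
                for il, lev in enumerate(levels):
                    cells = {}
                    for jc, c in enumerate(clusters):
                        nc, d = counts[il, jc], denoms[c]
                        pct = nc / d * 100 if d else np.nan
                        cells[f"cluster_{c}"] = f"{nc} ({pct:.3g})" if d else "NA"
                    rows.append(
                        {"variable": label, "level": lev, **cells,
                         **{f"missing_{c}": np.nan for c in clusters},
                         "test": "", "p_value": np.nan, "p_rendered": ""}
                    )

    frame = pd.DataFrame(rows)
    return ClusterComparisonTable(frame=frame, clusters=clusters)


_REGIMEN_FIELDS = [
    ("postnatal_age_first_admin", "Postnatal age at first administration (days)", False),
    ("max_dose", "Maximum dose during treatment", False),
    ("min_dose", "Minimum dose during treatment", False),
    ("duration", "Duration of treatment (hours)", False),
    ("mean_time_to_increase", "Mean time to dose (mg) increase (hours)", True),
    ("mean_dose_increase", "Mean dose increase (mg)", True),
]


def regimen_table(summaries) -> pd.DataFrame:
    """Table-2-style per-drug regimen summary: median (Q1, Q3) of each
    descriptor over courses where present, with missing counts for the
    optional increase descriptors."""
    recs = pd.DataFrame(
        [
            {
                "drug": s.drug,
                "course_id": s.course_id,
                **{f: getattr(s, f) for f, _, _ in _REGIMEN_FIELDS},
            }
            for s in summaries
        ]
    )
    if len(recs) == 0:
        raise ValueError("need at least one regimen summary")
    rows = []
    for drug, grp in recs.groupby("drug", sort=True):
        for f, label, optional in _REGIMEN_FIELDS:
            vals = pd.to_numeric(grp[f], errors="coerce")
            nonmiss = vals.dropna()
            if len(nonmiss):
                med, q1, q3 = quartiles(nonmiss)
                summary = f"{med:.3g} ({q1:.3g}, {q3:.3g})"
            else:
                med = q1 = q3 = np.nan
                summary = ""
            rows.append(
                {"drug": drug, "variable": label, "n_courses": len(grp),
                 "median": med, "q1": q1, "q3": q3,
                 "missing": int(vals.isna().sum()) if optional else 0,
                 "summary": summary}
            )
    return pd.DataFrame(rows)
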