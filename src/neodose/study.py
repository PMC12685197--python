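"""End-to-end dosing-trajectory study: a model-style object over the
three EMR tables whose ``fit()`` runs cohort selection, trajectory
construction, window selection, clustering and cluster characterization,
returning a results object that carries every intermediate product and
writes a deterministic set of CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import compare as compare_mod
from .cluster import ClusterSolution, fit_range, vectorize
from .codes import HEMANGIOMA_PREFIXES, STUDY_DRUGS
from .simulate import attach_relative_minutes, read_cohort
from .trajectories import (
    CourseSplitError,
    build_trajectory,
    summarize_regimen,
    trajectories_frame,
)
from .window import WindowSelection, select_window

__all__ = ["StudyConfig", "DosingTrajectoryStudy", "StudyResults"]


@dataclass
class StudyConfig:
    drug_list: tuple[str, ...] = STUDY_DRUGS
    hemangioma_prefixes: tuple[str, ...] = HEMANGIOMA_PREFIXES
    top_n: int = 3
    ks: tuple[int, ...] = (2, 3, 4)
    table_k: int = 3  # cluster count used for the comparison tables
    window_overrides: dict[str, int] = field(default_factory=dict)
    window_grid: str = "hours"  # "hours" | "observed_durations"
    min_courses: int = 4  # below this, a drug is summarized but not clustered


class DosingTrajectoryStudy:
    """The full analysis over (visits, administrations, weights) tables.

    Tables must carry ``time_min`` columns (minutes since admission);
    :func:`neodose.simulate.attach_relative_minutes` adds them from
    ISO timestamps.
    """

    def __init__(self, visits, administrations, weights, config: StudyConfig | None = None):
        self.visits = visits
        self.administrations = administrations
        self.weights = weights
        self.config = config or StudyConfig()
        for frame, name in ((administrations, "administrations"), (weights, "weights")):
            if "time_min" not in frame.columns and len(frame):
                raise ValueError(f"{name} table lacks a time_min column; "
                                 "use attach_relative_minutes first")

    @classmethod
    def from_csv_dir(cls, indir, config: StudyConfig | None = None) -> "DosingTrajectoryStudy":
        visits, administrations, weights = read_cohort(indir)
        return cls(visits, administrations, weights, config=config)

    @classmethod
    def from_tables(cls, visits, administrations, weights, config=None) -> "DosingTrajectoryStudy":
        administrations, weights = attach_relative_minutes(visits, administrations, weights)
        return cls(visits, administrations, weights, config=config)

    def fit(self) -> "StudyResults":
        cfg = self.config
        included, ledger = cohort_mod.apply_inclusion(
            self.visits, self.administrations, cfg.drug_list, cfg.hemangioma_prefixes
        )
        flags = cohort_mod.derive_flags_table(included)
        cohort_summary = cohort_mod.summarize_cohort(included, flags)
        prevalence = cohort_mod.drug_prevalence(included, self.administrations)
        top = (
            cohort_mod.select_top_agents(prevalence, cfg.top_n) if len(prevalence) else []
        )

        admin_included = self.administrations[
            self.administrations["visit_id"].isin(set(included["visit_id"]))
        ]
        trajectories: dict[str, list] = {}
        regimens: dict[str, list] = {}
        for drug in top:
            trajs, summ = [], []
            sub = admin_included[admin_included["drug"] == drug]
            for visit_id, grp in sub.groupby("visit_id", sort=True):
                grp = grp.sort_values("time_min", kind="stable")
                wts = self.weights[self.weights["visit_id"] == visit_id]
                cid = f"{visit_id}:{drug}"
                try:
                    trajs.append(build_trajectory(grp, wts, course_id=cid))
                except CourseSplitError:
                    # mixed-route course: split per route deterministically
                    for route, rgrp in grp.groupby("route", sort=True):
                        trajs.append(
                            build_trajectory(rgrp, wts, course_id=f"{cid}:{route}")
                        )
                        summ.append(summarize_regimen(rgrp, wts, course_id=f"{cid}:{route}"))
                    continue
                summ.append(summarize_regimen(grp, wts, course_id=cid))
            trajectories[drug] = trajs
            regimens[drug] = summ

        windows: dict[str, WindowSelection] = {}
        solutions: dict[str, dict[int, ClusterSolution]] = {}
        for drug in top:
            trajs = trajectories[drug]
            if len(trajs) < max(cfg.min_courses, 3):
                continue
            grid = None
            if cfg.window_grid == "observed_durations":
                grid = sorted({t.end_hour for t in trajs})
            sel = select_window(
                trajs, grid=grid, override=cfg.window_overrides.get(drug)
            )
            windows[drug] = sel
            cm = vectorize(trajs, sel.chosen)
            ks = [k for k in cfg.ks if k <= cm.n]
            solutions[drug] = {s.k: s for s in fit_range(cm, ks)}

        regimen_tbl = (
            compare_mod.regimen_table([s for lst in regimens.values() for s in lst])
            if any(regimens.values())
            else pd.DataFrame()
        )

        comparison: dict[str, compare_mod.ClusterComparisonTable] = {}
        course_cov = self._course_covariates(included, flags)
        for drug, sols in solutions.items():
            if cfg.table_k not in sols:
                continue
            sol = sols[cfg.table_k]
            assignments = sol.assignments
            cov = course_cov.reindex(assignments.index)
            comparison[drug] = compare_mod.build_comparison_table(assignments, cov)

        return StudyResults(
            study=self,
            included=included,
            ledger=ledger,
            flags=flags,
            cohort_summary=cohort_summary,
            prevalence=prevalence,
            top_agents=top,
            trajectories=trajectories,
            regimens=regimens,
            regimen_table=regimen_tbl,
            windows=windows,
            solutions=solutions,
            comparison=comparison,
        )

    def _course_covariates(self, included: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
        """Visit covariates + flags, re-indexed by course_id."""
        base = included.set_index("visit_id")
        joined = base.join(flags, how="left")
        rows = {}
        pairs = self.administrations[["visit_id", "drug"]].drop_duplicates()
        for visit_id, drug in sorted(map(tuple, pairs.to_numpy())):
            if visit_id in joined.index:
                rows[f"{visit_id}:{drug}"] = joined.loc[visit_id]
        cov = pd.DataFrame(rows).T
        cov.index.name = "course_id"
        return cov


@dataclass
class StudyResults:
    """Everything the fitted study produced, with deterministic export."""

    study: DosingTrajectoryStudy
    included: pd.DataFrame
    ledger: cohort_mod.ExclusionLedger
    flags: pd.DataFrame
    cohort_summary: pd.DataFrame
    prevalence: pd.DataFrame
    top_agents: list[str]
    trajectories: dict
    regimens: dict
    regimen_table: pd.DataFrame
    windows: dict
    solutions: dict
    comparison: dict

    def assignments_frame(self) -> pd.DataFrame:
        rows = []
        for drug in sorted(self.solutions):
            for k in sorted(self.solutions[drug]):
                sol = self.solutions[drug][k]
                for cid, lab in zip(sol.course_ids, sol.letters):
                    rows.append((drug, k, cid, lab))
        return pd.DataFrame(rows, columns=["drug", "k", "course_id", "cluster"])

    def stepplot_frame(self, drug: str, k: int) -> pd.DataFrame:
        """Long-format (hour, dose, course_id, label) data sufficient to
        redraw the per-cluster step plots."""
        sol = self.solutions[drug][k]
        window = self.windows[drug].chosen
        by_id = {t.course_id: t for t in self.trajectories[drug]}
        rows = []
        for cid, lab in zip(sol.course_ids, sol.letters):
            vals = by_id[cid].sample(window)
            for h, v in enumerate(vals):
                rows.append((cid, lab, h, v))
        return pd.DataFrame(rows, columns=["course_id", "cluster", "hour", "dose"])

    def summary(self) -> str:
        lines = [
            "Dosing-trajectory study",
            f"  visits: {len(self.study.visits)} total, {len(self.included)} included, "
            f"{self.ledger.n_excluded} excluded",
            "  top agents: " + (", ".join(self.top_agents) if self.top_agents else "none"),
        ]
        for drug in self.top_agents:
            n = len(self.trajectories.get(drug, []))
            if drug in self.windows:
                sel = self.windows[drug]
                tag = f"window {sel.chosen} h" + (
                    f" (override; unconstrained argmax {sel.argmax} h)" if sel.overridden else ""
                )
            else:
                tag = "not clustered (too few courses)"
            lines.append(f"  {drug}: {n} courses, {tag}")
            for k in sorted(self.solutions.get(drug, {})):
                sol = self.solutions[drug][k]
                sizes = ", ".join(f"{l}={c}" for l, c in sol.sizes().items())
                lines.append(f"    k={k}: sizes {sizes}, WCSS {sol.wcss:.4g}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.included.to_csv(out / "included_visits.csv", index=False)
        self.ledger.records.to_csv(out / "exclusion_ledger.csv", index=False)
        self.ledger.counts.rename_axis("rule_id").rename("n").reset_index().to_csv(
            out / "exclusion_counts.csv", index=False
        )
        self.cohort_summary.to_csv(out / "cohort_summary.csv", index=False)
        self.prevalence.to_csv(out / "prevalence.csv", index=False)
        if len(self.regimen_table):
            self.regimen_table.to_csv(out / "regimen_table.csv", index=False)
        wrows = []
        for drug in sorted(self.windows):
            sel = self.windows[drug]
            wrows.append((drug, sel.chosen, sel.argmax, sel.overridden))
            sel.profile.to_csv(out / f"window_profile_{drug}.csv", index=False)
        pd.DataFrame(
            wrows, columns=["drug", "chosen_window", "unconstrained_argmax", "overridden"]
        ).to_csv(out / "windows.csv", index=False)
        for drug in sorted(self.trajectories):
            trajectories_frame(self.trajectories[drug]).to_csv(
                out / f"trajectories_{drug}.csv", index=False
            )
        self.assignments_frame().to_csv(out / "assignments.csv", index=False)
        for drug in sorted(self.solutions):
            for k in sorted(self.solutions[drug]):
                sol = self.solutions[drug][k]
                cent = pd.DataFrame(sol.centroids.T)
                cent.columns = [chr(ord("A") + i) for i in range(sol.k)]
                cent.insert(0, "hour", np.arange(sol.centroids.shape[1]))
                cent.to_csv(out / f"centroids_{drug}_k{k}.csv", index=False)
                self.stepplot_frame(drug, k).to_csv(
                    out / f"stepplot_{drug}_k{k}.csv", index=False
                )
        for drug in sorted(self.comparison):
            self.comparison[drug].frame.to_csv(
                out / f"comparison_{drug}_k{self.study.config.table_k}.csv", index=False
            )
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
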