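"""Weight-standardized, hourly piecewise-constant dose trajectories.

Each administration of an oral agent is standardized to mg/kg (mass over
the weight measured closest in time; exact ties in minutes are averaged);
IV infusion rates are standardized to mg/kg/min. A treatment course's
trajectory is a step function on a left-closed hour grid anchored at the
first administration: hour ``h`` carries the standardized dose of the
latest administration falling before the end of hour ``h``. Oral courses
keep the last dose for six hours after the final administration and drop
to 0 mg/kg (six hours being the modal dosing interval in this population);
IV courses end at an explicit rate-0 event, or one hour (configurable)
after the last rate event when no stop was recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MissingWeightError",
    "CourseSplitError",
    "DoseTrajectory",
    "RegimenSummary",
    "assign_weight",
    "standardize_dose",
    "build_trajectory",
    "summarize_regimen",
    "extract_courses",
]

ORAL_TAIL_HOURS = 6
DEFAULT_IV_SEGMENT_MIN = 60.0


class MissingWeightError(ValueError):
    """No weight measurement available for a visit."""


class CourseSplitError(ValueError):
    """A course mixes oral and IV administrations and must be split."""


@dataclass
class DoseTrajectory:
    """Hourly step curve of standardized dose for one treatment course.

    ``values[h]`` is the dose carried over hour ``h`` (hours since the
    first administration); the curve is 0 for every hour >= ``end_hour``.
    """

    course_id: str
    drug: str
    route: str  # "oral" | "IV"
    t0: float  # minutes since visit start of the first administration
    values: np.ndarray
    end_hour: int

    def sample(self, window: int) -> np.ndarray:
        """Curve evaluated at hours 0..window-1, zero past its end."""
        out = np.zeros(int(window), dtype=float)
        m = min(len(self.values), int(window))
        out[:m] = self.values[:m]
        return out

    @property
    def duration_hours(self) -> int:
        return int(self.end_hour)


@dataclass
class RegimenSummary:
    """Descriptors of one dosing regimen (Table-2-style inputs).

    Doses are per-administration standardized doses converted, for oral
    drugs, to mg/kg/day using the course's modal inter-dose interval
    (ties to the smaller interval; 6 h assumed for single-dose courses).
    ``mean_dose_increase`` / ``mean_time_to_increase`` are absent (None)
    when the administered mass load (mg) never increased.
    """

    course_id: str
    drug: str
    route: str
    postnatal_age_first_admin: float  # days
    min_dose: float
    max_dose: float
    duration: float  # hours, last minus first administration
    mean_time_to_increase: float | None = None  # hours
    mean_dose_increase: float | None = None  # mg (oral) / mg/min (IV)
    dose_unit: str = field(default="mg/kg/day")


def assign_weight(admin_time: float, weights: pd.DataFrame) -> float:
    """Weight (kg) measured closest in time to an administration.

    ``weights`` needs columns ``time_min`` and ``weight_g``. Exact ties in
    absolute minute distance are averaged.
    """
    if len(weights) == 0:
        raise MissingWeightError("no weight measurements available for this visit")
    t = np.asarray(weights["time_min"], dtype=float)
    w = np.asarray(weights["weight_g"], dtype=float)
    d = np.abs(t - float(admin_time))
    tied = d == d.min()
    return float(w[tied].mean()) / 1000.0


def standardize_dose(amount: float, weight_kg: float) -> float:
    """mg -> mg/kg (oral) or mg/min -> mg/kg/min (IV)."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    return float(amount) / float(weight_kg)


def _standardized_doses(admins: pd.DataFrame, weights: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    """Per-administration (relative minute, standardized dose) plus route."""
    routes = set(admins["route"])
    if len(routes) > 1:
        raise CourseSplitError(
            f"course mixes routes {sorted(routes)}; split into per-route courses"
        )
    route = routes.pop()
    times = np.asarray(admins["time_min"], dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    col = "mass_mg" if route == "oral" else "rate_mg_min"
    amounts = np.asarray(admins[col], dtype=float)[order]
    doses = np.array(
        [standardize_dose(a, assign_weight(t, weights)) for a, t in zip(amounts, times)]
    )
    return times, doses, route


def build_trajectory(
    admins: pd.DataFrame,
    weights: pd.DataFrame,
    course_id: str | None = None,
    iv_default_segment_min: float = DEFAULT_IV_SEGMENT_MIN,
) -> DoseTrajectory:
    """Build the hourly step trajectory for one course.

    ``admins`` needs columns ``drug``, ``route``, ``time_min`` and
    ``mass_mg`` (oral) or ``rate_mg_min`` (IV); all rows must share one
    drug and route.
    """
    if len(admins) == 0:
        raise ValueError("course has no administrations")
    times, doses, route = _standardized_doses(admins, weights)
    drug = admins["drug"].iloc[0]
    t0 = float(times[0])
    rel = times - t0

    if route == "oral":
        end_hour = int(math.ceil(rel[-1] / 60.0)) + ORAL_TAIL_HOURS
    else:
        # rate-0 event is an explicit stop; otherwise one default segment
        if doses[-1] == 0.0:
            t_stop = rel[-1]
        else:
            t_stop = rel[-1] + float(iv_default_segment_min)
        end_hour = int(math.ceil(t_stop / 60.0))
        end_hour = max(end_hour, 1)

    hours = np.arange(end_hour)
    # hour h carries the latest administration with rel < (h+1)*60
    idx = np.searchsorted(rel, (hours + 1) * 60.0, side="left") - 1
    idx = np.clip(idx, 0, len(doses) - 1)
    values = doses[idx]
    if course_id is None:
        course_id = f"{admins['visit_id'].iloc[0]}:{drug}"
    return DoseTrajectory(
        course_id=str(course_id),
        drug=str(drug),
        route=str(route),
        t0=t0,
        values=values,
        end_hour=end_hour,
    )


def _modal_interval_hours(rel_minutes: np.ndarray) -> float:
    """Modal inter-administration gap in hours; ties to the smaller gap;
    6 h for single-administration courses (no observed gap)."""
    if len(rel_minutes) < 2:
        return 6.0
    gaps = np.diff(rel_minutes) / 60.0
    vals, counts = np.unique(gaps, return_counts=True)
    return float(vals[counts == counts.max()].min())


def summarize_regimen(
    admins: pd.DataFrame,
    weights: pd.DataFrame,
    course_id: str | None = None,
) -> RegimenSummary:
    """Regimen descriptors for one course.

    Dose increase is defined on the administered mass load: a strict
    increase in mg (oral) or mg/min (IV) versus the immediately preceding
    administration. The mean time to increase averages gaps between
    consecutive increases, the first gap measured from the first
    administration.
    """
    times, doses, route = _standardized_doses(admins, weights)
    drug = admins["drug"].iloc[0]
    rel = times - times[0]
    if route == "oral":
        modal = _modal_interval_hours(rel)
        factor = 24.0 / modal
        unit = "mg/kg/day"
    else:
        factor = 1.0
        unit = "mg/kg/min"

    col = "mass_mg" if route == "oral" else "rate_mg_min"
    amounts = np.asarray(admins.sort_values("time_min", kind="stable")[col], dtype=float)
    deltas = np.diff(amounts)
    inc_mask = deltas > 0
    if inc_mask.any():
        mean_inc = float(deltas[inc_mask].mean())
        inc_times = rel[1:][inc_mask] / 60.0
        gaps = np.diff(np.concatenate([[0.0], inc_times]))
        mean_time = float(gaps.mean())
    else:
        mean_inc = None
        mean_time = None

    if course_id is None:
        course_id = f"{admins['visit_id'].iloc[0]}:{drug}"
    return RegimenSummary(
        course_id=str(course_id),
        drug=str(drug),
        route=route,
        postnatal_age_first_admin=float(times[0]) / 1440.0,
        min_dose=float(doses.min()) * factor,
        max_dose=float(doses.max()) * factor,
        duration=float(rel[-1]) / 60.0,
        mean_time_to_increase=mean_time,
        mean_dose_increase=mean_inc,
        dose_unit=unit,
    )


def extract_courses(administrations: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    """Split an administrations table into (course_id, frame) pairs,
    one course per (visit, drug), sorted for determinism."""
    out = []
    for (visit_id, drug), grp in administrations.groupby(["visit_id", "drug"], sort=True):
        out.append((f"{visit_id}:{drug}", grp.sort_values("time_min", kind="stable")))
    return out


def trajectories_frame(trajs: list[DoseTrajectory]) -> pd.DataFrame:
    """Long-format (course_id, hour, value) frame over each course's own support."""
    rows = []
    for tr in trajs:
        for h, v in enumerate(tr.values):
            rows.append((tr.course_id, tr.drug, h, v))
    return pd.DataFrame(rows, columns=["course_id", "drug", "hour", "value"])
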