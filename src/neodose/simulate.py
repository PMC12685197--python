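"""Synthetic EMR-style cohort with planted dosing archetypes.

The study data (an inpatient EMR extract of antihypertensive
administrations in preterm neonates) are access-restricted, so every
downstream stage is driven by a fully synthetic cohort with ground-truth
labels. Per drug, three dosing archetypes are planted, mirroring the
cluster morphologies observed clinically: propranolol is mostly started
at a target weight-based dose and held; captopril starts low and is
titrated stepwise; esmolol (IV) ranges from short low-rate infusions to
rapid high-rate titrations.

Oral masses (mg) are recomputed from the intended mg/kg level only when
the level changes and otherwise held fixed, so the standardized mg/kg
dose drifts downward as the infant gains weight — the same mechanism
that produces slow dose decreases in real records. Weights are emitted
daily. With ``noise_sd = 0`` and ``weight_growth_rate = 0`` the
trajectory rebuilt from the emitted records reproduces the intended dose
path on the hour grid.

Determinism: one root seed; each patient draws from its own counter-keyed
substream, so row order never affects the draws and a fixed seed yields
byte-identical CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .trajectories import assign_weight

__all__ = [
    "Archetype",
    "GeneratorConfig",
    "GroundTruth",
    "ConfigError",
    "DegenerateDesignError",
    "generate_cohort",
    "planted_separation",
    "write_cohort",
    "read_cohort",
    "attach_relative_minutes",
]

_EPOCH = datetime(2015, 1, 1)

VISIT_COLUMNS = [
    "patient_id", "visit_id", "admit_time", "sex", "race", "ethnicity",
    "ga_birth_weeks", "birthweight_g", "age_discharge_days",
    "pma_discharge_weeks", "dx_codes", "dx_missing",
]
ADMIN_COLUMNS = ["visit_id", "drug", "route", "time", "mass_mg", "rate_mg_min"]
WEIGHT_COLUMNS = ["visit_id", "time", "weight_g"]
TRUTH_COLUMNS = ["course_id", "visit_id", "drug", "archetype", "intended_path"]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the field."""


class DegenerateDesignError(ValueError):
    """Fewer than two archetypes present where a separation is required."""


@dataclass(frozen=True)
class Archetype:
    """One planted dosing pattern.

    ``start_dose`` is mg/kg per administration (oral) or mg/kg/min (IV).
    A titration adds ``step`` every ``step_every_h`` hours up to
    ``max_dose``; ``step = 0`` holds the start dose. Durations and the
    postnatal start day are drawn uniformly from the given ranges, and
    the gestational-age range lets archetypes plant covariate shifts.
    """

    name: str
    start_dose: float
    step: float = 0.0
    step_every_h: float = 48.0
    max_dose: float | None = None
    duration_h: tuple[float, float] = (100.0, 300.0)
    start_day: tuple[float, float] = (5.0, 38.0)
    ga_weeks: tuple[float, float] = (27.0, 36.5)

    def level(self, t_h: float) -> float:
        if self.step == 0.0:
            return self.start_dose
        lvl = self.start_dose + self.step * np.floor(t_h / self.step_every_h)
        cap = self.max_dose if self.max_dose is not None else np.inf
        return float(min(lvl, cap))


DEFAULT_ARCHETYPES: dict[str, tuple[Archetype, ...]] = {
    "propranolol": (
        Archetype("maintain", 0.75, duration_h=(150, 280), start_day=(5, 38),
                  ga_weeks=(30.0, 36.5)),
        Archetype("low-titrate", 0.40, step=0.15, step_every_h=48.0, max_dose=1.0,
                  duration_h=(300, 450), start_day=(5, 38), ga_weeks=(29.0, 36.0)),
        Archetype("high-start", 1.25, duration_h=(480, 700), start_day=(10, 45),
                  ga_weeks=(26.0, 31.0)),
    ),
    "captopril": (
        Archetype("low-brief", 0.15, duration_h=(24, 72), start_day=(12, 90),
                  ga_weeks=(24.5, 30.0)),
        Archetype("stepwise-up", 0.15, step=0.10, step_every_h=72.0, max_dose=0.5,
                  duration_h=(250, 400), start_day=(12, 90), ga_weeks=(24.5, 30.0)),
        Archetype("fast-up", 0.30, step=0.15, step_every_h=24.0, max_dose=0.9,
                  duration_h=(120, 250), start_day=(12, 90), ga_weeks=(24.5, 30.0)),
    ),
    "esmolol": (
        Archetype("short-low", 0.05, duration_h=(12, 36), start_day=(1, 12),
                  ga_weeks=(28.0, 36.5)),
        Archetype("long-moderate", 0.10, step=0.02, step_every_h=12.0, max_dose=0.2,
                  duration_h=(80, 140), start_day=(1, 12), ga_weeks=(28.0, 36.5)),
        Archetype("high-rapid", 0.35, step=0.05, step_every_h=6.0, max_dose=0.5,
                  duration_h=(30, 60), start_day=(1, 12), ga_weeks=(28.0, 36.5)),
    ),
}

DRUG_ROUTES = {"propranolol": "oral", "captopril": "oral", "esmolol": "IV"}


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    seed: int = 0
    #: proportions over the three emitted agents
    drug_mix: dict[str, float] = field(
        default_factory=lambda: {"propranolol": 0.74, "captopril": 0.11, "esmolol": 0.15}
    )
    #: per-drug proportions over its three archetypes (largest first)
    archetype_mix: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "propranolol": (0.51, 0.30, 0.19),
            "captopril": (0.50, 0.30, 0.20),
            "esmolol": (0.64, 0.22, 0.14),
        }
    )
    archetypes: dict[str, tuple[Archetype, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    #: per-administration perturbation of the standardized dose
    noise_sd: float = 0.05
    weight_growth_rate: float = 20.0  # g/day
    missing_birthweight_prob: float = 0.55
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "neonatal_hypertension": 0.11,
            "bronchopulmonary_dysplasia": 0.32,
            "acute_kidney_injury": 0.037,
            "congenital_heart_disease": 0.54,
            "patent_ductus_arteriosus": 0.35,
            "pulmonary_hypertension": 0.098,
        }
    )
    #: probabilities of deliberately excludable records
    exclusion_spike_probs: dict[str, float] = field(
        default_factory=lambda: {"term_ga": 0.04, "iv_propranolol": 0.02, "hemangioma": 0.03}
    )
    missing_dx_prob: float = 0.05
    cotherapy_prob: float = 0.0  # esmolol-then-propranolol sequences

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.weight_growth_rate < 0:
            raise ConfigError("weight_growth_rate must be >= 0")
        if abs(sum(self.drug_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("drug_mix proportions must sum to 1")
        if any(p < 0 for p in self.drug_mix.values()):
            raise ConfigError("drug_mix proportions must be >= 0")
        for drug, mix in self.archetype_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise ConfigError(f"archetype_mix[{drug}] must be nonnegative and sum to 1")
            if drug in self.archetypes and len(mix) != len(self.archetypes[drug]):
                raise ConfigError(f"archetype_mix[{drug}] length mismatch with archetypes")
        for name, p in {
            "missing_birthweight_prob": self.missing_birthweight_prob,
            "missing_dx_prob": self.missing_dx_prob,
            "cotherapy_prob": self.cotherapy_prob,
            **{f"exclusion_spike_probs[{k}]": v for k, v in self.exclusion_spike_probs.items()},
            **{f"comorbidity_prevalences[{k}]": v for k, v in self.comorbidity_prevalences.items()},
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")


@dataclass
class GroundTruth:
    """Planted label and intended standardized dose path for one course.

    ``intended_dose_path`` is a list of (hour, dose) breakpoints; the
    path is the step function carrying each dose from its breakpoint to
    the next, 0 from the final breakpoint on.
    """

    course_id: str
    visit_id: str
    drug: str
    archetype_label: str
    intended_dose_path: list[tuple[float, float]]

    def sample(self, window: int) -> np.ndarray:
        t = np.array([p[0] for p in self.intended_dose_path])
        v = np.array([p[1] for p in self.intended_dose_path])
        hours = np.arange(int(window), dtype=float)
        idx = np.searchsorted(t, hours, side="right") - 1
        out = np.where(idx >= 0, v[np.clip(idx, 0, len(v) - 1)], 0.0)
        return out.astype(float)

    def serialize_path(self) -> str:
        return "|".join(f"{h:g}:{d:.10g}" for h, d in self.intended_dose_path)

    @staticmethod
    def parse_path(text: str) -> list[tuple[float, float]]:
        if not text:
            return []
        return [tuple(map(float, part.split(":"))) for part in text.split("|")]


def _categorical(rng: np.random.Generator, items: list, probs: list[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


def _compress_path(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for h, d in points:
        if not out or out[-1][1] != d:
            out.append((h, d))
    return out


def _emit_course(
    rng: np.random.Generator,
    visit_id: str,
    drug: str,
    arch: Archetype,
    start_day: float,
    duration_h: float,
    weights_df: pd.DataFrame,
    noise_sd: float,
) -> tuple[list[tuple], GroundTruth]:
    """Emit administration rows and the ground-truth path for one course."""
    route = DRUG_ROUTES[drug]
    start_min = float(round(start_day * 1440.0))
    rows: list[tuple] = []
    path: list[tuple[float, float]] = []

    if route == "oral":
        offsets = np.arange(0.0, duration_h * 60.0 + 1e-9, 360.0)
        mass_held = None
        prev_level = None
        for off in offsets:
            t_h = off / 60.0
            level = arch.level(t_h)
            abs_min = start_min + off
            wkg = assign_weight(abs_min, weights_df)
            if mass_held is None or level != prev_level:
                mass_held = level * wkg
                prev_level = level
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            mass = max(mass_held + eps * wkg, 0.0)
            rows.append((visit_id, drug, "oral", abs_min, mass, np.nan))
            path.append((t_h, level))
        path = _compress_path(path)
        path.append((offsets[-1] / 60.0 + 6.0, 0.0))
    else:
        n_steps = int(np.ceil(duration_h / arch.step_every_h)) if arch.step else 1
        change_hours = [j * arch.step_every_h for j in range(n_steps)]
        change_hours = [h for h in change_hours if h < duration_h] or [0.0]
        for t_h in change_hours:
            level = arch.level(t_h)
            abs_min = start_min + round(t_h * 60.0)
            wkg = assign_weight(abs_min, weights_df)
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rate = max((level + eps) * wkg, 0.0)
            rows.append((visit_id, drug, "IV", abs_min, np.nan, rate))
            path.append((t_h, level))
        stop_rel = round(duration_h * 60.0)
        rows.append((visit_id, drug, "IV", start_min + stop_rel, np.nan, 0.0))
        path = _compress_path(path)
        # on the hour grid the stop takes effect at the hour containing it
        path.append((float(np.floor(stop_rel / 60.0)), 0.0))

    truth = GroundTruth(
        course_id=f"{visit_id}:{drug}",
        visit_id=visit_id,
        drug=drug,
        archetype_label=arch.name,
        intended_dose_path=path,
    )
    return rows, truth


_SEX_LEVELS = (["Female", "Male"], [0.40, 0.60])
_RACE_LEVELS = (
    ["White", "Black or African American", "Asian", "Other", "Hispanic or Latino"],
    [0.55, 0.38, 0.02, 0.02, 0.03],
)
_ETHNICITY_LEVELS = (["Non-Hispanic/Latino", "Hispanic/Latino"], [0.97, 0.03])

_FLAG_CODE_CHOICES = {
    "neonatal_hypertension": ["401.9", "I10", "P29.2"],
    "bronchopulmonary_dysplasia": ["770.7", "P27.1"],
    "acute_kidney_injury": ["584.9", "N17.1"],
    "congenital_heart_disease": ["745.4", "Q21.0", "Q25.1", "746.01"],
    "patent_ductus_arteriosus": ["747.0", "Q25.0"],
    "pulmonary_hypertension": ["747.83", "P29.30"],
}


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[GroundTruth]]:
    """Generate (visits, administrations, weights, ground truth).

    Tables follow the documented CSV schema with ISO-8601 minute
    timestamps; every non-spiked visit satisfies GA < 37 weeks and PMA at
    discharge < 44 weeks.
    """
    config.validate()
    visit_rows, admin_rows, weight_rows = [], [], []
    truths: list[GroundTruth] = []

    drugs = sorted(config.drug_mix)
    drug_probs = [config.drug_mix[d] for d in drugs]

    for i in range(config.n_patients):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, i])))
        patient_id, visit_id = f"P{i:04d}", f"V{i:04d}"

        spike = config.exclusion_spike_probs
        is_term = rng.random() < spike.get("term_ga", 0.0)
        is_iv_prop = rng.random() < spike.get("iv_propranolol", 0.0)
        has_hemangioma = rng.random() < spike.get("hemangioma", 0.0)

        drug = _categorical(rng, drugs, drug_probs)
        archs = config.archetypes[drug]
        mix = config.archetype_mix[drug]
        arch = archs[int(rng.choice(len(archs), p=np.asarray(mix) / np.sum(mix)))]

        duration_h = float(rng.uniform(*arch.duration_h))
        start_day = float(rng.uniform(*arch.start_day))
        discharge_day = int(np.ceil(start_day + duration_h / 24.0)) + int(rng.integers(2, 9))

        ga_hi = min(arch.ga_weeks[1], 43.8 - discharge_day / 7.0)
        ga_lo = min(arch.ga_weeks[0], ga_hi - 0.5)
        ga = float(rng.uniform(ga_lo, ga_hi))
        if is_term:
            ga = float(rng.uniform(37.5, 41.0))

        bw0 = float(np.round(max(rng.normal(1000.0 + (ga - 28.0) * 170.0, 220.0), 450.0)))

        days = np.arange(discharge_day + 1)
        wgt = np.round(bw0 + config.weight_growth_rate * days)
        weights_df = pd.DataFrame(
            {"time_min": days * 1440.0, "weight_g": wgt}
        )
        for d, w in zip(days, wgt):
            weight_rows.append((visit_id, float(d * 1440.0), float(w)))

        rows, truth = _emit_course(
            rng, visit_id, drug, arch, start_day, duration_h, weights_df, config.noise_sd
        )
        admin_rows.extend(rows)
        truths.append(truth)

        if config.cotherapy_prob and drug == "propranolol" and rng.random() < config.cotherapy_prob:
            e_arch = config.archetypes["esmolol"][0]
            e_start = float(rng.uniform(0.5, max(1.0, start_day - 5.0)))
            e_dur = float(rng.uniform(*e_arch.duration_h))
            e_rows, e_truth = _emit_course(
                rng, visit_id, "esmolol", e_arch, e_start, e_dur, weights_df, config.noise_sd
            )
            admin_rows.extend(e_rows)
            truths.append(e_truth)

        if is_iv_prop:
            t_spike = float(round(start_day * 1440.0)) + 30.0
            rate = 0.5 * assign_weight(t_spike, weights_df)
            admin_rows.append((visit_id, "propranolol", "IV", t_spike, np.nan, rate))

        dx = set()
        for flag in sorted(config.comorbidity_prevalences):
            if rng.random() < config.comorbidity_prevalences[flag]:
                choices = _FLAG_CODE_CHOICES[flag]
                dx.add(choices[int(rng.integers(len(choices)))])
        if has_hemangioma:
            dx.add("D18.01")
        dx_missing = rng.random() < config.missing_dx_prob
        dx_str = "" if dx_missing else ";".join(sorted(dx))

        sex = _categorical(rng, *_SEX_LEVELS) if rng.random() > 0.01 else ""
        race = _categorical(rng, *_RACE_LEVELS) if rng.random() > 0.07 else ""
        eth = _categorical(rng, *_ETHNICITY_LEVELS) if rng.random() > 0.08 else ""
        bw_missing = rng.random() < config.missing_birthweight_prob

        admit = _EPOCH + timedelta(
            days=int(rng.integers(0, 2922)), minutes=int(rng.integers(0, 1440))
        )
        visit_rows.append(
            (
                patient_id, visit_id, admit.strftime("%Y-%m-%dT%H:%M"), sex, race, eth,
                round(ga, 1), "" if bw_missing else bw0, discharge_day,
                round(ga + discharge_day / 7.0, 2), dx_str, dx_missing,
            )
        )

    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    administrations = pd.DataFrame(admin_rows, columns=["visit_id", "drug", "route", "time_min", "mass_mg", "rate_mg_min"])
    weights = pd.DataFrame(weight_rows, columns=["visit_id", "time_min", "weight_g"])

    # attach ISO timestamps (admit + minutes) while keeping minute offsets
    admit_map = {r[1]: datetime.strptime(r[2], "%Y-%m-%dT%H:%M") for r in visit_rows}

    def _stamp(frame: pd.DataFrame) -> pd.DataFrame:
        if len(frame) == 0:
            frame = frame.copy()
            frame.insert(1, "time", pd.Series(dtype=str))
            return frame
        stamps = [
            (admit_map[v] + timedelta(minutes=float(t))).strftime("%Y-%m-%dT%H:%M")
            for v, t in zip(frame["visit_id"], frame["time_min"])
        ]
        frame = frame.copy()
        frame.insert(1, "time", stamps)
        return frame

    administrations = _stamp(administrations)
    weights = _stamp(weights)
    # canonical column order with both absolute and relative times
    administrations = administrations[
        ["visit_id", "drug", "route", "time", "time_min", "mass_mg", "rate_mg_min"]
    ]
    weights = weights[["visit_id", "time", "time_min", "weight_g"]]
    return visits, administrations, weights, truths


def planted_separation(truths: list[GroundTruth], window: int) -> float:
    """Minimum Euclidean distance between archetype centroids.

    Each archetype's centroid is the mean of its intended dose paths
    discretized on the hourly grid over [0, window).
    """
    groups: dict[str, list[np.ndarray]] = {}
    for t in truths:
        groups.setdefault(t.archetype_label, []).append(t.sample(int(window)))
    if len(groups) < 2:
        raise DegenerateDesignError(
            f"need >= 2 archetypes to compute a separation, got {len(groups)}"
        )
    cents = {k: np.mean(v, axis=0) for k, v in groups.items()}
    labels = sorted(cents)
    dmin = np.inf
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            dmin = min(dmin, float(np.linalg.norm(cents[labels[a]] - cents[labels[b]])))
    return dmin


def truths_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.course_id, t.visit_id, t.drug, t.archetype_label, t.serialize_path())
            for t in truths
        ],
        columns=TRUTH_COLUMNS,
    )


def write_cohort(outdir, visits, administrations, weights, truths=None) -> None:
    """Write the cohort CSVs (documented schema, ISO minute timestamps)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    visits.to_csv(out / "visits.csv", index=False)
    administrations.drop(columns=["time_min"], errors="ignore").to_csv(
        out / "administrations.csv", index=False
    )
    weights.drop(columns=["time_min"], errors="ignore").to_csv(
        out / "weights.csv", index=False
    )
    if truths is not None:
        truths_frame(truths).to_csv(out / "ground_truth.csv", index=False)


def read_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the cohort CSVs and attach minute offsets relative to admission."""
    from pathlib import Path

    p = Path(indir)
    visits = pd.read_csv(p / "visits.csv", keep_default_na=False, na_values=[])
    administrations = pd.read_csv(p / "administrations.csv")
    weights = pd.read_csv(p / "weights.csv")
    administrations, weights = attach_relative_minutes(visits, administrations, weights)
    return visits, administrations, weights


def attach_relative_minutes(
    visits: pd.DataFrame, administrations: pd.DataFrame, weights: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute ``time_min`` (minutes since admission) from the ISO stamps."""
    admit = pd.to_datetime(visits.set_index("visit_id")["admit_time"])

    def _rel(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        if len(frame) == 0:
            frame["time_min"] = pd.Series(dtype=float)
            return frame
        t = pd.to_datetime(frame["time"])
        base = frame["visit_id"].map(admit)
        frame["time_min"] = (t - base).dt.total_seconds() / 60.0
        return frame

    return _rel(administrations), _rel(weights)
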