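"""Study drug list and ICD-9/10 code lists for comorbidity flags.

All lists are configuration data, not logic: downstream functions accept
alternatives. Codes are matched exactly on a normalized form that is
case-insensitive and insensitive to trailing zeros after the decimal point
(so ``745.60`` and ``745.6`` are the same code). The hemangioma exclusion
is the one prefix-matched list (``D18.0*`` / ``228.0*``), matched on the
raw upper-cased code so that e.g. D18.1 (lymphangioma) is not swallowed.
"""

from __future__ import annotations

#: The 14 antihypertensive agents defining cohort eligibility:
#: vasodilators, ACE inhibitors, beta-blockers, calcium channel blockers.
STUDY_DRUGS: tuple[str, ...] = (
    "hydralazine",
    "nitroprusside",
    "clonidine",
    "enalapril",
    "captopril",
    "propranolol",
    "labetalol",
    "esmolol",
    "atenolol",
    "metoprolol",
    "amlodipine",
    "isradipine",
    "nifedipine",
    "nicardipine",
)

#: Discharge-diagnosis code lists backing each comorbidity flag.
FLAG_CODES: dict[str, frozenset[str]] = {
    "neonatal_hypertension": frozenset({"401.9", "I10", "P29.2"}),
    "bronchopulmonary_dysplasia": frozenset({"770.7", "P27.1"}),
    "acute_kidney_injury": frozenset({"584.9", "N17.1"}),
    "congenital_heart_disease": frozenset(
        {
            # ICD-9
            "745.0", "745.10", "745.11", "745.2", "745.3", "745.4", "745.5",
            "745.60", "745.61", "745.69", "746.01", "746.1", "746.2", "746.3",
            "746.7", "747.10", "747.11", "747.41",
            # ICD-10
            "Q20.0", "Q20.1", "Q20.3", "Q20.4", "Q21.0", "Q21.1", "Q21.2",
            "Q21.3", "Q22.0", "Q22.4", "Q22.5", "Q23.0", "Q23.4", "Q25.1",
            "Q25.2", "Q25.21", "Q25.4", "Q26.2",
        }
    ),
    # PDA codes are a package default (standard codes); configurable.
    "patent_ductus_arteriosus": frozenset({"747.0", "Q25.0"}),
    "pulmonary_hypertension": frozenset({"747.83", "P29.30"}),
}

FLAG_NAMES: tuple[str, ...] = tuple(FLAG_CODES)

#: Hemangioma in any code position excludes a visit (propranolol has a
#: second indication there). Prefix semantics.
HEMANGIOMA_PREFIXES: tuple[str, ...] = ("D18.0", "228.0")


def normalize_code(code: str) -> str:
    """Normalize an ICD code: upper-case, strip blanks and trailing
    zeros in the fractional part (``745.60`` -> ``745.6``, ``Q20.0`` -> ``Q20``)."""
    code = str(code).strip().upper()
    if "." in code:
        head, frac = code.split(".", 1)
        frac = frac.rstrip("0")
        return f"{head}.{frac}" if frac else head
    return code


def normalize_codes(codes) -> frozenset[str]:
    return frozenset(normalize_code(c) for c in codes if str(c).strip())


def is_hemangioma(code: str, prefixes=HEMANGIOMA_PREFIXES) -> bool:
    c = str(code).strip().upper()
    return any(c.startswith(p.upper()) for p in prefixes)
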