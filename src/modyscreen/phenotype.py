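"""Rule-based diabetes phenotyping.

Classifies biobank participants into T1DM / T2DM / non-diabetes from blood
biomarkers (HbA1c, serum C-peptide) and self-report flags, assigns WHO BMI
categories, applies the classical clinical MODY screen (diabetic, normal BMI,
onset before age 25), and produces cohort-level summary tables.

The classification is a total function: a missing biomarker means the
corresponding criterion is not met, never an error.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DiabetesStatus",
    "BMICategory",
    "SubjectPhenotype",
    "classify_diabetes",
    "classify_bmi",
    "meets_clinical_mody_criteria",
    "classify_cohort",
    "summarize_cohort",
    "CohortSummary",
    "read_phenotypes",
    "write_phenotypes",
    "PHENOTYPE_COLUMNS",
]

# C-peptide below this (ng/mL) in a self-declared diabetic on insulin only
# indicates absolute insulin deficiency, i.e. type 1 diabetes.
T1DM_C_PEPTIDE_MAX = 0.5
# HbA1c strictly above this percentage is diagnostic for diabetes.
T2DM_HBA1C_THRESHOLD = 6.5
# Clinical MODY screen: age of onset strictly below this (years).
MODY_ONSET_MAX_AGE = 25.0


class DiabetesStatus(str, Enum):
    T1DM = "T1DM"
    T2DM = "T2DM"
    NON_DIABETES = "NON_DIABETES"


class BMICategory(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"
    NOT_AVAILABLE = "not_available"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SubjectPhenotype:
    """One participant's phenotype record.

    Optional floats use ``None`` for "not measured"; booleans default to
    False ("not reported"). Units: age/onset in years, bmi in kg/m^2,
    hba1c in percent, c_peptide in ng/mL.
    """

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float | None = None
    hba1c: float | None = None
    c_peptide: float | None = None
    self_declared_diabetes: bool = False
    on_insulin: bool = False
    on_tablets: bool = False
    age_of_onset: float | None = None
    family_history_father: bool = False
    family_history_mother: bool = False

    def __post_init__(self):
        if not (0 <= self.age <= 130):
            raise ValueError(f"{self.subject_id}: age {self.age} outside [0, 130]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.subject_id}: sex must be 'male' or 'female'")
        if not _is_missing(self.hba1c) and self.hba1c <= 0:
            raise ValueError(f"{self.subject_id}: HbA1c must be > 0 when present")
        if not _is_missing(self.c_peptide) and self.c_peptide < 0:
            raise ValueError(f"{self.subject_id}: C-peptide must be >= 0")
        if not _is_missing(self.bmi) and self.bmi <= 0:
            raise ValueError(f"{self.subject_id}: BMI must be positive when present")


def classify_diabetes(subject: SubjectPhenotype) -> DiabetesStatus:
    """Assign T1DM, T2DM or non-diabetes by the rule cascade.

    T1DM: self-declared diabetes, on insulin exclusively (no tablets), and
    measured C-peptide < 0.5 ng/mL. Failing that, T2DM if any of:
    self-declared diabetes, any diabetes medication, or HbA1c > 6.5%.
    Everyone else is non-diabetes. Missing values never satisfy a criterion.
    """
    if (
        subject.self_declared_diabetes
        and subject.on_insulin
        and not subject.on_tablets
        and not _is_missing(subject.c_peptide)
        and subject.c_peptide < T1DM_C_PEPTIDE_MAX
    ):
        return DiabetesStatus.T1DM
    if (
        subject.self_declared_diabetes
        or subject.on_insulin
        or subject.on_tablets
        or (not _is_missing(subject.hba1c) and subject.hba1c > T2DM_HBA1C_THRESHOLD)
    ):
        return DiabetesStatus.T2DM
    return DiabetesStatus.NON_DIABETES


def classify_bmi(bmi: float | None) -> BMICategory:
    """WHO BMI bands: <18.5, [18.5, 25), [25, 30), >=30; None -> not_available."""
    if _is_missing(bmi):
        return BMICategory.NOT_AVAILABLE
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return BMICategory.UNDERWEIGHT
    if bmi < 25.0:
        return BMICategory.NORMAL
    if bmi < 30.0:
        return BMICategory.OVERWEIGHT
    return BMICategory.OBESE


def meets_clinical_mody_criteria(
    subject: SubjectPhenotype, status: DiabetesStatus
) -> bool:
    """Classical clinical MODY screen: diabetic, normal BMI, onset < 25 years.

    Missing age of onset (common in self-reported data) counts as not met.
    """
    return (
        status in (DiabetesStatus.T1DM, DiabetesStatus.T2DM)
        and classify_bmi(subject.bmi) is BMICategory.NORMAL
        and not _is_missing(subject.age_of_onset)
        and subject.age_of_onset < MODY_ONSET_MAX_AGE
    )


def classify_cohort(
    subjects: Iterable[SubjectPhenotype],
) -> dict[str, DiabetesStatus]:
    """Classify every subject; returns subject_id -> status."""
    return {s.subject_id: classify_diabetes(s) for s in subjects}


@dataclass
class CohortSummary:
    """Cohort characteristics in the style of a baseline-characteristics table.

    ``class_counts``/``class_pct`` partition the cohort by diabetes status;
    biomarker entries are (mean, sd) per class; percentages use the full
    cohort as denominator and are rounded to 1 decimal.
    """

    n_subjects: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    sex_counts: dict[str, dict[str, int]]
    bmi_category_counts: dict[str, dict[str, int]]
    biomarker_mean_sd: dict[str, dict[str, tuple[float, float]]]
    family_history_counts: dict[str, dict[str, int]]
    treatment_counts: dict[str, dict[str, int]]
    n_clinical_mody: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary table (one row per class/metric)."""
        rows = []
        for cls in self.class_counts:
            rows.append(
                {
                    "class": cls,
                    "n": self.class_counts[cls],
                    "pct": self.class_pct[cls],
                    **{
                        f"{m}_mean": self.biomarker_mean_sd[cls][m][0]
                        for m in self.biomarker_mean_sd[cls]
                    },
                    **{
                        f"{m}_sd": self.biomarker_mean_sd[cls][m][1]
                        for m in self.biomarker_mean_sd[cls]
                    },
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return (float("nan"), float("nan"))
    arr = np.asarray(values, dtype=float)
    return (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)


def summarize_cohort(
    subjects: list[SubjectPhenotype],
    statuses: Mapping[str, DiabetesStatus] | None = None,
) -> CohortSummary:
    """Per-class counts, percentages and biomarker summaries for a cohort."""
    if not subjects:
        raise ValueError("cannot summarize an empty cohort")
    if statuses is None:
        statuses = classify_cohort(subjects)

    n = len(subjects)
    classes = [s.value for s in DiabetesStatus]
    by_class: dict[str, list[SubjectPhenotype]] = {c: [] for c in classes}
    for subj in subjects:
        by_class[statuses[subj.subject_id].value].append(subj)

    class_counts = {c: len(v) for c, v in by_class.items()}
    class_pct = {c: round(100.0 * class_counts[c] / n, 1) for c in classes}

    sex_counts = {
        c: dict(Counter(s.sex for s in by_class[c])) for c in classes
    }
    bmi_counts = {
        c: dict(Counter(classify_bmi(s.bmi).value for s in by_class[c]))
        for c in classes
    }
    biomarkers = {}
    for c in classes:
        grp = by_class[c]
        biomarkers[c] = {
            "age": _mean_sd([s.age for s in grp]),
            "bmi": _mean_sd([s.bmi for s in grp if not _is_missing(s.bmi)]),
            "hba1c": _mean_sd([s.hba1c for s in grp if not _is_missing(s.hba1c)]),
            "c_peptide": _mean_sd(
                [s.c_peptide for s in grp if not _is_missing(s.c_peptide)]
            ),
        }
    fam = {
        c: {
            "father": sum(s.family_history_father for s in by_class[c]),
            "mother": sum(s.family_history_mother for s in by_class[c]),
            "both": sum(
                s.family_history_father and s.family_history_mother
                for s in by_class[c]
            ),
        }
        for c in classes
    }
    treat = {
        c: {
            "insulin": sum(s.on_insulin for s in by_class[c]),
            "tablets": sum(s.on_tablets for s in by_class[c]),
        }
        for c in classes
    }
    n_mody = sum(
        meets_clinical_mody_criteria(s, statuses[s.subject_id]) for s in subjects
    )
    return CohortSummary(
        n_subjects=n,
        class_counts=class_counts,
        class_pct=class_pct,
        sex_counts=sex_counts,
        bmi_category_counts=bmi_counts,
        biomarker_mean_sd=biomarkers,
        family_history_counts=fam,
        treatment_counts=treat,
        n_clinical_mody=n_mody,
    )


# ---------------------------------------------------------------------------
# Phenotype CSV I/O
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "bmi",
    "hba1c",
    "c_peptide",
    "self_declared_diabetes",
    "on_insulin",
    "on_tablets",
    "age_of_onset",
    "family_history_father",
    "family_history_mother",
]

_BOOL_COLS = [
    "self_declared_diabetes",
    "on_insulin",
    "on_tablets",
    "family_history_father",
    "family_history_mother",
]
_OPT_FLOAT_COLS = ["bmi", "hba1c", "c_peptide", "age_of_onset"]


def read_phenotypes(path: str | Path) -> list[SubjectPhenotype]:
    """Read a phenotype CSV (documented header, booleans as 0/1, blanks = missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns: {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        kwargs = {
            "subject_id": rec["subject_id"],
            "age": float(rec["age"]),
            "sex": str(rec["sex"]),
        }
        for col in _OPT_FLOAT_COLS:
            v = rec[col]
            kwargs[col] = None if _is_missing(v) else float(v)
        for col in _BOOL_COLS:
            v = rec[col]
            kwargs[col] = bool(int(v)) if not _is_missing(v) else False
        out.append(SubjectPhenotype(**kwargs))
    return out


def write_phenotypes(subjects: Iterable[SubjectPhenotype], path: str | Path) -> None:
    """Write subjects to CSV with the documented header."""
    rows = []
    for s in subjects:
        row = {c: getattr(s, c) for c in PHENOTYPE_COLUMNS}
        for col in _BOOL_COLS:
            row[col] = int(row[col])
        rows.append(row)
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(path, index=False)
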