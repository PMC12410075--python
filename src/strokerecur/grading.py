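"""Three-level stroke-recurrence severity grading.

Recurrent infarcts are graded mild / moderate / severe from two independent
axes — the new infarct's volume on CT/DWI and the NIHSS score at recurrence —
and the two grades are reconciled by taking the worse one when they disagree
(the clinical "mismatch" rule). All downstream analyses use the binary
recoding in which moderate and severe count as the event.

Grade boundaries
----------------
imaging   : volume < 1 cm3 → mild; 1–3 cm3 → moderate; > 3 cm3 → severe
clinical  : NIHSS 0–5 → mild; 6–15 → moderate; ≥ 16 → severe

A volume of exactly 3 cm3 is graded moderate, so the imaging partition is
exhaustive and disjoint: [0, 1), [1, 3], (3, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import pandas as pd

__all__ = [
    "SeverityGrade",
    "ImagingFinding",
    "grade_from_imaging",
    "grade_from_nihss",
    "combine_grades",
    "binarize_outcome",
    "grade_cohort",
]


class SeverityGrade(IntEnum):
    """Ordinal recurrence severity; comparisons use the integer level."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2


@dataclass(frozen=True)
class ImagingFinding:
    """Imaging description of a recurrent infarct.

    Only the volume drives the grade; the maximum diameter is a fallback used
    when the volume is unknown (same 1 cm / 3 cm cut-points), and the
    major-territory flag is descriptive only.
    """

    infarct_volume_cm3: float | None = None
    max_diameter_cm: float | None = None
    involves_major_territory: bool | None = None

    def __post_init__(self) -> None:
        if self.infarct_volume_cm3 is not None and self.infarct_volume_cm3 < 0:
            raise ValueError(f"infarct volume must be >= 0, got {self.infarct_volume_cm3}")
        if self.max_diameter_cm is not None and self.max_diameter_cm < 0:
            raise ValueError(f"infarct diameter must be >= 0, got {self.max_diameter_cm}")


def _grade_extent(x: float) -> SeverityGrade:
    if x < 1.0:
        return SeverityGrade.MILD
    if x <= 3.0:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def grade_from_imaging(finding: ImagingFinding | float) -> SeverityGrade:
    """Grade severity from imaging; a bare number is taken as volume in cm3."""
    if not isinstance(finding, ImagingFinding):
        finding = ImagingFinding(infarct_volume_cm3=float(finding))
    if finding.infarct_volume_cm3 is not None:
        return _grade_extent(finding.infarct_volume_cm3)
    if finding.max_diameter_cm is not None:
        return _grade_extent(finding.max_diameter_cm)
    raise ValueError("imaging finding has neither volume nor diameter")


def grade_from_nihss(score: int) -> SeverityGrade:
    """Grade severity from the NIHSS score (0–42)."""
    score = int(score)
    if not 0 <= score <= 42:
        raise ValueError(f"NIHSS must be in [0, 42], got {score}")
    if score <= 5:
        return SeverityGrade.MILD
    if score <= 15:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def combine_grades(imaging: SeverityGrade, clinical: SeverityGrade) -> SeverityGrade:
    """Reconcile imaging and clinical grades: the worse grade wins."""
    return SeverityGrade(max(int(imaging), int(clinical)))


def binarize_outcome(grade: SeverityGrade) -> int:
    """Binary event coding: moderate and severe → 1, mild → 0."""
    return int(SeverityGrade(int(grade)) >= SeverityGrade.MODERATE)


def grade_cohort(
    df: pd.DataFrame,
    volume_col: str = "infarct_volume_cm3",
    nihss_col: str = "nihss",
) -> pd.DataFrame:
    """Append `recurrence_grade` and `recurrence_binary` columns to a cohort table."""
    out = df.copy()
    grades = [
        combine_grades(grade_from_imaging(v), grade_from_nihss(s))
        for v, s in zip(out[volume_col], out[nihss_col])
    ]
    out["recurrence_grade"] = [int(g) for g in grades]
    out["recurrence_binary"] = [binarize_outcome(g) for g in grades]
    return out
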