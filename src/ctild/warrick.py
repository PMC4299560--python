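"""Warrick-style semiquantitative HRCT scoring.

Each of five abnormality patterns carries a fixed severity point value;
extent is graded per abnormality from the number of involved
bronchopulmonary segments (1-3 segments -> 1, 4-9 -> 2, >9 -> 3) and the
grades are summed across abnormalities.  The total score (severity +
extent) ranges 0-30 and is dichotomized at a cutoff of 7: <=7 mild, >7
severe lung fibrosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

SEVERITY_POINTS: dict[str, int] = {
    "ground_glass": 1,
    "irregular_pleural_margins": 2,
    "septal_subpleural_lines": 3,
    "honeycombing": 4,
    "subpleural_cysts": 5,
}

ABNORMALITIES: tuple[str, ...] = tuple(SEVERITY_POINTS)

#: standard bronchopulmonary segment count; higher values trigger a warning
MAX_SEGMENTS = 18

DEFAULT_SEVERE_CUTOFF = 7


@dataclass(frozen=True)
class WarrickCase:
    """Per-patient findings: abnormality -> number of involved segments."""

    findings: Mapping[str, int]

    def __post_init__(self) -> None:
        for abnormality, n_segments in self.findings.items():
            if abnormality not in SEVERITY_POINTS:
                raise ValidationError(
                    f"unknown abnormality {abnormality!r}; "
                    f"expected one of {sorted(SEVERITY_POINTS)}"
                )
            if not isinstance(n_segments, (int,)) or isinstance(n_segments, bool):
                raise ValidationError(
                    f"segment count for {abnormality!r} must be an integer"
                )
            if n_segments < 0:
                raise ValidationError(
                    f"segment count for {abnormality!r} must be >= 0"
                )
            if n_segments > MAX_SEGMENTS:
                warnings.warn(
                    f"{abnormality}: {n_segments} segments exceeds the standard "
                    f"bronchopulmonary segment count ({MAX_SEGMENTS})",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class WarrickScore:
    severity: int
    extent: int
    category: str  # "mild" or "severe"

    @property
    def total(self) -> int:
        return self.severity + self.extent


def severity_points(abnormality: str) -> int:
    """Fixed point value of an abnormality pattern."""
    try:
        return SEVERITY_POINTS[abnormality]
    except KeyError:
        raise ValidationError(
            f"unknown abnormality {abnormality!r}; "
            f"expected one of {sorted(SEVERITY_POINTS)}"
        ) from None


def extent_grade(n_segments: int) -> int:
    """Extent grade from the number of involved segments:
    0 -> 0, 1-3 -> 1, 4-9 -> 2, >=10 -> 3."""
    if isinstance(n_segments, bool) or not isinstance(n_segments, int):
        raise ValidationError("segment count must be an integer")
    if n_segments < 0:
        raise ValidationError(f"segment count must be >= 0, got {n_segments}")
    if n_segments == 0:
        return 0
    if n_segments <= 3:
        return 1
    if n_segments <= 9:
        return 2
    return 3


def categorize(total: float, cutoff: float = DEFAULT_SEVERE_CUTOFF) -> str:
    """Mild/severe dichotomization, strict ``> cutoff`` = severe."""
    return "severe" if total > cutoff else "mild"


def score_case(case: WarrickCase, cutoff: float = DEFAULT_SEVERE_CUTOFF) -> WarrickScore:
    """Score a case: severity sums point values of abnormalities present in
    at least one segment, extent sums per-abnormality extent grades.

    An abnormality reported with 0 segments is treated as absent.
    """
    severity = 0
    extent = 0
    for abnormality, n_segments in case.findings.items():
        grade = extent_grade(n_segments)
        if grade > 0:
            severity += severity_points(abnormality)
            extent += grade
    return WarrickScore(
        severity=severity, extent=extent, category=categorize(severity + extent, cutoff)
    )


def reader_consensus(
    scores_reader1: Sequence[float], scores_reader2: Sequence[float]
) -> list[float]:
    """Element-wise mean of two readers' totals (half points permitted)."""
    if len(scores_reader1) != len(scores_reader2):
        raise ValidationError(
            f"reader score lists differ in length: "
            f"{len(scores_reader1)} vs {len(scores_reader2)}"
        )
    return [(a + b) / 2.0 for a, b in zip(scores_reader1, scores_reader2)]


# ---------------------------------------------------------------------------
# CSV interface: long findings table -> per-patient score table


def read_findings_csv(path) -> dict[str, WarrickCase]:
    """Read a long-format findings table with columns
    ``patient_id, abnormality, n_segments``."""
    df = pd.read_csv(path)
    required = {"patient_id", "abnormality", "n_segments"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"findings CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    cases: dict[str, WarrickCase] = {}
    for patient_id, group in df.groupby("patient_id", sort=True):
        findings = {
            str(row.abnormality): int(row.n_segments) for row in group.itertuples()
        }
        cases[str(patient_id)] = WarrickCase(findings=findings)
    return cases


def score_table(
    cases: Mapping[str, WarrickCase], cutoff: float = DEFAULT_SEVERE_CUTOFF
) -> pd.DataFrame:
    """Score many cases into a tidy table."""
    rows = []
    for patient_id, case in cases.items():
        score = score_case(case, cutoff=cutoff)
        rows.append(
            {
                "patient_id": patient_id,
                "severity": score.severity,
                "extent": score.extent,
                "total": score.total,
                "category": score.category,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "severity", "extent", "total", "category"])
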