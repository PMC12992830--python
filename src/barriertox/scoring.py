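"""Clinical GI toxicity scoring.

Each drug's gastrointestinal adverse-event profile is condensed into a
single integer: the CTCAE v5.0 severity grade (1-4) multiplied by an
incidence score (uncommon = 1, common = 2, very common = 3), giving a
total of 1-12. Totals band into risk classes — low (<=3), moderate
(4-8), high (>=9) — and the binary reference label used throughout the
diagnostic evaluation is total >= 4 (moderate or high risk).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import DrugPanel, DrugRecord, IncidenceCategory

__all__ = [
    "RiskClass",
    "ToxicityScore",
    "DEFAULT_REFERENCE_THRESHOLD",
    "incidence_score",
    "total_score",
    "risk_class",
    "reference_label",
    "score_panel",
    "reference_labels",
]

DEFAULT_REFERENCE_THRESHOLD = 4

_INCIDENCE_SCORES = {
    IncidenceCategory.UNCOMMON: 1,
    IncidenceCategory.COMMON: 2,
    IncidenceCategory.VERY_COMMON: 3,
}

RISK_LOW = "low"
RISK_MODERATE = "moderate"
RISK_HIGH = "high"
RiskClass = str


def incidence_score(category: IncidenceCategory | str) -> int:
    """uncommon -> 1, common -> 2, very common -> 3 (case-insensitive)."""
    if isinstance(category, str):
        category = IncidenceCategory(category.strip().lower())
    return _INCIDENCE_SCORES[category]


def risk_class(total: int) -> RiskClass:
    """Band a total score: low (<=3), moderate (4-8), high (>=9)."""
    if not 1 <= total <= 12:
        raise ValueError(f"total score must be in 1-12, got {total}")
    if total <= 3:
        return RISK_LOW
    if total <= 8:
        return RISK_MODERATE
    return RISK_HIGH


@dataclass(frozen=True)
class ToxicityScore:
    severity_score: int
    incidence_score: int
    total: int
    risk_class: RiskClass
    reference_positive: bool


def total_score(severity_grade: int, incidence: IncidenceCategory | str,
                threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> ToxicityScore:
    """Severity grade x incidence score, with risk band and binary label.

    The severity score is the CTCAE grade itself (the two are printed as
    the same number); graded ranges must be resolved to a single integer
    upstream.
    """
    if severity_grade not in (1, 2, 3, 4):
        raise ValueError(f"severity grade must be 1-4, got {severity_grade}")
    inc = incidence_score(incidence)
    total = severity_grade * inc
    return ToxicityScore(
        severity_score=severity_grade,
        incidence_score=inc,
        total=total,
        risk_class=risk_class(total),
        reference_positive=reference_label(total, threshold),
    )


def reference_label(total: int, threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> bool:
    """Reference-positive (clinically toxic) when total >= threshold."""
    return total >= threshold


def score_drug(record: DrugRecord,
               threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> ToxicityScore:
    return total_score(record.severity_grade, record.incidence_category, threshold)


def score_panel(panel: DrugPanel,
                threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> pd.DataFrame:
    """Per-drug score table in panel order."""
    rows = []
    for r in panel.records:
        s = score_drug(r, threshold)
        rows.append({
            "drug": r.name,
            "severity_score": s.severity_score,
            "incidence_score": s.incidence_score,
            "total_score": s.total,
            "risk_class": s.risk_class,
            "reference_positive": s.reference_positive,
        })
    return pd.DataFrame(rows)


def reference_labels(panel: DrugPanel,
                     threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> dict[str, bool]:
    """drug name -> binary clinical-toxicity label."""
    return {r.name: score_drug(r, threshold).reference_positive for r in panel.records}
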