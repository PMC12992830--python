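"""Margin of safety (MOS): assay potency relative to clinical exposure.

MOS = IC value / clinical C_max, both in uM. An IC15:C_max ratio below
one flags potential clinical risk — the therapeutic plasma
concentration reaches the concentration producing an early (15%)
decrement in the assay. IC50:C_max is computed secondarily.

Right-censored ICs (">100 uM") carry no point estimate; per the
censoring policy the drug is classified nontoxic within the assay
range, even though the censored MOS lower bound (limit / C_max) can be
below the threshold. Such rows are flagged in the exposure table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .panel import Assay, CensorableConc, DrugPanel, Model

__all__ = [
    "MosResult",
    "ExposureAssessment",
    "mos",
    "mos_classify",
    "exposure_table",
]

DEFAULT_MOS_THRESHOLD = 1.0


@dataclass(frozen=True)
class MosResult:
    """An MOS ratio, or its censored lower bound when the IC is censored."""

    value: Optional[float] = None
    censored: bool = False
    lower_bound: Optional[float] = None  # limit_uM / cmax when censored


def mos(ic: CensorableConc, cmax_uM: float) -> MosResult:
    """IC / C_max in consistent uM units; censored IC -> censored MOS."""
    if not cmax_uM > 0:
        raise ValueError(f"cmax_uM must be positive, got {cmax_uM}")
    if ic.censored:
        return MosResult(censored=True, lower_bound=ic.limit_uM / cmax_uM)
    return MosResult(value=ic.value_uM / cmax_uM)


def mos_classify(result: MosResult, threshold: float = DEFAULT_MOS_THRESHOLD) -> bool:
    """Predicted toxic iff the MOS is uncensored and strictly below threshold.

    Censored MOS -> nontoxic by policy, regardless of the lower bound.
    Equality with the threshold is nontoxic (the rule is strict).
    """
    if result.censored:
        return False
    return result.value < threshold


@dataclass(frozen=True)
class ExposureAssessment:
    drug: str
    model: Model
    assay: Assay
    mos15: MosResult
    mos50: MosResult
    predicted_toxic_mos: bool


def assess(panel: DrugPanel, model: Model | str, assay: Assay | str,
           threshold: float = DEFAULT_MOS_THRESHOLD) -> list[ExposureAssessment]:
    """Per-drug MOS assessment for one model/assay combination."""
    out = []
    for s in panel.summaries_for(model, assay):
        cmax = panel.record(s.drug).cmax_uM
        m15 = mos(s.ic15, cmax)
        m50 = mos(s.ic50, cmax)
        out.append(ExposureAssessment(
            drug=s.drug, model=s.model, assay=s.assay,
            mos15=m15, mos50=m50,
            predicted_toxic_mos=mos_classify(m15, threshold),
        ))
    return out


def exposure_table(panel: DrugPanel, model: Model | str, assay: Assay | str,
                   threshold: float = DEFAULT_MOS_THRESHOLD) -> pd.DataFrame:
    """Tabular exposure report with explicit censor flags."""
    rows = []
    for a in assess(panel, model, assay, threshold):
        rows.append({
            "drug": a.drug,
            "model": a.model.value,
            "assay": a.assay.value,
            "mos15": a.mos15.value,
            "mos15_censored": a.mos15.censored,
            "mos15_lower_bound": a.mos15.lower_bound,
            "mos50": a.mos50.value,
            "mos50_censored": a.mos50.censored,
            "mos50_lower_bound": a.mos50.lower_bound,
            "predicted_toxic_mos": a.predicted_toxic_mos,
        })
    return pd.DataFrame(rows)
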