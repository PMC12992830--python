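"""Diagnostic-accuracy evaluation of assay decision rules.

Predictions from a prespecified rule (>=50% reduction at the top dose,
or MOS IC15:C_max < 1) are compared against the binary clinical
reference label (GI toxicity score >= 4). This module provides the
confusion-matrix metrics, a threshold sweep over percent-reduction
cutoffs (Youden's J and accuracy per cutoff, with the maximal-J
plateau), the rank (Mann-Whitney) AUC with DeLong 95% confidence
intervals and rank-sum p-values, and Pearson correlation analysis
between assay readouts, toxicity scores and clinical exposure.

Two AUC conventions are exposed. The headline convention applies the
rank AUC to the *binarized decisions* of a prespecified rule, which
equals the single-operating-point trapezoid (sensitivity +
specificity) / 2; the continuous convention ranks the raw percent
reductions. Both are reported by :func:`evaluate_assay`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import DEFAULT_MOS_THRESHOLD, mos, mos_classify
from .panel import Assay, DrugPanel, Model
from .scoring import DEFAULT_REFERENCE_THRESHOLD, reference_labels

__all__ = [
    "ConfusionCounts",
    "DiagnosticReport",
    "ThresholdCurve",
    "CorrelationResult",
    "EvaluationError",
    "classify_by_reduction",
    "confusion",
    "metrics",
    "rank_auc",
    "delong_ci",
    "mann_whitney_p",
    "threshold_sweep",
    "pearson_r",
    "correlation_matrix",
    "evaluate_assay",
]

DEFAULT_REDUCTION_CUTOFF = 50.0


class EvaluationError(ValueError):
    """Labels degenerate (single class) — sensitivity/specificity undefined."""


# --------------------------------------------------------------------------
# confusion counts and rates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class DiagnosticReport:
    """Rates derived from a confusion matrix, optionally with ROC results.

    Undefined rates (zero denominator) are NaN with the offending rate
    listed in ``undefined``; they are never coerced to 0 or 1.
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    youden_j: float
    undefined: list[str] = field(default_factory=list)
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    auc_degenerate: bool = False
    p_value: Optional[float] = None
    auc_continuous: Optional[float] = None
    auc_continuous_ci: Optional[tuple[float, float]] = None
    p_value_continuous: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "ppv": self.ppv, "npv": self.npv,
            "youden_j": self.youden_j,
        }
        if self.auc is not None:
            d.update(auc=self.auc, auc_ci_low=self.auc_ci[0], auc_ci_high=self.auc_ci[1],
                     p_value=self.p_value)
        if self.auc_continuous is not None:
            d.update(auc_continuous=self.auc_continuous,
                     auc_continuous_ci_low=self.auc_continuous_ci[0],
                     auc_continuous_ci_high=self.auc_continuous_ci[1],
                     p_value_continuous=self.p_value_continuous)
        return d


def classify_by_reduction(pct_reduction: float,
                          cutoff: float = DEFAULT_REDUCTION_CUTOFF) -> bool:
    """Predicted toxic iff the reduction meets the cutoff (inclusive >=)."""
    return pct_reduction >= cutoff


def _as_bool_arrays(predictions: Sequence[bool], labels: Sequence[bool]):
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have equal length")
    return pred, lab


def confusion(predictions: Sequence[bool], labels: Sequence[bool]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN of binary predictions against reference labels."""
    pred, lab = _as_bool_arrays(predictions, labels)
    if lab.all() or not lab.any():
        raise EvaluationError("labels contain a single class")
    return ConfusionCounts(
        tp=int(np.sum(pred & lab)),
        tn=int(np.sum(~pred & ~lab)),
        fp=int(np.sum(pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
    )


def metrics(counts: ConfusionCounts) -> DiagnosticReport:
    """Sensitivity, specificity, accuracy, PPV, NPV and Youden's J.

    Accuracy = (TP + TN) / (TP + TN + FP + FN); J = sensitivity +
    specificity - 1.
    """
    undefined: list[str] = []

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sens = rate(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = rate(counts.tn, counts.tn + counts.fp, "specificity")
    acc = rate(counts.tp + counts.tn, counts.n, "accuracy")
    ppv = rate(counts.tp, counts.tp + counts.fp, "ppv")
    npv = rate(counts.tn, counts.tn + counts.fn, "npv")
    return DiagnosticReport(
        counts=counts, sensitivity=sens, specificity=spec, accuracy=acc,
        ppv=ppv, npv=npv, youden_j=sens + spec - 1.0, undefined=undefined,
    )


# --------------------------------------------------------------------------
# rank AUC, DeLong CI, Mann-Whitney p
# --------------------------------------------------------------------------

def _score_label_arrays(scores, labels):
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must have equal length")
    if lab.all() or not lab.any():
        raise EvaluationError("labels contain a single class")
    return s, lab


def rank_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC with midrank tie handling.

    AUC = P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    On binary 0/1 decision scores this reduces exactly to
    (sensitivity + specificity) / 2.
    """
    s, lab = _score_label_arrays(scores, labels)
    pos, neg = s[lab], s[~lab]
    ranks = stats.rankdata(s)  # midranks
    r_pos = ranks[lab].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # one per positive
    v01 = cmp.mean(axis=0)  # one per negative
    return v10, v01


def delong_variance(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """DeLong variance estimate of the rank AUC."""
    s, lab = _score_label_arrays(scores, labels)
    v10, v01 = _delong_components(s, lab)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(scores: Sequence[float], labels: Sequence[bool],
              alpha: float = 0.05) -> tuple[float, float, bool]:
    """Normal-approximation CI for the AUC via the DeLong variance.

    Returns ``(low, high, degenerate)``; bounds are truncated to
    [0, 1]. Zero estimated variance (perfect separation or all-tied
    scores) collapses the CI to the AUC point and sets the degenerate
    flag.
    """
    auc = rank_auc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        return auc, auc, True
    z = stats.norm.ppf(1 - alpha / 2.0)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half), False


def mann_whitney_p(scores: Sequence[float], labels: Sequence[bool],
                   alternative: str = "greater") -> float:
    """Rank-sum p-value comparing positive vs negative score distributions.

    Tie-corrected normal approximation. ``alternative='greater'`` tests
    AUC > 0.5 (positives score higher), the one-sided test used against
    the chance line; 'two-sided' is also available.
    """
    s, lab = _score_label_arrays(scores, labels)
    if np.all(s == s[0]):
        return 1.0  # every score tied: no evidence of separation
    res = stats.mannwhitneyu(s[lab], s[~lab], alternative=alternative,
                             method="asymptotic")
    return float(res.pvalue)


# --------------------------------------------------------------------------
# threshold sweep
# --------------------------------------------------------------------------

@dataclass
class ThresholdCurve:
    """Youden's J and accuracy along a grid of percent-reduction cutoffs."""

    cutoffs: np.ndarray
    youden_j: np.ndarray
    accuracy: np.ndarray
    plateau: tuple[float, float]  # cutoff interval attaining max J
    max_j: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "youden_j": self.youden_j,
            "accuracy": self.accuracy,
        })


def threshold_sweep(reductions: Sequence[float], labels: Sequence[bool],
                    grid: Optional[Sequence[float]] = None) -> ThresholdCurve:
    """Evaluate the >= cutoff rule along a grid of cutoffs.

    Default grid: 0-100% in steps of 5. The plateau is the maximal
    contiguous cutoff interval whose J is within 1e-9 of the maximum.
    """
    if grid is None:
        grid = np.arange(0.0, 100.0 + 1e-9, 5.0)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("cutoff grid must be nonempty")
    red = np.asarray(reductions, dtype=float)
    js, accs = [], []
    for c in grid:
        rep = metrics(confusion(red >= c, labels))
        js.append(rep.youden_j)
        accs.append(rep.accuracy)
    js_arr = np.array(js)
    accs_arr = np.array(accs)
    max_j = float(np.nanmax(js_arr))
    at_max = np.abs(js_arr - max_j) < 1e-9
    # maximal contiguous run containing the first attaining index
    first = int(np.argmax(at_max))
    last = first
    while last + 1 < len(grid) and at_max[last + 1]:
        last += 1
    return ThresholdCurve(
        cutoffs=grid, youden_j=js_arr, accuracy=accs_arr,
        plateau=(float(grid[first]), float(grid[last])), max_j=max_j,
    )


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation, r = sum((x-xbar)(y-ybar)) / sqrt(Sxx * Syy)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(np.sum(dx * dy) / math.sqrt(sxx * syy))
    return max(-1.0, min(1.0, r))


@dataclass
class CorrelationResult:
    """Symmetric Pearson correlation matrix over panel-level variables."""

    variables: list[str]
    matrix: pd.DataFrame

    def entry(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


def correlation_matrix(panel: DrugPanel,
                       threshold: int = DEFAULT_REFERENCE_THRESHOLD) -> CorrelationResult:
    """Pairwise Pearson r over the four assay reductions, score and C_max."""
    from .scoring import score_drug

    columns: dict[str, list[float]] = {}
    for model in (Model.HIEC, Model.CACO2):
        for assay in (Assay.TEER, Assay.ATP):
            name = f"{model.value} {assay.value}"
            by_drug = {s.drug: s.pct_reduction
                       for s in panel.summaries_for(model, assay)}
            columns[name] = [by_drug[r.name] for r in panel.records]
    columns["GI toxicity score"] = [float(score_drug(r).total) for r in panel.records]
    columns["Cmax"] = [r.cmax_uM for r in panel.records]

    names = list(columns)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = pearson_r(columns[a], columns[b])
            mat.loc[a, b] = mat.loc[b, a] = r
    return CorrelationResult(variables=names, matrix=mat)


# --------------------------------------------------------------------------
# end-to-end rule evaluation
# --------------------------------------------------------------------------

RULES = ("reduction_cutoff", "mos15", "mos50")


def evaluate_assay(panel: DrugPanel, model: Model | str, assay: Assay | str,
                   rule: str = "reduction_cutoff", *,
                   cutoff: float = DEFAULT_REDUCTION_CUTOFF,
                   mos_threshold: float = DEFAULT_MOS_THRESHOLD,
                   label_threshold: int = DEFAULT_REFERENCE_THRESHOLD,
                   alpha: float = 0.05) -> DiagnosticReport:
    """Full diagnostic report for one rule on one model/assay combination.

    Reference labels come from the clinical toxicity scores; predictions
    from the chosen rule. The report carries the confusion-matrix rates,
    the binarized-decision AUC with DeLong CI and one-sided rank-sum p
    (the headline convention), and — for the reduction rule — the same
    for the continuous percent-reduction predictor.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    labels_by_drug = reference_labels(panel, label_threshold)
    summaries = panel.summaries_for(model, assay)
    if len(summaries) != len(panel.records):
        have = {s.drug for s in summaries}
        missing = [r.name for r in panel.records if r.name not in have]
        raise ValueError(f"panel lacks {Model(model).value}/{Assay(assay).value} "
                         f"summaries for: {missing}")
    labels = [labels_by_drug[s.drug] for s in summaries]

    continuous: Optional[list[float]] = None
    if rule == "reduction_cutoff":
        predictions = [classify_by_reduction(s.pct_reduction, cutoff) for s in summaries]
        continuous = [s.pct_reduction for s in summaries]
    else:
        which = "ic15" if rule == "mos15" else "ic50"
        predictions = [
            mos_classify(mos(getattr(s, which), panel.record(s.drug).cmax_uM),
                         mos_threshold)
            for s in summaries
        ]

    report = metrics(confusion(predictions, labels))
    decisions = [1.0 if p else 0.0 for p in predictions]
    report.auc = rank_auc(decisions, labels)
    lo, hi, degen = delong_ci(decisions, labels, alpha)
    report.auc_ci = (lo, hi)
    report.auc_degenerate = degen
    report.p_value = mann_whitney_p(decisions, labels)
    if continuous is not None:
        report.auc_continuous = rank_auc(continuous, labels)
        lo, hi, _ = delong_ci(continuous, labels, alpha)
        report.auc_continuous_ci = (lo, hi)
        report.p_value_continuous = mann_whitney_p(continuous, labels)
    return report
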