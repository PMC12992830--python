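"""Synthetic dose-response series and drug panels with known ground truth.

The generator emulates the study's assay design: six-point dose grid
{0, 1, 5, 10, 50, 100} uM, four replicates per dose, baseline TEER
drawn from the model-specific window (hIEC 80-240 Ohm*cm2, Caco-2
400-1000 Ohm*cm2), and replicate readouts scattered around a true 4PL
curve with multiplicative Gaussian noise (TEER and ATP measurement
error scales with signal size). Toxic drugs carry deep response drops
(low log_ic, low bottom); nontoxic drugs barely respond within the
tested range, so their ICs censor at 100 uM. Severity/incidence
annotations and synthetic C_max values are assigned consistently with
the ground-truth label, making the panels usable end to end through
scoring, exposure and diagnostic evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dose_response import (DEFAULT_DOSE_GRID_UM, DoseResponseSeries,
                            FourPLFit, four_pl, summarize_series)
from .panel import (Assay, AssaySummary, DrugClass, DrugPanel, DrugRecord,
                    IncidenceCategory, Model, Route)

__all__ = [
    "SyntheticPanelConfig",
    "TrueParamRanges",
    "BASELINE_TEER_WINDOWS",
    "generate_series",
    "generate_panel",
]

#: baseline (vehicle) TEER windows in Ohm*cm2 per epithelium model;
#: ATP baselines use an arbitrary-luminescence window instead
BASELINE_TEER_WINDOWS = {
    Model.HIEC: (80.0, 240.0),
    Model.CACO2: (400.0, 1000.0),
}
BASELINE_ATP_WINDOW = (5e4, 2e5)


@dataclass(frozen=True)
class TrueParamRanges:
    """Uniform sampling ranges for the true 4PL parameters of one class."""

    top: tuple[float, float] = (95.0, 105.0)
    bottom: tuple[float, float] = (0.0, 15.0)
    hill: tuple[float, float] = (0.8, 2.0)
    log_ic: tuple[float, float] = (0.3, 1.2)

    def draw(self, rng: np.random.Generator) -> FourPLFit:
        return FourPLFit(
            top=float(rng.uniform(*self.top)),
            bottom=float(rng.uniform(*self.bottom)),
            hill_slope=float(rng.uniform(*self.hill)),
            log_ic=float(rng.uniform(*self.log_ic)),
        )


#: deep drop well inside the tested range -> reduction >> 50%, IC15/IC50 finite
TOXIC_RANGES = TrueParamRanges()
#: shallow drop: curve stays near control within 100 uM -> censored ICs
NONTOXIC_RANGES = TrueParamRanges(bottom=(88.0, 99.0), log_ic=(1.5, 3.5))


@dataclass
class SyntheticPanelConfig:
    """Study-design parameters for panel simulation.

    Defaults mirror the reference study conditions: 12 toxic and 5
    nontoxic drugs, six-dose grid, four replicates, 5% multiplicative
    noise. The seed is mandatory; all draws flow from one generator.
    """

    n_toxic: int = 12
    n_nontoxic: int = 5
    seed: int = 0
    doses_uM: tuple[float, ...] = DEFAULT_DOSE_GRID_UM
    n_replicates: int = 4
    noise_cv: float = 0.05  # multiplicative Gaussian sigma as fraction of signal
    toxic_ranges: TrueParamRanges = field(default_factory=lambda: TOXIC_RANGES)
    nontoxic_ranges: TrueParamRanges = field(default_factory=lambda: NONTOXIC_RANGES)
    models: tuple[Model, ...] = (Model.HIEC, Model.CACO2)
    assays: tuple[Assay, ...] = (Assay.TEER, Assay.ATP)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _baseline(model: Model, assay: Assay, rng: np.random.Generator) -> float:
    lo, hi = BASELINE_TEER_WINDOWS[model] if assay == Assay.TEER else BASELINE_ATP_WINDOW
    return float(rng.uniform(lo, hi))


def generate_series(true_params: FourPLFit, config: SyntheticPanelConfig,
                    *, drug: str = "synthetic", model: Model = Model.HIEC,
                    assay: Assay = Assay.TEER,
                    rng: Optional[np.random.Generator] = None) -> DoseResponseSeries:
    """Simulate replicate readouts around a known 4PL curve.

    Raw units: the % -of-control curve is scaled by a baseline drawn
    from the model's TEER window (or the ATP luminescence window), then
    each replicate is perturbed multiplicatively, response * (1 + eps)
    with eps ~ N(0, noise_cv^2). Deterministic for a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    baseline = _baseline(model, assay, rng)
    responses = []
    for dose in config.doses_uM:
        if dose == 0:
            mean_pct = 100.0
        else:
            mean_pct = float(four_pl(np.log10(dose), true_params.top,
                                     true_params.bottom, true_params.hill_slope,
                                     true_params.log_ic))
        raw = baseline * mean_pct / 100.0
        eps = rng.normal(0.0, config.noise_cv, size=config.n_replicates)
        responses.append(raw * (1.0 + eps))
    return DoseResponseSeries(drug=drug, model=model, assay=assay,
                              doses_uM=config.doses_uM, responses=responses)


def _annotations(toxic: bool, rng: np.random.Generator):
    """Severity/incidence consistent with the label, plus a synthetic C_max."""
    if toxic:
        # products >= 4: moderate/high risk
        grade = int(rng.integers(2, 5))
        choices = (IncidenceCategory.COMMON, IncidenceCategory.VERY_COMMON)
        cmax = float(rng.uniform(0.5, 50.0))
    else:
        grade = 1
        choices = (IncidenceCategory.UNCOMMON, IncidenceCategory.COMMON)
        cmax = float(rng.uniform(1.0, 300.0))
    return grade, choices[int(rng.integers(len(choices)))], cmax


def generate_panel(config: SyntheticPanelConfig) -> tuple[DrugPanel, dict[str, bool]]:
    """Simulate a full panel and return it with its ground-truth labels.

    Each drug gets one true parameter set per model x assay combination
    (drawn from its class ranges), simulated series, and summaries
    derived through the real fitting pipeline (4PL fit, IC
    interpolation with censoring at the top dose, percent reduction).
    Returns ``(panel, truth)`` where ``truth`` maps drug name to the
    ground-truth toxic label.
    """
    if config.n_toxic < 2 or config.n_nontoxic < 2:
        raise ValueError("need >=2 drugs per ground-truth class for evaluation")
    rng = np.random.default_rng(config.seed)
    records, summaries = [], []
    truth: dict[str, bool] = {}
    specs = [(f"tox{i:02d}", True) for i in range(config.n_toxic)]
    specs += [(f"ref{i:02d}", False) for i in range(config.n_nontoxic)]
    for name, toxic in specs:
        grade, incidence, cmax = _annotations(toxic, rng)
        records.append(DrugRecord(
            name=name,
            drug_class=DrugClass.CELL_CYCLE_INHIBITOR if toxic else DrugClass.NSAID,
            severity_grade=grade, incidence_category=incidence,
            cmax_uM=cmax, route=Route.UNSPECIFIED,
        ))
        truth[name] = toxic
        ranges = config.toxic_ranges if toxic else config.nontoxic_ranges
        for model in config.models:
            for assay in config.assays:
                params = ranges.draw(rng)
                series = generate_series(params, config, drug=name,
                                         model=model, assay=assay, rng=rng)
                summary, _fit = summarize_series(series)
                summaries.append(summary)
    return DrugPanel(records=records, summaries=summaries), truth
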