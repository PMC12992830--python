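"""Dose-response normalization, 4PL fitting and IC interpolation.

The concentration-response model is the four-parameter logistic (4PL)
in log10-dose:

    y(x) = bottom + (top - bottom) / (1 + 10^((x - log_ic) * hill))

with x = log10(dose in uM). With ``hill > 0`` the curve decreases from
``top`` at low dose to ``bottom`` at high dose, the direction of a
toxic response; this is the mirror-image sign convention of the
GraphPad-style parameterization 10^((log_ic - x) * hill), whose Hill
slope would be negative for the same curve. ``log_ic`` is the log10
dose of the curve midpoint; when top = 100 and bottom = 0 it is the
log IC50.

ICx values (IC15, IC50) are interpolated from the fitted curve as the
dose where the prediction crosses the residual level (85% resp. 50% of
vehicle control). If the curve never reaches the level within the
tested range the IC is right-censored at the top tested dose
(reported ">100 uM" on the default grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .panel import Assay, CensorableConc, Model

__all__ = [
    "DoseResponseSeries",
    "FourPLFit",
    "FitBounds",
    "DEFAULT_BOUNDS",
    "InsufficientDataError",
    "four_pl",
    "normalize_to_control",
    "percent_reduction",
    "fit_4pl",
    "interpolate_ic",
]

#: tested concentration grid, uM (vehicle plus five drug doses)
DEFAULT_DOSE_GRID_UM = (0.0, 1.0, 5.0, 10.0, 50.0, 100.0)

#: fitted |top - bottom| below this (% of control) means the drug produced
#: no interpretable response window; both ICs are censored
NONINFORMATIVE_SPAN_PCT = 5.0


class InsufficientDataError(ValueError):
    """Too few usable doses to fit a dose-response curve."""


def four_pl(x: np.ndarray | float, top: float, bottom: float,
            hill: float, log_ic: float) -> np.ndarray | float:
    """Evaluate the 4PL at log10-dose ``x`` (decreasing for hill > 0)."""
    return bottom + (top - bottom) / (1.0 + np.power(10.0, (np.asarray(x, dtype=float) - log_ic) * hill))


def normalize_to_control(responses: Sequence[float] | np.ndarray,
                         control_mean: float) -> np.ndarray:
    """Scale raw readouts so the vehicle-control mean maps to 100%."""
    if not control_mean > 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return np.asarray(responses, dtype=float) / control_mean * 100.0


def percent_reduction(control_value: float, value_at_top_dose: float) -> float:
    """(control - value at top dose) / control x 100.

    Signed: negative when the treated readout exceeds the control
    (e.g. NSAID-induced TEER increases).
    """
    if not control_value > 0:
        raise ValueError(f"control value must be positive, got {control_value}")
    return (control_value - value_at_top_dose) / control_value * 100.0


@dataclass
class DoseResponseSeries:
    """Replicate readouts on the dose grid for one drug x model x assay.

    ``responses[i]`` holds the replicates at ``doses_uM[i]``; the grid
    must start with the vehicle (dose 0), which anchors normalization
    but is excluded from the log-dose fit.
    """

    drug: str
    model: Model
    assay: Assay
    doses_uM: tuple[float, ...]
    responses: list[np.ndarray]

    def __post_init__(self) -> None:
        self.doses_uM = tuple(float(d) for d in self.doses_uM)
        self.responses = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.responses]
        if len(self.doses_uM) != len(self.responses):
            raise ValueError("one replicate set per dose required")
        if 0.0 not in self.doses_uM:
            raise ValueError("vehicle dose (0) is required")
        if any(b <= a for a, b in zip(self.doses_uM, self.doses_uM[1:])):
            raise ValueError("doses must be strictly increasing")
        if sum(d > 0 for d in self.doses_uM) < 2:
            raise ValueError("at least 2 non-vehicle doses required")

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.responses[self.doses_uM.index(0.0)]))

    def normalized(self) -> "DoseResponseSeries":
        """Return a copy with all replicates as % of the vehicle mean."""
        c = self.control_mean
        return DoseResponseSeries(
            drug=self.drug, model=self.model, assay=self.assay,
            doses_uM=self.doses_uM,
            responses=[normalize_to_control(r, c) for r in self.responses],
        )

    def top_dose_uM(self) -> float:
        return self.doses_uM[-1]

    def pct_reduction(self) -> float:
        """Percent reduction at the top tested dose, on replicate means."""
        top_mean = float(np.mean(self.responses[-1]))
        return percent_reduction(self.control_mean, top_mean)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the 4PL optimizer (percent-of-control scale)."""

    top: tuple[float, float] = (80.0, 120.0)
    bottom: tuple[float, float] = (-10.0, 100.0)
    hill: tuple[float, float] = (0.1, 10.0)
    log_ic: tuple[float, float] = (-3.0, 4.0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.top[0], self.bottom[0], self.hill[0], self.log_ic[0]])
        hi = np.array([self.top[1], self.bottom[1], self.hill[1], self.log_ic[1]])
        return lo, hi


DEFAULT_BOUNDS = FitBounds()


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with diagnostics."""

    top: float
    bottom: float
    hill_slope: float
    log_ic: float
    residual_sse: float = 0.0
    converged: bool = True
    noninformative: bool = False

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, dose_uM: np.ndarray | float) -> np.ndarray | float:
        dose = np.asarray(dose_uM, dtype=float)
        return four_pl(np.log10(dose), self.top, self.bottom, self.hill_slope, self.log_ic)


def _initial_guess(x: np.ndarray, y: np.ndarray, bounds: FitBounds) -> np.ndarray:
    top = float(np.clip(np.max(y), *bounds.top))
    bottom = float(np.clip(np.min(y), *bounds.bottom))
    mid = (np.max(y) + np.min(y)) / 2.0
    log_ic = float(np.clip(x[np.argmin(np.abs(y - mid))], *bounds.log_ic))
    hill = float(np.clip(1.0, *bounds.hill))
    return np.array([top, bottom, hill, log_ic])


def fit_4pl(series: DoseResponseSeries,
            bounds: FitBounds = DEFAULT_BOUNDS,
            start: Optional[Sequence[float]] = None,
            *, on_means: bool = True) -> FourPLFit:
    """Least-squares 4PL fit on normalized responses.

    The vehicle (dose 0) has no log-dose coordinate: it is used only to
    normalize, and the curve is fitted to the non-vehicle doses. By
    default the fit is on per-dose replicate means (``on_means=False``
    fits all replicates). Fits whose response window ``|top - bottom|``
    is below ``NONINFORMATIVE_SPAN_PCT`` are flagged non-informative and
    downstream IC interpolation censors them.
    """
    norm = series.normalized()
    xs, ys = [], []
    for dose, reps in zip(norm.doses_uM, norm.responses):
        if dose <= 0:
            continue
        if on_means:
            xs.append(math.log10(dose))
            ys.append(float(np.mean(reps)))
        else:
            xs.extend([math.log10(dose)] * len(reps))
            ys.extend(float(v) for v in reps)
    x = np.array(xs)
    y = np.array(ys)
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("need >=2 distinct non-vehicle doses")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")

    p0 = np.asarray(start, dtype=float) if start is not None else _initial_guess(x, y, bounds)
    lo, hi = bounds.as_arrays()
    p0 = np.clip(p0, lo, hi)

    def residuals(p: np.ndarray) -> np.ndarray:
        return four_pl(x, *p) - y

    sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf")
    top, bottom, hill, log_ic = (float(v) for v in sol.x)
    sse = float(np.sum(sol.fun ** 2))
    fit = FourPLFit(
        top=top, bottom=bottom, hill_slope=hill, log_ic=log_ic,
        residual_sse=sse, converged=bool(sol.success),
        noninformative=abs(top - bottom) < NONINFORMATIVE_SPAN_PCT,
    )
    return fit


def interpolate_ic(fit: FourPLFit, level_pct: float,
                   max_dose_uM: float = 100.0, *,
                   span_relative: bool = False) -> CensorableConc:
    """Dose at which the fitted curve crosses ``level_pct`` % of control.

    ``level_pct`` is the residual response level on the absolute
    percent-of-control scale: IC15 corresponds to level 85 (a 15%
    decrement from vehicle control), IC50 to level 50. With
    ``span_relative=True`` the level is instead read as percent of the
    fitted top-bottom window (level 85 = bottom + 0.85 * span), for
    workflows that define ICx on the curve span rather than the control
    anchor. Closed-form inversion of the 4PL; if the curve never
    reaches the level within (0, max_dose_uM] — including
    non-informative fits and levels outside the fitted (bottom, top)
    window — the result is right-censored at ``max_dose_uM``, never an
    exception.
    """
    if not 0 < level_pct < 100:
        raise ValueError(f"level must be in (0, 100), got {level_pct}")
    censored = CensorableConc(censored=True, limit_uM=max_dose_uM)
    if fit.noninformative or not fit.converged:
        return censored
    top, bottom = fit.top, fit.bottom
    if span_relative:
        level_pct = bottom + (level_pct / 100.0) * (top - bottom)
    if not (bottom < level_pct < top):
        return censored
    # level = bottom + span / (1 + 10^((x - log_ic) h))  =>
    # x = log_ic + log10((top - level)/(level - bottom)) / h
    ratio = (top - level_pct) / (level_pct - bottom)
    x = fit.log_ic + math.log10(ratio) / fit.hill_slope
    dose = 10.0 ** x
    if not (0 < dose <= max_dose_uM) or not math.isfinite(dose):
        return censored
    return CensorableConc(value_uM=dose, limit_uM=max_dose_uM)


def summarize_series(series: DoseResponseSeries,
                     bounds: FitBounds = DEFAULT_BOUNDS,
                     max_dose_uM: Optional[float] = None):
    """Fit a series and derive (IC15, IC50, percent reduction).

    Convenience wrapper returning the pieces an :class:`AssaySummary`
    needs; ``max_dose_uM`` defaults to the series' top tested dose.
    """
    from .panel import AssaySummary

    if max_dose_uM is None:
        max_dose_uM = series.top_dose_uM()
    fit = fit_4pl(series, bounds=bounds)
    return AssaySummary(
        drug=series.drug, model=series.model, assay=series.assay,
        ic15=interpolate_ic(fit, 85.0, max_dose_uM),
        ic50=interpolate_ic(fit, 50.0, max_dose_uM),
        pct_reduction=series.pct_reduction(),
    ), fit
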