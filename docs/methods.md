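# Methods

## Problem and model

`barriertox` evaluates how well in vitro intestinal epithelial assays
predict clinical gastrointestinal (GI) toxicity. Two epithelium models
(stem-cell-derived hIEC monolayers and the Caco-2 line) are each read
out two ways — transepithelial electrical resistance (TEER, barrier
integrity, Ω·cm²) and ATP luminescence (viability) — after 96 h of drug
exposure on a six-point grid: 0 (vehicle), 1, 5, 10, 50 and 100 µM,
four replicates per dose.

Concentration–response is modeled by the four-parameter logistic in
log10 dose,

    y(x) = bottom + (top − bottom) / (1 + 10^((x − log_ic)·h)),

where y is percent of vehicle control, x = log10(dose/µM), and h > 0
gives the decreasing (inhibitory) direction. This is the mirror-image
sign convention of the GraphPad-style form 10^((log_ic − x)·h); the
curves are identical with h negated. `log_ic` is the midpoint log dose
(the log IC50 when top = 100, bottom = 0).

From a fit, ICx values invert the curve in closed form: IC15 is the
dose where y = 85 (a 15 % decrement from control, the early-damage
marker), IC50 where y = 50. Levels are absolute percent-of-control by
default; a span-relative variant (level measured on the fitted
top–bottom window) is available via `interpolate_ic(...,
span_relative=True)` for workflows that define ICx on the curve span.
If the curve never reaches the level inside (0, 100 µM], the IC is
right-censored and reported ">100 µM"; censored drugs are treated as
nontoxic within the assay range and never excluded silently — censor
flags propagate into every output table.

Drug effect at the top dose is summarized as

    % reduction = (control − value at 100 µM) / control × 100,

signed, so readouts above control (e.g. NSAID-induced TEER increases)
give negative reductions. The statistic is invariant to the raw unit
scale, so it can be computed on raw or normalized values.

## Clinical reference and decision rules

Each drug's clinical GI toxicity is scored as CTCAE v5.0 severity
grade (1–4) × incidence score (uncommon 1, common 2, very common 3),
total 1–12, banded low (≤3) / moderate (4–8) / high (≥9). The binary
reference label is total ≥ 4. Two prespecified prediction rules are
evaluated:

* **Reduction rule** — predicted toxic iff percent reduction ≥ 50 %
  (inclusive) at 100 µM.
* **MOS rule** — margin of safety MOS = IC / C_max; predicted toxic
  iff IC15:C_max < 1 (strict). Censored ICs classify nontoxic by
  policy even when the censored lower bound limit/C_max is below 1
  (ibuprofen, bound ≈ 0.69); such rows are flagged. IC50:C_max is
  computed secondarily.

## Diagnostics

Confusion-matrix rates use the standard definitions; accuracy =
(TP+TN)/n and Youden's J = sensitivity + specificity − 1. Undefined
rates (zero denominators) are reported as NaN and named in the report,
never coerced.

The AUC is the Mann–Whitney rank statistic with midrank ties. Two
conventions are reported side by side: the headline AUC ranks the
*binarized decisions* of a prespecified rule — algebraically the
single-operating-point trapezoid (sensitivity + specificity)/2 — and
the secondary AUC ranks the continuous percent reductions. Confidence
intervals use the DeLong structural-components variance with a normal
approximation, truncated to [0, 1]; zero estimated variance (perfect
separation or all-tied scores) collapses the CI to the point estimate
and sets a degenerate flag. Significance against AUC = 0.5 uses the
tie-corrected asymptotic Mann–Whitney U test, one-sided by default.
No multiple-testing adjustment is applied; p-values are reported as
computed, one per assay/rule.

The threshold sweep evaluates the reduction rule on a cutoff grid
(default 0–100 % in steps of 5) and reports the maximal contiguous
plateau of cutoffs whose J is within 1e−9 of the maximum. Pearson
correlations implement the textbook two-pass formula and are assembled
into a symmetric matrix over the four assay reductions, the toxicity
score and C_max.

## Fitting: numerical choices

Fits minimize the SSE of the 4PL on per-dose replicate means (an
all-replicates option exists) with `scipy.optimize.least_squares`
(trust-region reflective) inside the box top ∈ [80, 120], bottom ∈
[−10, 100], h ∈ [0.1, 10], log_ic ∈ [−3, 4] — bounds that stabilize
the optimizer on six-point grids. All assays here measure decay, so
only the decreasing direction of h is searched. The vehicle dose has
no log coordinate; it anchors normalization (control mean → 100 %) and
is excluded from the fit. Initial guess: top = max response, bottom =
min response, h = 1, log_ic = the dose nearest the half-window
crossing, all clipped to the box. A fitted window |top − bottom| < 5
percentage points is flagged non-informative and both ICs censor —
there is no interpretable response to invert.

On noise-free six-point data the fit recovers generating parameters to
better than 1e−6; the closed-form IC inversion agrees with a bisection
oracle to 1e−9 relative error (both are enforced by tests).

## Synthetic data generator

`synthetic.generate_panel` emulates the study design: 12 toxic + 5
nontoxic drugs by default, the six-point grid, four replicates,
baseline TEER drawn uniformly from the model windows (hIEC 80–240
Ω·cm²; Caco-2 400–1000 Ω·cm², the lower printed bound of the reported
~400–1,200 range), and multiplicative Gaussian noise, response × (1 +
ε), ε ~ N(0, σ²) with σ = 5 % by default — measurement error in both
readouts scales with signal. ATP baselines use an arbitrary
luminescence window (5×10⁴–2×10⁵); normalization removes the unit.
Toxic drugs draw deep curves (bottom 0–15 %, log_ic 0.3–1.2), nontoxic
drugs shallow ones (bottom 88–99 %, log_ic 1.5–3.5) whose ICs censor
by construction. Severity/incidence annotations and synthetic C_max
values are drawn consistently with the label, so generated panels run
end to end.

What the generator does *not* emulate: time-course TEER trajectories
(only the 96-h endpoint), replicate-to-replicate plate effects,
heteroscedastic floor noise at near-zero ATP signal, correlated errors
across the four model × assay combinations, and mechanistic
drug-class differences. Passing recovery tests therefore demonstrate
the pipeline's correctness and its behavior under idealized
multiplicative noise, not assay performance on real monolayers.

## Scales used in stochastic validation

DeLong CI coverage is checked by a seeded binormal experiment (true
AUC 0.8, 100 positives + 100 negatives, 1,000 replicates; observed
coverage ≈ 0.95). Synthetic label recovery runs 100 seeded panels
(17 drugs each, hIEC TEER) through the full fit → IC → reduction →
classify pipeline. These sizes keep the whole suite under a minute
while leaving Monte-Carlo error well below the asserted margins.

## Known limitations

* The printed IC15/IC50/reduction table is the authoritative input for
  the evaluation stage; the paper-of-record's raw readouts are not
  deposited, so curve fitting is validated on synthetic data only.
* The lumen-surrogate margin of safety for oral agents is not
  implemented: no formula for the surrogate luminal concentration is
  available, and guessing one would change classifications silently.
* C_max is taken as a single point value per drug; clinical exposure
  variability (median/IQR across studies) is out of scope.
* Exact figure-legend CI bounds and p-values depend on estimator
  variants for binary predictors; the package reproduces the CI
  truncation behavior and significance verdicts, not those digits.
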