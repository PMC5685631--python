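# Methods

This note documents the statistical machinery in `beadcal`, the choices
made where the design was open, and what the synthetic test bed does and
does not establish.

## Models and fitting space

All fitting, residual analysis, bands and LOQ work happen in the doubly
log-transformed plane `(x, y) = (log10 concentration, log10 MFI)`.  Raw
MFIs from bead readers are strongly heteroscedastic — the variance grows
with the mean — and the log10 transform approximately stabilizes it, so
an unweighted least-squares criterion is reasonable in that space.
Conversion back to natural units happens only at the reporting boundary
(`conc = 10**x_hat`, `y0 = 10**a0`).

Three mean functions are available:

* **LL5** (five-parameter log-logistic):
  `f(x) = c + (d - c) / (1 + 10^{b(x-e)})^f`.  `c` and `d` are the lower
  and upper asymptotes in log10-MFI units, `e` is the log10
  concentration at the halfway response, `b` the slope around `e`, and
  `f > 0` the asymmetry that lets the curve approach its two asymptotes
  at different rates.
* **LL4**: the same with `f = 1` (symmetric sigmoid).
* **EXP**: `y = a0 + b·x`, i.e. `MFI = y0·10^{x·b}` — the fallback for
  curves that never reach their upper asymptote within the standards'
  concentration range.  The exponent is read as the *product* `x·b`
  (`b` a growth rate per log10-concentration unit); the alternative
  `x/b` reading would make `b` a scale rather than a rate, which does
  not match calling `b` a growth rate.  The reading is fixed and the
  parameter is named a rate in the API.

Sign convention: under this parameterization an *increasing* curve has
`b < 0`, because `10^{b(x-e)} → 0` as `x → ∞`.  The package never flips
signs silently; summaries report `b` as estimated.

Derivatives in `x` (orders 1–3) and the gradient in the parameters are
closed-form.  Writing `u = 10^{b(x-e)}` and `L = ln 10`, the chain rule
`d/dx = bLu·d/du` gives for the LL5 core `(1+u)^{-f}`:

* order 1: `-(d-c) f bL u (1+u)^{-f-1}`
* order 2: `-(d-c) f (bL)^2 u (1+u)^{-f-2} (1 - fu)`
* order 3: `-(d-c) f (bL)^3 u (1+u)^{-f-3} (1 - (3f+1)u + f^2 u^2)`

The quadratic factor in the third derivative has two positive roots for
every `f > 0`; for `f = 1` they are `u = 2 ± √3`, i.e.
`x = e ± log10(2+√3)/|b|` — the closed form the test suite uses as an
independent oracle for the derivative-based LOQ.

## Background (blank-control) treatments

The blank wells' geometric mean `GM` (geometric, because blank MFIs are
approximately lognormal) feeds one of four treatments: **ignore** (left
tail approaches the background on its own), **subtract** (`mfi - GM`
before the log; wells driven to zero or below are excluded with the
reason recorded, since their log is undefined), **include** (the GM
appended as a pseudo-standard at the smallest expected concentration
divided by the serial-dilution factor), and **constraint** (the lower
asymptote — `c`, or `a0` for EXP — fixed at `log10 GM` and removed from
the free parameter set, shrinking the covariance by one dimension).
The dilution factor, when not supplied, is inferred as the median ratio
of consecutive distinct sorted expected concentrations; this assumes a
serial-dilution design, which is how standards are laid out in practice.

## Optimization

Nonlinear least squares uses Levenberg–Marquardt
(`scipy.optimize.least_squares`, `xtol = ftol = gtol = 1e-10`, iteration
cap configurable, default 200).  Self-start values: `c0`/`d0` just
outside the observed response range (±5% of the span), `f0 = 1`, and
`b0`, `e0` from a logit linearization — regressing
`log10((d0-y)/(y-c0))` on `x` is exact for an LL4 with known asymptotes,
so its slope and `-intercept/slope` are good starts.  Models are tried
in order (default LL5 → LL4 → EXP) and the first that converges *and*
lands in the valid parameter domain (`c < d`, `f > 0`) wins; every
attempt is logged.  A run where nothing converges returns a fit object
with `converged = False` and the attempt log rather than raising, so
batch processing keeps its provenance.

The parameter covariance is `σ²(JᵀJ)⁺` with `σ² = RSS/(n-p)` and `J`
the Jacobian at the optimum (pseudo-inverse guards near-singular
designs).  Standardized residuals are `r/σ`; when `σ < 1e-8` (an
essentially exact fit) they are reported as zero rather than as `0/0`
round-off artifacts.

## Fit diagnostics

`R²` is computed on log10 MFI (`1 - RSS/TSS`), with the adjusted version
alongside.  AIC uses the Gaussian likelihood with the residual variance
counted as a parameter: `n ln 2π + n ln(RSS/n) + n + 2(p+1)` — the
convention under which a tiny linear fit's AIC can be reproduced by hand
and compared across implementations.

The lack-of-fit (Neill) test partitions the fit's RSS into pure error
(within groups of replicated `x`) and lack of fit:
`F = (SS_lof/(m-p)) / (SS_pe/(n-m))` on `F(m-p, n-m)`.  The default
grouping is by identical expected concentration — replicated dilutions
supply pure error; if the grouping is degenerate (no replicates, or `m`
outside `(p, n)`) the result carries an `undefined` status instead of a
guessed grouping.  The F reference is exact for linear models and
approximate for these nonlinear ones; its empirical size at α = 0.05 on
model-true duplicated-dilution plates is measured by the acceptance
script (≈ 0.03–0.06 at n = 34).

## Bands and inverse prediction

The delta-method SE of the fitted mean at `x` is `√(gᵀΣg)` with `g` the
parameter gradient restricted to free parameters.  Confidence band:
`ŷ ± t_{df,1-α/2}·se`; prediction band: the same with `√(σ² + se²)`, so
it contains the confidence band wherever `σ > 0`.

Inverse prediction differentiates `f(x̂; θ) = y` implicitly:
`∂x̂/∂θ = -g(x̂)/f'(x̂)`, hence `Var(x̂) = gᵀΣg / f'(x̂)²`.  By default the
SE is conditional on the observed MFI (parameter uncertainty only); a
flag adds the response-noise term `σ²/f'(x̂)²` for wells that carry
fresh measurement noise.  When `|f'(x̂)|` falls below `1e-10` (asymptote
region) the SE is reported infinite rather than astronomically large.
The natural-scale CV of an inverse-predicted concentration follows the
lognormal identity `CV = √(exp((SE·ln10)²) - 1)`.

## LOQ estimators

* **Derivative**: the bend points of the sigmoid — roots of the third
  derivative, bracketed by sign changes on a 1,000-point grid over the
  standards' `x` range extended by two dilution steps (widened
  geometrically if the roots lie outside) and polished with Brent's
  method.  Not applicable to EXP (third derivative ≡ 0).  For LL4 the
  limits are exactly `e ± log10(2+√3)/|b|`.
* **Interval**: LLOQ where the lower prediction bound crosses the upper
  confidence limit of `ĉ`; HLOQ where the upper prediction bound crosses
  the lower confidence limit of `d̂` (for a decreasing curve the two
  bounds swap roles).  Under the constraint background the fixed
  asymptote's CI collapses to a point.  Roots are searched over the
  standard range extended by one dilution step; with multiple crossings
  the one closest to `e` is kept — the conservative (inner) choice.  No
  crossing, or an inestimable asymptote CI, yields `not-estimable`.
* **CV**: over the same 1,000-point grid, each grid concentration's
  fitted response is inverse-predicted back with its delta-method SE and
  converted to a CV; the LOQs are the extreme grid points with
  CV ≤ cutoff (default 0.20; 0.30 is also common in practice).  If the
  minimum CV exceeds the cutoff the status is `not-estimable` and the
  minimum is reported.  CV is strictly increasing in SE, so shrinking
  parameter uncertainty monotonically widens this dynamic range.

LOQs are estimated per plate and analyte, never pooled: curve shape and
variability differ between plates, and that plate-specific variability
is precisely what the limits should reflect.  Values are carried in
log10 units with natural-scale convenience accessors.

## Calibration of test wells

A test MFI is moved into the curve's response space exactly as the
standards were (subtract subtracts the blank GM; the other treatments
leave it untouched — the curve and the samples must live in the same
space), then inverted.  Every well gets exactly one status from
{quantified, below-lloq, above-hloq, below-curve-range,
above-curve-range, not-invertible, missing-fit}; batch calibration emits
one output row per input row with no silent drops.

## QC

Outliers are wells with `|standardized residual| >` a cutoff (default
2.0, configurable).  Removal is one flag-and-refit cycle driven by the
analyst: the workflow preserves both the original and the refitted
curve, renders flagged wells as empty circles in the plots, and reports
— without acting on — any new exceedances after the refit.  Automatic
iterative deletion is deliberately absent: repeated culling against a
data-estimated σ inflates the apparent precision of the curve.

`intra_icc` exposes the Shrout–Fleiss ICC family (one-/two-way ANOVA,
consistency/agreement, single/average unit) for replicate reliability
across operators or runs; the ANOVA decomposition and F-based CI are
delegated to `pingouin.intraclass_corr`, with complete-case row
dropping.  No variant is privileged.

## Synthetic plates

The generator emulates the standard-curve design the fitting code is
meant for: 16 serial 1:2 dilutions from a top concentration of 1000,
top dilution duplicated (17 designed wells), two blank wells, 4PL truth
on log10 MFI with Gaussian noise, optional missing wells and designated
outlier wells.  Defaults: `b = -1.2, c = 1.1, d = 3.2, e = 0.9`,
noise SD 0.05 log10-MFI units, blank MFIs lognormal around `10^c` with
log10-SD 0.05 — a mid-quality cytokine-like curve whose lower asymptote
sits at the background level, as the blank-treatment heuristics assume.
Four presets cover the canonical multiplexed-panel scenarios: a clean
full curve; a 10-point curve (7 missing); a 10-point curve with one
outlier; a full curve with two outliers.

A designated outlier's noise is drawn from the inflated distribution
`N(0, 2·sd)` *conditioned on exceeding twice that inflated SD* in
magnitude.  An unconditioned inflated draw is frequently small, which
would make "this well is an outlier" a label rather than a property;
with the conditioning, roughly 70% of two-outlier plates show at least
one exceedance at the standard cutoff, the rest being absorbed by the
fit — detection remains genuinely stochastic.

What the synthetic bed does **not** emulate: bead-count–dependent MFI
precision, plate-position effects, carry-over, analyte cross-reactivity,
or inter-plate drift.  Tests passing on it establish the correctness of
the estimators under the stated noise model, not the behaviour of any
particular assay.

## Raw-export parsing

The fluorescence-type parser treats any line starting with `DataType:`
as a block delimiter, keeps unknown block names generically, sniffs
comma vs semicolon delimiters, tolerates a UTF-8 BOM, and is
quote-aware (well locations like `"1(1,A1)"` embed the delimiter).
Over-long lines are collected with their line numbers, never silently
dropped.  Expected concentrations are never read from the raw export —
instrument exports do not carry them reliably — and always come from a
user-supplied dilution map.

## Problem sizes

The statistical studies run at sizes chosen to give stable Monte-Carlo
estimates while staying interactive: 200 plates for parameter
recovery/coverage, 500 replicates for the lack-of-fit size, 2,000
parameter draws for the bootstrap cross-check of the delta-method SE.

## Known limitations

* No weighted or robust regression; the log10 transform is the only
  variance treatment.
* LODs (detection limits from blank distributions) are out of scope.
* The Neill grouping requires replicated dilutions; designs without
  replicates get an `undefined` status, not a fallback partition.
* The interval method depends on the prediction band's delta-method
  approximation, which degrades for strongly curved small-n fits.
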