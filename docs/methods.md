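# Methods

## Model

A sealed vial of total volume `V` holds `V_sol` of spiked aqueous solution
and `V_hs = V − V_sol` of headspace; `r = V_hs / V_sol`. At equilibrium the
partition law `c_hs = Kaw·c_sol` and mass balance
`c0·V_sol = c_sol·V_sol + c_hs·V_hs` give

```
c_sol = c0 / (1 + Kaw·r)        area(r) = A0 / (1 + Kaw·r),  A0 = RF·c0
```

where RF is the (unknown) LC–MS response factor. Only the product `RF·c0`
is identifiable, so the fit estimates the pair (A0, Kaw). Assumptions: ideal
dilute behavior (the carrier cosolvent stays ≤0.1 v/v %, where its effect on
solubility is negligible), full equilibration before sampling, no losses to
walls, lids or the air–water interface, and an RF that does not vary across
the vial series measured in one batch.

Temperature dependence follows a Van't Hoff-type law at constant system
volume, `ln Kaw = −ΔU/(R·T) + const`, with ΔU (kJ/mol) treated as
temperature-independent over the fitted range (the regression R² > 0.97
typical for these chemicals supports this over 40–80 °C). ΔU is the
internal-energy analogue of the enthalpy of volatilization appropriate to a
sealed, constant-volume vial. `R = 8.3145 J mol⁻¹ K⁻¹`; Celsius/Kelvin
conversions add 273.15 exactly, and 25 °C is 298.15 K.

## Direct estimation

`HeadspaceKawModel` fits replicate-level areas (not group means) by weighted
nonlinear least squares, minimizing `Σ wᵢ (areaᵢ − A0/(1+Kaw·rᵢ))²` with
`wᵢ = areaᵢ^(−p)`:

- **Weighting exponent `p`**: default 2 (weights 1/y²), i.e. constant
  *relative* error — the natural choice for multiplicative LC–MS noise and
  the conventional relative-weighting option of curve-fitting software.
  `p ∈ {0, 1, 2}` is exposed because practice varies.
- **Optimizer**: Levenberg–Marquardt (scipy `curve_fit`) started from the
  linearized form (1/area is linear in r), which is accurate enough that
  convergence failures are rare. A failed optimizer or a negative Kaw
  estimate is reported with `converged=False` rather than clamped or
  bounded: a negative point estimate is itself the diagnostic for "Kaw too
  low to determine at this temperature".
- **CIs**: Wald intervals from the WLS covariance (scaled by reduced
  chi-square) with a Student-t quantile at n−2 df. Empirically the nominal
  95% interval covers the true Kaw ~95% of the time under the synthetic
  study conditions below.
- **R²** is computed unweighted on the raw areas, matching how goodness of
  fit for this model is usually quoted.
- **Reportability**: a log10 Kaw with CI is quoted only when the fit
  converged and both the estimate and the lower CI bound are positive.

### Triplicate quality rule

Replicates sharing a ratio form a group with mean and relative standard
deviation (RSD). A group is excluded when its RSD is **≥** the smallest
relative deviation between its mean and the means of its adjacent (vicinal)
ratio groups, with the pair-mean denominator
`|mᵢ−mⱼ| / ((mᵢ+mⱼ)/2)`; terminal groups have one neighbour. Rationale: if
replicate scatter exceeds the signal step to the neighbouring ratio, the
point carries no shape information. Decisions are made in one pass over the
original groups (no re-evaluation after exclusions); ties are excluded. Two
readings were open — which neighbour and which denominator — and this
implementation uses both neighbours (taking the minimum deviation) and the
pair mean, the most conservative symmetric reading. The rule operates on
group means only; the fit always uses the surviving replicate-level points.
A practical consequence: for nearly flat signals (Kaw·r ≪ RSD at every
ratio) the rule can exclude almost everything, and the per-temperature fit
is then skipped and logged — which is the correct outcome, since such data
cannot constrain Kaw anyway.

## Indirect estimation

`VantHoffModel` regresses the ln of the per-temperature Kaw point estimates
on 1/T, by default unweighted OLS over the 40–80 °C fits only (the target
temperature is excluded because it is the value under extrapolation; the
subset is configurable). Optional inverse-variance weighting uses
delta-method variances of ln Kaw. Slope CIs use t quantiles at n−2 df; ΔU
and its CI are the exact linear map `−R·slope/1000` (endpoints swap order).
Extrapolation to a target temperature reports the regression line at 1/T
with the confidence band of the regression *mean* there, converted to
log10; evaluation outside the fitted 1/T range is permitted and flagged.
Fitting point estimates rather than replicate-level values means the slope
CI reflects between-temperature scatter only, so it is typically narrower
than one computed from raw replicates.

## Comparisons and classification

Structural contrasts are absolute differences of log10 Kaw point estimates
per shared condition (per temperature and per 25 °C method), summarized by
mean and max. Experiment-vs-prediction deltas are signed
(experimental − predicted). OECD 309 indicative volatility classes use
log10 Kaw thresholds −3.39 and −1.39; the outer classes take strict
inequalities, so boundary values fall in the semivolatile class. The
pipeline classifies on the indirect 25 °C estimate because it exists for
every chemical, including those whose direct 25 °C fit is not reportable.
Out-of-domain in-silico predictions are included but flagged.

## Synthetic studies

`simulate_study` emulates the experimental design: 20 mL vials filled with
1, 2, 5, 10, 15, 18 mL in triplicate at 25, 40, 50, 60, 70, 80 °C (all
configurable). Per chemical, truth is (ΔU, log10 Kaw at 298.15 K); the
default truths used throughout the tests (ΔU = 23.8 kJ/mol,
log10 Kaw = −1.09; and 37.4 / −2.64 for the low-volatility case) sit at the
two ends of the measured range for the fluorinated alcohols this method was
developed on. Expected areas follow the depletion curve with amplitude
A0 = 10⁶ signal units (arbitrary, since RF is never known); noise is
**mean-one multiplicative lognormal** parameterized by the CV of the area,
default 2% — chosen as a realistic replicate-level repeatability for
UHPLC-MS peak areas, consistent with the 1/y² weighting, and producing CI
widths of the magnitude seen in practice. Loss artifacts:

- `constant_fraction f`: every vial loses the fraction f (wall/lid sorption
  of the dissolved fraction; f = 0.31 emulates a measured 31% loss). It
  scales the whole curve, biasing A0 by (1−f) while leaving Kaw untouched —
  the estimator depends only on the shape in r.
- `ratio_dependent (f_max, r_half)`: loss `f_max·r/(r+r_half)`, a
  saturating surrogate for air–water interface sorption (no functional form
  is established; saturation reflects a finite interface). This distorts
  the shape, biasing Kaw and degrading R² — the qualitative signature used
  to recognize and dismiss sorption-compromised chemicals.

What the generator does *not* emulate: equilibration kinetics, carryover,
RF drift between vials, interference at high temperature, heteroscedastic
baseline noise at very low signal. Passing recovery tests therefore shows
the estimator chain is correct and calibrated under its own error model,
not that real measurements meet that model.

## Verification problem sizes

The recovery and coverage properties are measured over 200 seeded synthetic
studies (seeds 1–200) of one chemical at CV 2% with the full
6-temperature × 6-ratio × triplicate design — 1200 nonlinear fits — chosen
as the smallest campaign that pins empirical coverage to within a few
percent; it completes in seconds. Observed under these conditions: CI
coverage ≈ 0.95 (required ≥ 0.90), median |ΔU error| ≈ 0.35 kJ/mol
(required ≤ 2), median indirect-25 °C error well under 0.05 log units. The
weighted-NLS optimum is cross-checked against an independent brute-force
grid search refined below 1e−6 resolution, and against a 2000×2000 fixed
grid spanning four decades. One numerical note: doubling the noise CV
scales the median CI width by ≈1.99 rather than exactly ≥2, because the
lognormal sigma `√ln(1+cv²)` is marginally sublinear in cv; the test
asserts ≥1.9.

## Numerical choices and edge cases

- Water density for gravimetric vial calibration uses the Kell (1975)
  polynomial for air-free water at 1 atm (coefficients in
  `kawfit.partition`), valid 0–100 °C; air saturation shifts density by
  ~2 ppm, far below the 4th significant digit that matters here.
- Volumes are mL internally; ratios are unit-free so the choice is visible
  only at I/O. Temperatures are °C in files and CLI, K internally.
- `fit_kaw` requires ≥3 points spanning ≥2 distinct ratios; all-equal
  ratios raise an unidentifiability error.
- Reports are plain JSON-serializable dicts; serialization sorts keys and
  carries no timestamps, so identical inputs give byte-identical reports.
  The shipped `report_schema.json` is enforced by a small structural
  validator (type/required/properties/items/enum/nullable subset).

## Known limitations

- No correction for wall/lid or interfacial sorption — chemicals with
  appreciable sorption need different methods; the simulator can only mimic
  the resulting bias signatures.
- Wald CIs can undercover for barely identifiable fits (Kaw·r ≲ noise);
  such fits usually fail the reportability bar instead. Profile-likelihood
  intervals are not implemented.
- The indirect method inherits the constant-ΔU assumption; extrapolating
  far beyond the fitted temperature range is flagged but not prevented.
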