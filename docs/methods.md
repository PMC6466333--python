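# Methods

This note documents the models implemented in `fertrisk`, the packaged
parameters, the synthetic-survey generator, the numerical conventions,
and the design choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and data model

The package operates on *concentration tables*: per-sample measurements
of Cr, Ni, Cu, Zn, As, Cd and Pb in organic fertilizer, in mg/kg dry
weight (As is a metalloid but treated identically). Three survey regions
(`north`, `northwest`, `northeast`, with 48/55/14 samples) have packaged
parameter rows; `northern` denotes their pooled aggregate. The raw
per-sample survey data are not available, so the package ships the
regional summary statistics (range, mean, median, SD, CV) and a
generator that emulates them (below).

## Soil accumulation

Each application year adds a constant flux to a homogeneous 20 cm plow
layer:

* `Q_p = IR_f · α / (ρ_b · V)` — mg metal per kg soil per year, with
  `IR_f` the application rate (t·hm⁻²·yr⁻¹), `α` the fertilizer
  concentration (mg/kg DW; the survey median for deterministic tables),
  `ρ_b` the bulk density (g/cm³) and `V = 2000` m³/hm² the plow-layer
  volume. The t→kg factor cancels between fertilizer mass and soil mass.
* `Q(n) = Q_0 + n·Q_p` — no loss terms. Leaching, runoff, crop uptake
  and atmospheric deposition are outside the model, so accumulation is
  slightly overestimated; a per-year loss fraction would be a natural
  extension hook.
* `T = (C_s − Q_0)/Q_p` — years to the agricultural soil limit `C_s`
  (GB15618-2018, dry land at pH > 7.5: Cr 250, Ni 190, Cu 100, Zn 300,
  As 25, Cd 0.6, Pb 170 mg/kg). `Q_p = 0` gives `T = +∞`; a background
  at or above the limit gives `T = 0` with an `already_exceeding` flag.

Times are reported unrounded and rounded (half-up) to the nearest year.
Rounded times are always computed from the *unrounded* flux: chaining
the 2-decimal printed flux changes e.g. the north-region Cr time by
almost two decades, which the test suite demonstrates.

### Pooled-region aggregation

The pooled `northern` parameters are sample-size-weighted means
(48/55/14) of the regional soil backgrounds and bulk densities, and the
unweighted arithmetic mean of the three application rates. The weights
are overridable (`load_region_parameters("northern", weights=...)`).
This convention reproduces the pooled accumulation results for the
fast-accumulating metals (Zn, Cd, As) and the pooled dose/risk totals;
for slowly accumulating metals small (~1 %) residuals against other
plausible aggregations remain, which is why only the robust pooled
quantities (the minimum time, HI, TCR) are anchored in tests.

## Monte Carlo time-to-limit

`mc_time_to_limit` propagates the fitted per-metal concentration
distribution through the closed form: per iteration, draw α, form `Q_p`
and `T`, then summarize quantiles (default 5/50/95 %) and optional
threshold probabilities `P(T ≤ horizon)`. Because `T` is a strictly
decreasing function of α, the median of the simulated `T` equals the
deterministic `T` evaluated at the distribution median — an analytic
oracle the tests exercise, alongside the exact point-mass identity at
CV = 0 and the draw-for-draw scaling law in `IR_f`. Draws follow the
untruncated fitted lognormal by default (`SimulationConfig.
truncate_to_range` restores hard bounds); truncating at the observed
survey extremes would bias the induced time distribution and break the
median identity precisely for the metals whose observed maximum lies
close to the median. `n_iterations` defaults to 10⁵, which bounds the
Monte Carlo error of the reported medians well inside one year.

## Synthetic survey generator

The generator exists so every downstream stage is testable without the
undeposited raw samples. Each regional summary rejects normality and has
mean ≫ median wherever variability is substantial, so the default family
is a lognormal parameterized directly by the published median and CV:

    location = ln(median)      spread² = ln(1 + (CV/100)²)

The median pins the location exactly and the CV pins the spread exactly
(the lognormal CV depends only on the spread), so parameter recovery at
n = 10⁴ (median within ±5 %, CV within ±10 %) holds by construction up
to sampling noise, for every regional spec — the suite verifies all 28.

Draws are **not** hard-bounded to the published observed range by
default. The observed extremes describe the finite survey, not the
population, and the two halves of the published summary are mutually
inconsistent as joint constraints: a distribution supported on `[a, b]`
with a fixed median has a capped CV, and for several metals the
published CV exceeds that cap (for the northeast Zn row the cap is
about 94 % against a published 117 %). Rejection-sampling truncation —
resampling rejected draws rather than clipping, so no probability mass
accumulates at the bounds — remains available behind an explicit
`truncate` flag, with an error when the range carries essentially no
mass under the fitted distribution.

An `empirical` family (resampling user-supplied values) is available as
a robustness alternative. Metals are generated independently by
default; a Gaussian copula with a user-supplied rank-correlation matrix
(`rank_correlation=`) imposes inter-metal Spearman structure when the
correlation stage itself is under test. What passing tests show is that
the pipeline handles right-skewed, normality-rejecting survey data with
the published location/scale structure; they do not show robustness to
features the generator omits — inter-metal correlation (by default),
censored values below detection limits, or manure-type mixtures within
a region.

## Survey statistics

* `summarize`: sample SD with the n−1 denominator; CV = 100·SD/mean;
  Shapiro–Wilk on the raw concentrations (reported absent for n < 3 or
  constant columns, where the statistic is undefined).
* `spearman_matrix`: midrank ties; two-sided p-values from the exact
  permutation distribution for n ≤ 10 (vectorized enumeration of all
  n! orderings) and the t approximation above; pairs with a constant
  column are undefined and reported absent; the diagonal is exactly 1.
  Requires n ≥ 4.
* `exceedance_rates`: a sample exceeds only when strictly above the
  limit — standards phrase limits as "maximum acceptable
  concentrations", so a sample exactly at the limit complies. Metals a
  jurisdiction does not regulate are flagged, never counted as zero
  limits. `merge_limits` composes standards first-match-wins per metal
  (the survey's screening convention: Chinese organic-fertilizer limits
  for Cr/As/Cd/Pb backed by German class-I limits for Ni/Cu/Zn).

## Exposure and risk

Doses are linear in the soil concentration `Q_i`; the exposure
constants model an adult farm population (ingestion 100 mg/day,
250 day/yr over 25 yr, body weight 56.8 kg, lifetime 26 280 days, skin
1.614 m² with 18 % exposed and 0.2 mg/cm² adherence, particulates
0.15 mg/m³ at 14.5 m³/day with outdoor/indoor soil-particle fractions
0.8/0.5 over 87.5/262.5 day/yr). The dermal surface is converted
m² → cm² before the adherence factor; the 10⁻⁶ converts mg soil to kg.

Two coefficient conventions are implemented side by side:

* `as_written` — route-specific absorption: gastrointestinal β orally,
  skin γ dermally, lung θ for inhalation (θ = 1.00 assumed for Cr and
  As, for which no measured lung value is available);
* `as_published` (default) — the gastrointestinal β in all three
  routes. This is the convention under which the reference risk tables
  the suite anchors against are reproducible cell by cell; for a given
  metal the two modes differ by the exact factors γ/β (dermal) and θ/β
  (respiratory), which the tests assert.

Risk exposure uses `Q_i = Q_0 + years·Q_p` with `years = 1` by default
(a config knob), i.e. the soil state after a single application year.
HQ/HI use route-specific reference doses; CR/TCR use slope factors for
the four carcinogens Cr, Ni, As, Cd only. The qualitative grade is a
4×4 matrix lookup over right-closed HI bands (0.25/0.50/0.75/1.00; an
HI above 1 clamps into the extreme band and is flagged) and TCR bands
(10⁻⁶/10⁻⁵, with ≥ 10⁻⁴ extreme).

`years_to_hi_threshold` exploits the affinity of HI in the year count:
`n = (threshold − HI(Q_0)) / Σ_i u_i·Q_p,i`, with `u_i` the per-unit-Qi
hazard quotient. It is validated against an independent year-stepping
oracle rather than any external figure; projections of this kind are
sensitive to the assumed coefficient mode and dose growth, and the
package makes both explicit.

## Numerical conventions and degenerate inputs

* Half-up rounding for reported years (`floor(x + 0.5)`), avoiding
  banker's rounding surprises at `.5`.
* `Q_0 + T·Q_p = C_s` holds to machine precision for every finite
  deterministic `T` (property-tested).
* Dose/HQ/CR linearity in `Q_i` and the exact additive decomposition of
  HI and TCR are property-tested at machine precision.
* Degenerate inputs are encoded in results, not exceptions: infinite
  times for zero flux, `already_exceeding` flags, absent statistics for
  constant columns; validation errors (negative concentrations,
  unknown regions/jurisdictions, malformed CSVs) raise with the
  offending row or the list of valid names.
* CSV outputs carry `# key: value` comment headers (version, seed,
  config hash, excluding the output path) so a run is auditable and
  reproducible from its files alone.

## Problem sizes

Deterministic table reproductions are closed-form (milliseconds). The
test suite uses 10⁴-draw generator-recovery checks, 10⁵-draw Monte
Carlo medians, 40-seed normality-rejection frequencies and ≤ 8-sample
exact permutation tests; `scripts/acceptance.py` runs one 10⁵-draw
simulation. These sizes put the sampling error of every asserted
quantity well inside the asserted tolerance.

## Known limitations

* No loss terms in the accumulation model (overestimates accumulation);
  single homogeneous plow layer per region.
* Adult receptors only; no dietary/food-chain exposure, no child
  parameters, no As speciation.
* The standards registry is a frozen snapshot; limits change.
* The generator emulates marginal summaries, not the full joint
  distribution of a real survey (see above).
* Pooled-region aggregation is a convention, not a measurement; only
  robust pooled quantities are asserted.
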