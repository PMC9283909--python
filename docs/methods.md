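# Methods

This note records the models, conventions and open design choices behind
`airdense`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or the acceptance script do
not themselves compute.

## 1. Hourly QC

**Completeness.** For each station × pollutant, completeness is the number
of non-missing hours divided by the number of hours in the full study
window (hours absent from the input file count as missing). Inclusion uses
a closed bound (≥ 0.75 by default): a series at exactly the threshold is
kept. Completeness is assessed on the *raw* panel, before outlier removal,
since removal itself depends on which stations are included. Inclusion is
per station × pollutant; a `station_level=True` switch reproduces
whole-station exclusion (a station failing for any pollutant is dropped
for all).

**Modified Z-score.** Z is computed per station × pollutant × calendar
year over observed hours. The SD convention is the sample SD (ddof = 1);
`sd_ddof=0` switches to the population convention. A year with fewer than
2 observed hours or zero SD yields missing Z there, with a warning — a
constant series cannot be standardized, and hours without a defined Z are
never flagged.

**The four conditions.** The detector evaluates, per observed hour,

- z1: |Zₜ| > 4
- z2: |Zₜ − Zₜ₋₁| > 6
- z3: |Zₜ / RM3(Z)ₜ| > 1.5
- z4: |ΔZₜ| / |mean over the other included stations of ΔZₜ| > 2

and removes the hour when **all four** hold (`rule="any"` is available).
Conventions that the printed one-line rendering of such rules typically
leaves ambiguous were resolved as follows:

- **Absolute values.** z2–z4 use |·|; negative spikes are physically
  symmetric to positive ones (a `one_sided=True` switch reproduces the
  literal signed reading).
- **z3 is a ratio.** RM3 is the *centered* 3-point running median over
  observed hours (gaps skipped, not interpolated); at a series endpoint
  the median of the 2 available points is used. When |RM3| < 10⁻⁶ the
  ratio is replaced by |Zₜ| > 1.5, so a spike against a flat background
  cannot escape by zero-division; the same guard logic applies to the z4
  denominator (|ΔZ| > 2 when the city-wide change is numerically zero).
- **Differences restart at year boundaries.** Z is standardized per year,
  so ΔZ across a year boundary would mix scales; z2 and z4 are false at
  the first observed hour of each series-year.
- **City-wide denominator.** The z4 denominator averages ΔZ over the
  *other* completeness-included stations reporting that pollutant-hour.
  With fewer than 2 included stations z4 is undefined, warned about, and
  treated false.
- **Single pass.** Z is computed once and flags applied once; the cleaning
  is not iterated to convergence. Re-running the cleaner on its own output
  can in principle flag further hours (Z is re-estimated from the cleaned
  data); one pass is the documented procedure.

The conjunction rule is deliberately conservative: in synthetic panels
with injected spikes, only spikes large and sharp enough to satisfy all
four conditions simultaneously are removed, and a fraction of injected
anomalies survives. That is the intended behaviour of the rule, not a
defect of the implementation, and the test suite checks the detector
against an independently coded loop oracle rather than against the
injection list.

## 2. Exposure assignment

Annual means are arithmetic means of observed hours per station-year on
the cleaned panel. For a participant, pollutant and year, the estimate is
inverse-distance-weighted over the **3 nearest included stations**
(wᵢ ∝ dᵢ⁻ᵖ, p = 2 by default; the method's power is not fixed by common
usage, so it is exposed as configuration). A participant within 10⁻⁹ km of
a station receives that station's value exactly. Ties in distance are
broken by station id, making results independent of input row order.

Home/work blending uses a weekly time budget: h_work = reported weekly
work hours, h_home = 168 − h_work. This is the simplest defensible
closure; field practice only records work hours, not a full time-activity
diary, and whether the original analysis blended or substituted locations
is unknowable from a narrative description. The 3-year exposure is the
unweighted mean of the three yearly estimates (rather than IDW of 3-year
station means) so that year-specific station inclusion is respected;
the difference is second-order when inclusion is stable.

Geometry is planar km (Euclidean) for synthetic data; geographic mode uses
haversine with Earth radius 6371.0 km. Cohort years absent from the panel
raise a hard error rather than silently truncating the averaging window.

## 3. Statistical analysis

- **Dichotomization.** BI-RADS a, b → low; c, d → high. Analyses use the
  first rater's reading; the second rater exists to quantify agreement.
- **Cohen's κ** is unweighted on the 4-category scale, with the
  large-sample asymptotic SE and normal-quantile CI (statsmodels supplies
  the variance computation; a hand-formula check is in the tests).
- **Univariable screens** use the two-sided t-test (2 groups) or one-way
  ANOVA (4 BI-RADS categories) for continuous variables and the Pearson
  chi-square **without** continuity correction for categorical ones — the
  uncorrected test is what reproduces the reference p-value (0.016) on
  the smoking 2×2 used as a frozen check; Yates' correction gives ≈ 0.022.
- **Logistic models** are ML fits (statsmodels `Logit`) with Wald CIs,
  exp(β ± 1.96·SE). Perfect separation and non-convergence raise typed
  errors; no silent estimates. Complete-case analysis for missing values.
- **Stepwise** is forward selection with backward pruning on
  likelihood-ratio p-values, entry 0.05 / removal 0.10 — the common
  statistical-package default family; the procedure's direction and
  thresholds are rarely reported, so they are configuration. With
  p_enter = p_remove = 1 the full candidate set is reproduced, which the
  tests use as a consistency check. A candidate whose design is singular
  in a given step simply cannot enter.
- **Confounder models.** Model 1 = retained pollutants; Model 2 adds age,
  BMI, smoking, OCP history, menopause, parity and breast-disease
  history; Model 3 adds metformin, aspirin, vitamin D and calcium.
- **Moderator analysis** fits the adjusted model per stratum and tests all
  exposure × stratum interactions jointly by likelihood ratio in the
  pooled model. Age as a moderator is dichotomized at the cohort median
  by default.
- **Sample size** derives p₁ from p₀ and the assumed OR
  (p₁ = OR·p₀/(1 + p₀(OR − 1))), applies the two-sided normal
  approximation and reports both the uncorrected and the
  continuity-corrected (Fleiss/Casagrande–Pike–Smith) totals, the
  corrected one as headline — that is the default family of the classic
  Epi Info-style calculators.

## 4. Synthetic data: what it emulates, and what not

**Panels.** Each station × pollutant series is a shared city-wide signal
(seasonal + diurnal sinusoids; O3 peaks in summer, the others in winter)
plus a station-level offset (N(0, offset SD)) and iid Gaussian noise,
floored at 0. Missingness is Bernoulli per hour; outliers are single-hour
replacements at baseline ± m·SD (default m = 8), recorded in a truth
table. Single-hour spikes match what the four conditions target (Zₜ vs
Zₜ₋₁, 3-point median); level shifts and drifts are deliberately absent.
Default baselines (PM2.5 30 µg/m³, PM10 80 µg/m³, NO2 40 ppb, SO2 8 ppb,
O3 25 ppb, CO 2.5 ppm) are typical annual levels for a large polluted
city. Not emulated: meteorology, spatial covariance beyond the shared
signal, instrument drift, cross-pollutant chemistry.

**Cohorts.** Home points are uniform over the network square. Exposure
surfaces are random sinusoid fields with a shared latent component
(pairwise correlation ≈ 0.3–0.4 across pollutants) and per-pollutant
spreads around realistic between-subject SDs — enough inter-correlation
to exercise the collinearity rationale for stepwise selection, far from
the degenerate identical-surface case. Covariate marginals approximate a
screening population (age ≈ 50 ± 7.6, BMI ≈ 28, ~50% postmenopausal,
~10% smoking exposure, ~11% employed). The outcome is Bernoulli with
P(high) = expit(β₀ + Σβ_p·exposure + Σβ_c·covariate); default true odds
ratios are NO2 1.039 per ppb and CO 0.331 per ppm (the two signals the
multi-pollutant stepwise model is meant to retain), other pollutants
null, and the covariate defaults are the fully adjusted model's
estimates. β₀ defaults to the value that calibrates mean prevalence to
62.2% given the realized linear predictor (an explicit intercept can be
supplied instead; the printed constant of a fitted model is not portable
across exposure distributions). Rater 1 reads the true class; rater 2
disagrees at a configurable rate (default 2%) and only into an *adjacent*
BI-RADS category, which reproduces the near-perfect κ regime of two
expert readers.

A green parameter-recovery test therefore establishes that the estimation
chain is unbiased **under the generator's assumptions** — correctly
specified logistic outcome, exposure known at the home point, no
residual spatial confounding. It does not validate exposure-measurement
error, address-history gaps, or selection effects in a real screening
population.

## 5. Parameter recovery and the acceptance script

`airdense.validation.recovery_run` generates a pollutants-only cohort
(covariate effects zero, so the pollutants-only refit is correctly
specified — logistic odds ratios are non-collapsible, and leaving true
covariate effects in the generator while fitting without them would bias
the comparison) at n = 50,000 and refits the six-candidate stepwise
model. `recovery_summary` repeats this over seeds and reports mean
recovered ORs and retention fractions. `scripts/acceptance.py` runs one
such replicate from a user seed and writes the recovered per-ppm CO odds
ratio.

## 6. Numerical choices and degenerate inputs

- Guards: 10⁻⁶ for the z3/z4 denominators, 10⁻⁹ km for the IDW exact hit.
- IDW weights always sum to 1 by construction; all-missing neighbor sets
  yield NaN, never 0.
- κ is undefined when both raters are constant and identical (p_e = 1):
  typed error.
- Intercept calibration solves a 1-D root with Brent's method on the mean
  inverse-logit; the bracket is widened by the linear predictor's range.
- All generators take integer seeds and are deterministic (numpy
  `default_rng`); derived sub-seeds stay below 2³¹.

## 7. Known limitations

- The QC detector's conjunction rule has low sensitivity by design;
  users wanting aggressive cleaning should use `rule="any"` knowingly.
- Exposure assignment ignores address changes within a year and assumes
  the recorded home/work split is stable across the 3 years.
- The stepwise procedure inherits the usual post-selection inference
  caveats; reported CIs for selected terms are conditional on selection.
- The synthetic cohort draws covariates independently of each other and
  of location, so confounding structure in real data (e.g. age–menopause
  dependence, deprivation–pollution correlation) is not represented.
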