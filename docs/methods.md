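# Methods

This note records the demographic model behind `lifegap`, the conventions and
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Abridged period life tables

Each stratum (race/ethnicity × gender × urbanicity × 5-year period) supplies
central death rates m_x = D_x / N_x on the fixed 19-interval grid
[0,1), [1,5), [5,10), …, [80,85), [85,∞). D_x are pooled deaths and N_x
pooled person-years; period person-years are the *sum* of the five midyear
populations (the standard period-exposure convention; summing versus
averaging ×5 is immaterial for rates but matters if absolute counts are
reported).

Conversion to death probabilities uses the Greville/Chiang relation
q_x = n·m_x / (1 + (n − a_x)·m_x), clipped to 1. Separation factors a_x
(years lived in the interval by those dying in it):

| interval | a_x | why |
|---|---|---|
| [0,1) | 0.1 (configurable) | conventional low-mortality infant value; deaths cluster near birth |
| [1,5) | 1.5 | early-childhood deaths skew young |
| other closed | n/2 | midpoint rule |
| 85+ | 1/m_85+ | constant-hazard closure, so e_85 = 1/m_85+ |

An m₀-dependent infant rule can be emulated by passing a different `a0`;
nothing downstream assumes 0.1. The survivorship recursion runs from radix
l₀ = 100,000 in double precision with no internal rounding; presentation
rounding (1 decimal for years, 2 for ratios/CVs) exists only in the report
layer behind `round_output`.

Under the accounting L_x = n·l_{x+n} + a_x·d_x (open: L = l/m), the discrete
death distribution with mass d_x at age x + a_x satisfies
Σ d_x·(x + a_x)/l₀ = e₀ *exactly* (a telescoping identity), so the variation
measures below are centred on a quantity consistent with the life table
itself. The test suite asserts this to 1e−9 relative tolerance, and radix
conservation Σ d_x = l₀ to 1e−6.

## Lifespan variation

σ_y is the standard deviation of age at death among survivors to exact age
y: the discrete distribution {d_x/l_y at x + a_x, x ≥ y}, centred at its own
mean (equal to y + e_y by the identity above — centring on the weighted mean
keeps the variance non-negative even for an inconsistent user-supplied
table). CV_y = σ_y / e_y by default; normalization by total mean age at
death y + e_y is available (`normalize="total"`). The two coincide at birth;
the remaining-life normalization is the one that makes CV at older ages a
statement about *remaining* lifetime uncertainty.

**Open-interval treatment.** A point mass at 85 + a_open would discard all
dispersion inside the open group. That is negligible when few survive to 85
but badly biased for low-mortality schedules: with 60–70% of the cohort
surviving to 85 (attained by the lowest-mortality strata here), the
point-mass convention understates σ₀ by ~5–10%, and a plain exponential tail
(the naive counterpart of the constant-hazard closure) overstates it by a
similar margin because the true senescent hazard keeps rising. We therefore
model remaining life in the open group as a Gompertz variable whose mean is
pinned to the life table's own closure value a_open = 1/m_open and whose
slope β is estimated from the log-growth of the last two closed intervals'
rates (per year of age, floored at 0). The tail's coefficient of variation
κ(β/m_open) is tabulated once from the normalized Gompertz family — κ(0) = 1
recovers the exponential exactly, so a flat old-age schedule reproduces the
constant-hazard oracle — and the variance gains d_open/l_y·(κ·a_open)².
Against 10⁶-lifetime simulations over 50 random human schedules
(e₀ ∈ [45, 90]) this keeps σ₀ within 0.7% of truth, versus errors up to 12%
for either naive convention. Closed intervals remain point masses; their
within-interval spread contributes under ~0.5% to σ₀ and is ignored.

## Uncertainty

A parametric Poisson bootstrap: D*_x ~ Poisson(D_x) with exposures fixed,
full life-table recomputation per replicate, SE = replicate standard
deviation, bounds = 2.5/97.5 percentiles (percentile rather than normal
intervals because CV replicates skew in small strata). Default 1000
replicates; fewer than 100 is refused. Replicates drawing zero open-interval
deaths cannot close a table and are redrawn (logged, capped). Replicate
computation is vectorized over a (reps × 19) rate matrix, so a bootstrap
call costs milliseconds. Empirical coverage of the 95% interval for e₀,
measured over 100 simulated datasets × 1000 replicates at ~26,000 deaths per
dataset, sits at 92–96%.

Per-stratum bootstrap seeds derive from the run's root seed via
`SeedSequence(root, spawn_key=crc32(stratum_key))`, so adding or removing
strata never reshuffles the draws of others.

## Inequality measures

Absolute inequality: metropolitan value − nonmetropolitan value for the same
race-gender group and measure; relative inequality: their ratio. Range gap:
max − min across race groups within a gender × urbanicity × period cell,
ties broken by the fixed race-label order (H, NHW, NHB, NHAPI) with a logged
flag. Trend change: gap(earlier) − gap(later), reported as "narrowed by"
when positive. Cross-measure association: Pearson correlation. All
comparisons use unrounded values; the report layer rounds for display only.

## The synthetic generator

The generating hazard is Siler: h(t) = a₁e^(−b₁t) + c + a₂e^(b₂t) —
infant decay, constant background, Gompertz senescence — which produces the
infant hump and old-age acceleration the abridged grid is designed around.
Defaults (a₁ = 0.02, b₁ = 2.5, c = 3e−4, a₂ = 1.2e−5, b₂ = 0.106) anchor the
baseline to circa-1990 US low-risk mortality: e₀ ≈ 79, infant death
probability ≈ 0.8%.

Group structure is proportional on the whole hazard. Default multipliers
emulate the familiar US orderings — Asian/Pacific Islander advantage (0.55),
Hispanic advantage (0.82), White reference (1.0), Black disadvantage (1.45);
male disadvantage (1.45, ≈5 years of e₀); a rural gradient from large-fringe
advantage (0.95) to noncore penalty (1.16) — and a 1%/yr hazard decline
(improvement factor 0.99 per calendar year since the first study year). With
these, 2015–2019 group e₀ spans ≈72 (Black noncore men) to ≈88
(Asian/Pacific Islander metro women), matching the magnitude of the real
inequalities the pipeline is meant to resolve. Race population shares
default to 0.61/0.18/0.13/0.08 (NHW/H/NHB/NHAPI).

County exposures are log-normal around a configurable scale (σ = 0.5), split
across ages by the stationary-population structure (L_x/T₀) of the group's
first-year schedule and held constant over calendar time; deaths are Poisson
with mean m_x·N_x. Expected interval rates come from fine-step integration
(step 0.01 yr) of hazard·survival over each interval, the open interval
integrating to where survival < 1e−10.

**Ground truth.** The truth table reports e₀/σ₀/CV₀ of the *abridged-grid*
life table built from the exact expected pooled period rates — the estimand
of the pipeline — at the 6-level and 2-level urbanicity resolutions plus
race-pooled rows, with 2-level and pooled rates formed by exact
exposure-weighting. The moments of the continuous hazard itself are exposed
separately (`continuous_moments`) and are verified against 10⁶ simulated
exact lifetimes (mean within 0.05 yr). Keeping the two notions distinct lets
the recovery tests isolate sampling error (estimate vs abridged truth,
within 0.1 yr / 0.005 at county populations ~10⁷) from discretization error
(abridged vs continuous, within 1% for e₀).

**What the generator does not emulate**: migration, spatial correlation
between counties, cohort effects, cause-of-death structure, age
misreporting, census denominator error, or within-group heterogeneity beyond
the proportional-hazards differentials. Passing tests therefore demonstrate
the estimators' correctness under clean Poisson sampling from a known
surface, not robustness to the data problems of real vital registration
(bridged-race denominator mismatch being the prominent one).

## Cleaning conventions

County merges and the Hispanic state-year exclusion list are data files, not
code, so scheme sensitivity analyses are a config swap. The state is the
first two characters of the 5-character county fips. Exclusions remove
matching rows from deaths and denominators together and report the removed
fraction of the affected race's person-years to the log (the pipeline warns
when the fraction leaves the expected 0–1% band). Strata containing an
interval with deaths but no exposure raise an error; strata with an empty
interval or no open-interval deaths (no life-table closure) are excluded
with a warning rather than imputed — no smoothing is applied anywhere.

## Problem sizes used by the tests

The default suite runs in well under a minute: the oracle panel uses 50
random schedules with one 10⁶-lifetime simulation each; coverage uses 100
datasets × 1000 replicates; parameter recovery uses a one-period scenario
with two counties per urbanicity level at a 1.5e7 population scale; the
national analysis scenario uses 18 counties over 1990–2019 (~74 M
person-years). These sizes give Monte-Carlo margins several times smaller
than the tolerances they are tested against.

## Known limitations

- The open-interval Gompertz tail is a model; for populations whose old-age
  hazard plateaus (observed at extreme ages), κ is slightly understated and
  σ₀ correspondingly overstated, though far less than under either naive
  convention.
- e_y is only available at grid start ages; no interpolation.
- The bootstrap treats exposures as fixed and deaths as Poisson; denominator
  uncertainty is not propagated.
- The a₀ = 0.1 infant convention and the constant-hazard e-closure are
  uncited conventions of "standard" abridged tables; estimates at real-data
  precision would need the producing agency's exact rules.
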