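# Methods

## Cohort model and person-time

The cohort consists of all births in the study municipalities over a range
of birth years, followed from birth to the 15th birthday or the study end
year, whichever is earlier.  Death and migration are ignored.  Ages are
completed years at calendar-year resolution: a child born in year `b` is
at age `a` during year `b + a` and contributes exactly one person-year at
every age `a ∈ [0, 14]` with `b + a ≤ study_end_year`.  Finer (fractional)
exposure time is not identifiable from year-resolution inputs, so no
attempt is made to model it.

Reference rates are estimated internally: the national case count at each
age class divided by national person-years, pooled over the whole study
period (a per-period variant is possible by running the pipeline on
restricted birth-year ranges).  Age classes are one-year (0, 1, …, 14) for
AL/ALL/BCP-ALL and grouped (<1, 1–4, 5–9, 10–14) for AML, whose cases are
too sparse for one-year classes.  Expected counts are
`E_mp = Σ_a PY(m,p,a) · rate(a)`.  Internal rates make standardization
conservative: `Σ E = Σ O` exactly (to floating tolerance), per outcome and
within any analysed stratum, because rates are recomputed on the analysed
subset after exclusions or stratification.

Case subtype labels are disjoint at the finest known resolution (BCP-ALL;
ALL meaning non-BCP lymphoblastic; AML; AL meaning otherwise
unclassified), and outcomes aggregate them (AL = all, ALL = ALL ∪ BCP-ALL,
…), which keeps case rows non-overlapping while supporting the nested
outcome definitions.

## Exposure categories

Densities may exceed 100% (farm-headquarters assignment) and are passed
through unchanged.  Category systems are anchored at a 5% cut-off:

* `total_5cat` — category 1: total density < 5%; categories 2–5:
  birth-weighted quartiles of total density among the rest.
* `specific_6cat` — category 1 as above; category 2: total ≥ 5% but the
  specific crop < 5%; categories 3–6: birth-weighted quartiles of the
  specific density among municipalities at ≥ 5%.
* `semiquartile_10cat` — as `specific_6cat` with octile (semi-quartile)
  bins, to resolve the right tail of skewed crops such as viticulture.

The weighted quantile is the left-continuous empirical one: `q(p)` is the
smallest density whose cumulative birth weight reaches `p`.  For integer
weights it equals the plain quantile of the weight-expanded multiset,
which is the oracle used in the tests.  Bins are left-closed/right-open
with the top bin closed above; a municipality exactly at a breakpoint goes
to the upper bin.  Breakpoints are estimated pooling all birth periods
(the weights are the period births), so one breakpoint set describes a
crop.  Municipalities with zero births still receive a category (weight
zero in estimation); their cells carry `E = 0` and are dropped from fits
with a logged count.

Because categories balance *births*, a single municipality holding more
than one bin's share of the exposed births makes two breakpoints coincide.
This is reported as a configuration error rather than silently merged:
the category system the analysis assumes does not exist on such data.  It
occurs only in small or extremely concentrated populations (at the desk
simulation scale, roughly 1 in 1,000 landscapes for quartiles of total
density).

## Models and tests

All models are Poisson GLMs with offset `ln E`, fitted by IRLS
(statsmodels, deviance tolerance 1e-10, max 100 iterations; fits are
deterministic).  The categorical model uses K category dummies and no
intercept, so `exp(δ_k)` is the SIR of category k; unadjusted, this equals
`O_k/E_k` in closed form, which the tests verify to 1e-8.  The
semi-quantitative model replaces the dummies by the birth-weighted mean
density `Y_k` of the cell's category; the continuous model uses the cell's
own density.  Densities enter models (2) and (3) in units of 10
percentage points, so `exp(β̂′)` is the SIRR per 10-point increase.

Tests: heterogeneity = LR(categorical vs intercept-only), df K−1;
departure from log-linearity = LR(categorical vs semi-quantitative), df
K−2, with both models sharing the adjustment set so they remain nested;
slope tests are one-sided (H0: β′ ≤ 0), all other tests two-sided
chi-square.  The category SIR table is reported unadjusted (the closed
form), while the exposure–response fits (2)–(3) include the urban-unit
dummy by default for AL/ALL/BCP-ALL; the full adjustment set is
{urban_unit, uv, deprivation}, each entering as a binary dummy.  No
multiple-testing correction is applied across crops or outcomes.  Spatial
autocorrelation is deliberately out of scope.

Wald CIs for category SIRs use `se(log SIR) = 1/√O`, the standard error of
the saturated Poisson model; with `O = 0` the SIR is 0 and the CI is
unavailable.  This closed form reproduces published worked-example rows to
printed precision (e.g. O=154, E=139.5 → 1.10 [0.94–1.29]).

A subtlety of *internal* standardization: the constraint `Σ E = Σ O`
shrinks the sampling variance of `log(O_k/E_k)` by roughly a factor
`(1 − E_k/ΣE)`, so nominal 95% intervals over-cover slightly for
categories holding a large share of the expected count (about 97% at a
35% share).  The coverage calibration in the test suite therefore judges
the Wald interval against the generator's oracle expectations, where the
Poisson assumptions hold exactly; the over-coverage under internal rates
is a property of the design, not of the interval.

## Synthetic data generator

The generator emulates the structure of the protected registry, birth and
census data; its defaults are the study conditions used throughout the
tests.

* **Municipalities**: 2,000 by default (a `paper_scale` preset has 35,000
  and 26 birth years); land areas log-normal with median 15 km².
* **Densities**: per crop, a point mass at zero plus a log-normal tail,
  with presets chosen so that the sampled distributions match the
  qualitative shape of the real ones (viticulture: ~70% zeros, median 0,
  99th percentile two orders of magnitude above the 75th; straw cereals
  the most widespread crop; total = specific crops + a large
  "other cropland" component so most rural municipalities are
  majority-cropland).  Densities are drawn once per municipality and held
  across censuses (adequate for permanent crops; rotational-crop
  variability is not modelled).
* **Births**: log-normal municipality sizes (median 20/year, log-sd 1.3)
  with yearly Poisson variation; 2.5% of municipalities are "urban" with
  15× births and densities scaled by 0.03; births also thin with total
  density (`exp(−0.8 · density/100)`).  These choices reproduce the
  documented population structure: ~6% of municipalities below 5% total
  cropland holding about one third of births, and birth-weighted density
  quartiles near 2/17/43%.
* **Confounders**: UV class is positively associated with viticulture
  presence; deprivation is drawn independently; the urban classes are the
  exposure-confounding axis.
* **Outcome**: baseline age-specific rates peak at ages 2–4 (4.5–9.5 per
  100,000 person-years, ≈5/100k overall, the magnitude of childhood AL);
  case counts are Poisson at (municipality, birth year, age) resolution
  with a configurable rate ratio: null, log-linear
  (`SIRR^(density/10)`), or a step on one category of a realised
  categorisation.  Cases are exploded to one row each with a subtype drawn
  as BCP-ALL 78%, other ALL 5%, AML 15%, other AL 2%.

What the generator does *not* emulate: real geography and spatial
correlation of crops, municipality boundary changes, migration and death,
census-to-census crop rotation, and within-municipality address detail.
Passing calibration tests therefore demonstrates correctness of the
estimators under the assumed sampling model, not robustness to those
real-data features.

`simulate_dataset` writes the four validated tables plus ground truth;
`simulate_cells` produces the same draws directly at analysis-cell
resolution (observed, internally standardized expected, and oracle
expected counts) for many-replicate calibration studies — a dedicated test
verifies the two routes agree cell by cell.

## Problem sizes in the calibration studies

The shipped studies use: 1,000 null replicates at 2,000 municipalities ×
10 birth years for type-I error (one-sided slope test, nominal 5%) and
Wald-CI coverage (categories with O ≥ 20, against oracle expectations);
500 replicates for log-linear recovery of SIRR 1.04 per 10 points on the
total-crop density; 200 replicates at 10,000 municipalities with births
scaled so the top viticulture semi-quartile expects ≈120 cases for
threshold recovery of a planted SIR 1.25.  Replicates whose landscape
draws yield a degenerate category system (breakpoint collision, see above)
are skipped and counted; the landscape is independent of the outcome
draws, so this does not bias the calibration.

## Numerical conventions

* Ties at a category breakpoint go to the upper category.
* `Y_k` falls back to the unweighted mean density in a category with zero
  births.
* Cells with `E = 0` are dropped before fitting (logged); a cell with
  `O > 0` and `E = 0` is an input error.
* Rank-deficient designs raise an error naming the collinear columns;
  non-convergence raises with the deviance trace.
* Report formatting: E to 1 decimal, SIR/CI/p to 2 decimals.
* All randomness flows through a single integer seed per simulation spec;
  identical spec + seed reproduce every table bit for bit.
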