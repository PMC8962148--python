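# Methods

## Scope

`ehrlife` studies how immortal time distorts period life-expectancy estimates
when the exposure is a life-long condition recorded with delay on an
electronic health record. It has four analytic layers — synthetic cohort
generation, cohort construction under five entry rules, person-time
tabulation with Chiang abridged life tables, and diagnostics — orchestrated
by a pipeline/CLI. Everything is deterministic given a scenario
configuration, whose seed drives independent substreams for generation and
matching.

## Synthetic data-generating model

One patient is one row: birth, registration, practice up-to-standard (UTS)
date, optional transfer-out, last collection date, optional death, a recorded
exposure flag with diagnosis date and diagnosis *system* date, and a hidden
`true_exposed` flag.

**Mortality.** Lifetimes are piecewise-exponential over age bands: annual
rates per band (`baseline_hazard`), multiplied by `exposure_rate_ratio` for
exposed people. Sampling inverts the piecewise-linear cumulative hazard, so
the survival function is continuous across bands and closed-form survival
probabilities are available as an independent oracle (`expected_survival`).
The default rates rise from 3×10⁻⁴/yr at ages 10–19 to 0.18/yr at 90+ — a
schematic modern-population schedule, deliberately *not* calibrated to any
real cohort. The default rate ratio 2.5 reflects the substantial excess
mortality reported for intellectual disability.

**Exposure and recording.** Exposure is assigned at birth with probability
`exposure_prevalence` (default 0.03, matching the enriched sampling of the
motivating study rather than true population prevalence ~0.5%). The first
diagnosis is *recorded* at a random time from cohort eligibility
(max(registration, study start)) with hazard 1/`mean_years` (default mean 3
years), multiplied by `surge_multiplier` (default 5) while the calendar date
lies inside `surge_window` (default 2004-01-01 to 2008-12-31, mirroring the
2004–2008 primary-care incentive era). Recording is truncated at exit from
observation: a person who dies or leaves first remains exposed in truth but
is emitted indistinguishable from unexposed — exactly the people Method 5's
rationale is about. With `backdating_probability` (default 0.15) the written
diagnosis date is the birth date instead of the recording date. The system
date linked to the diagnosis starts equal to the recording date; with
`sysdate_overwrite_probability` (default 0.6, the 45–80% range of
post-diagnosis system dates seen in practice) it is replaced by a uniform
later date in observation, and with `sysdate_post_exit_probability` (default
0.02, cf. 1–3%) by a date up to two years *after* exit — the administrative
artefact that sinks Method 4.

**Everything else.** Births and registrations are uniform over configurable
windows (defaults 1920–2009 and 1985–2019; registration is floored at
birth), UTS defaults to the study start, last collection is the study end
(2019-09-29), and transfer-out is exponential from registration (default
0.05/yr), suppressed when it would fall after death or last collection.
`birth_window` is a package addition: an age-structured cohort needs a
birth-date process even though it is not part of the recording story.

**Randomness.** Each patient consumes a fixed-width block of uniforms from
one PCG64 stream seeded by the config: patient *i*'s history depends only on
the seed and *i*, so runs are reproducible, order-independent, and cheap to
vectorise (all variates are inverse-transform draws). Death dates are capped
at an administrative horizon of 2250-01-01 — nanosecond datetimes cannot
represent later dates, and nothing past the study window is analysed.

**What the generator does not emulate.** No severity grades, no linked
hospitalisation, no family/practice clustering, no secular mortality trends,
no duplicate or conflicting diagnosis codes, uniform rather than realistic
age pyramids. Passing tests therefore demonstrate correctness of the
*methods* under a known truth with the recording pathologies of interest,
not fidelity to any real population.

## Cohort construction

Dates are whole days; every interval is half-open `[start, end)`; durations
in years are days/365.25. Ordinary (Method-1) entry is the latest of study
start, registration, UTS date and the `min_age`-th birthday (calendar
anniversary; 29 February maps to 28 February off leap years). Exit from each
calendar period is the earliest of death, period end, last collection and
transfer-out. Tie-breaks: a death on the period-end date (31 December)
belongs to that period; a death on the same day as transfer-out or last
collection is censored (administrative censoring applies at the start of its
day). A death after the period-specific exit is censored at exit. People
censored by a period boundary re-enter the next period, so segments tile
follow-up without gaps or overlap and never cross a period boundary.

Method specifics follow the definitions in the README table. Method 4 drops
(and counts) exposed people whose system-date entry is on or after their
full-study exit although their Method-2 entry was not — i.e. people excluded
*because of* the system date. Method 5 splits each diagnosed person at the
(entry-floored) diagnosis date; backdated diagnoses make the person exposed
from entry, so Methods 2/3/5 share one exposed person-time set — the tests
assert the three exposed life tables are bit-identical.

**Matching (Method 3).** Exposed people are processed in ascending (index
date, patient id) order — nothing in the design forces an order, and a
sorted order makes risk sets well defined and runs reproducible. For each, up to `ratio`
(default 10) controls are drawn uniformly without replacement from people at
risk at the index date whose entry lies within `window_days` (default 150)
before it; the shortfall comes from the fallback pool (entry any time before
the index date, still at risk) with a per-row `fallback_used` flag. The
candidate pool contains never-exposed people and exposed people's
pre-diagnosis time; self-matching is impossible because a person's risk as a
candidate ends at their own diagnosis. "Without replacement" is read
globally — a control serves at most one exposed person; a
`match_unique_controls=False` switch exposes the looser per-set reading
(under which one person may be matched twice and contribute overlapping
person-time). An exposed person with an empty pool even after fallback is
retained with zero controls and a logged warning. Matching runs once on
full-study entry dates; the resulting segments are then period-split.

## Life tables

Person-time is tabulated into age bands by splitting each segment at the
ages (days since birth / 365.25) where it crosses a band boundary; deaths
increment the band containing the age at death. Because whole-day entry
dates can sit up to ~2 days below the first band's calendar age, that sliver
is counted in the first band — person-years then reconcile with segment
durations exactly (the tests require 10⁻⁶ years on a 20,000-patient cohort).

The Chiang computation uses a = 0.5 in every band (configurable), radix
100,000, default bands 10–14 … 85–89, 90+. The final open band closes the
table with q = 1 and L = l/m, so its rate must be positive. Sparse data are
*not* smoothed: a band with zero person-years, or a final band with no
deaths, raises an error telling the caller to merge bands; `merge_band`
merges a band with its successor, and `collapse_sparse_bands` applies the
explicit policy the pipeline uses (merge the final band downward until it
contains a death; merge zero-exposure bands into their successors). A group
with no deaths anywhere is skipped and listed in the run report. Interval
probabilities are clipped at 1 (attainable only when n·m > 2).

**Chiang-II intervals.** Var(q) = q²(1−q)/D per closed band (0 when D = 0);
Var(e_x) is the Chiang weighted sum over bands at or above x plus the
final-interval term l_ω²/(m_ω²·D_ω) — the delta-method variance of
e_ω = 1/m_ω under Poisson deaths — which the uncorrected Chiang variance
sets to zero. Intervals are symmetric normal approximations, not
log-transformed, and are left unclipped at zero.

**Calibration target.** In the coverage experiment the "true" e₁₀ is the
Chiang functional applied to the true piecewise-constant band rates, i.e.
the estimand of the procedure; the experiment therefore tests the variance
estimator, which is what the interval claims. (For a constant hazard with
a = 0.5 the Chiang functional reproduces 1/λ exactly, so the closed-form
check needs no such distinction.) Observed coverage at n = 20,000 over
replicate cohorts sits near 95% within the 92–98% acceptance band.

## Diagnostics

Immortal person-time in a period is the overlap of
[Method-1 entry, min(first diagnosis, exit)) with the period, summed over
diagnosed people, divided by total Method-1 exposed person-time in that
period. Backdated person-time uses the same denominator with a person-level
backdating indicator; "backdated to birth" is read at year level (diagnosis
date in the birth year) because that is the weaker of the two natural
readings, with an `exact_date=True` switch. The exposed share by observation
year counts, per calendar year, the proportion of people under observation
who contribute any exposed time; under full 1:10 matching it sits near 1/11
by design. Method-4 losses difference the per-period exposed person-year
totals of Methods 1/2/4 and count the excluded people. Every diagnostic is
checked against an independently coded per-patient recount on small cohorts.

## Problem sizes

The package's experiments run at sizes chosen to make Monte Carlo error
small relative to the effects studied while staying desk-scale: 100,000
lifetimes for the closed-form and oracle-equivalence checks, 50,000 patients
(~1,500 exposed) for the bias-direction scenario, 30,000 for the matching
contract, and 500 replicates of 20,000 for interval coverage (the
acceptance script uses 300; both are parameters).

## Known limitations

- The mortality schedule, delay distribution and surge are illustrative;
  nothing is calibrated to CPRD, so only qualitative patterns (directions,
  identities, conservation laws) transfer.
- The diagnosis-delay surge applies to the exponential family only; a fixed
  delay ignores the surge (its recording time is deterministic).
- Backdating is all-or-nothing to the exact birth date; real records show a
  spectrum of partial backdating.
- Matching ignores covariates (age, sex) by design, as in the motivating
  comparison — entry date is the only matching variable.
- With the non-unique-controls switch a person matched to several exposed
  people contributes overlapping person-time; the default global reading
  avoids this.
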