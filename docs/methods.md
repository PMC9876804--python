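# Methods

This note documents the costing model, its parameters and conventions, the
synthetic-data generators, and the design choices made where the methodology
left room.

## Cost model

The unit of account is the cost item: one priced ingredient of one
subactivity, tagged with country, modality (`inddex24`, `papi`, `shared`),
activity, cost centre and payer. The activity taxonomy is closed
(dietary-reference-data preparation, survey preparation, training, survey
execution, data entry, data cleaning/processing, administration), as is the
cost-centre taxonomy (personnel, facilities, travel, transportation,
lodging, per diem, equipment, supplies, other). Overhead and IRB fees are
ordinary items under centre `other`; there is no separate overhead rate.

**Shared costs.** Dietary reference data serve both data-collection arms.
The default allocation counts shared items at full cost in each arm's total
(so arm totals are not additive across arms); a 50/50 split is available via
`shared_allocation="split"` for users who prefer additive accounting.

**Normalisation** (`valuation.normalize`) is order-contractual: local
currency → deflate in local currency to the base year → convert at the
*base-year* exchange rate. USD → deflate only. The operation is idempotent.
Missing deflator/exchange entries raise lookup errors naming the currency
and year rather than silently passing amounts through.

**Annualisation.** Equivalent annual cost E = K/A(r, n) with
A(r, n) = (1 − (1+r)⁻ⁿ)/r, A = n at r = 0. Defaults: r = 3 %/year, full
annualised year charged to the survey (`survey_duration_months = 12`);
a shorter attribution prorates linearly. Note E > K at n = 1 for r > 0
(the annuity carries financing cost); E ≤ K holds from n = 2 at the default
rate. Backup equipment is handled through quantities: field-equipment
quantities include a backup fraction (default 10 %) covering loss and
damage.

**Time.** Internal unit is the person-minute; 1 person-day = 480 minutes
(8 h), configurable. Staff items are valued as minutes/480 × daily wage of
the (role, location) pair. Respondent time is valued at the minimum monthly
wage divided by 168 working hours (21 days × 8 h) per month — this
convention, combined with ~15 minutes for recruitment and consent,
reproduces the reference participation costs ($0.81 and $0.36 per
respondent at $151 and $59 per month) from the rounded mean interview
durations; it is configurable via `hours_per_month`.

**Rounding.** Internal arithmetic runs at full float precision. Reports
round to the nearest dollar (totals, per-respondent) and nearest cent
(respondent costs), with ties away from zero — the per-respondent arm
difference is computed from unrounded per-respondent values and rounded
last, which is what makes −64.48 report as −$64 rather than the −$65 that
differencing rounded figures would give.

## Scenario engines

**Reference-data borrowing.** A fraction f of the dietary reference data is
assumed to pre-exist in a shared repository; the electronic arm's
reference-preparation cost scales by (1 − f). Personnel items scale through
their person-minutes (borrowing saves preparation time), other items through
their amounts; shared reference items are split into a full-cost paper-arm
copy and a scaled electronic-arm copy so the paper arm is compared
unchanged. The transformation is monotone in f and commutes with
localisation (they touch disjoint attributes: minutes vs. wage rates).

**Localisation.** Every internationally based personnel item is re-assigned
to a configured in-country equivalent role and re-valued at that role's
in-country wage; person-minutes are unchanged. Missing substitutions or
wages fail loudly, naming the role.

**National projection.** Staffing first: effective interviews =
n × (1 + replicate fraction), with 20 % replicate recalls by default;
enumerator FTEs = effective interviews / (interviews-per-day × working days
per month × months per hub); field supervisors at 1:6; data-entry clerks
(paper arm only) from an entries-per-clerk-day rate, with data supervisors
at 1:10 clerks; the electronic arm keeps one data supervisor per hub for
ongoing electronic data monitoring. Staffing is rounded to the nearest
whole FTE — not the budgeting-conventional ceiling — so that reported staff
counts match the rounding convention of the reference staffing table; set
`round_staffing=False` for continuous FTEs. Then each valued item scales by
its variability class: `fixed` ×1, `per_respondent` × effective-interview
ratio, `per_enumerator` × enumerator-FTE ratio (this covers per-enumerator
equipment such as tablets), `per_hub` × hub ratio, `per_month` × total
field-month ratio. Data-entry personnel are instead re-derived from the
staffing model (clerk items × clerk-FTE ratio — zero for the electronic
arm — and data-supervisor items × data-supervisor ratio), which is what
produces the paper arm's steep data-entry growth at scale. Items in the
`capacity_building` subactivity are dropped unless
`capacity_building_included=True`, on the assumption that a national team
needs no external capacity building. A configuration that reproduces the
base study's own scale reproduces its total exactly (identity property).

National assumptions used by the packaged fixtures, chosen as plausible
values for the two study countries: Viet Nam n = 4,376 respondents, 3
subnational hubs; Burkina Faso n = 6,500, 4 hubs; one month of simultaneous
data collection per hub; 4 interviews per enumerator-day; 8 entries per
clerk-day; 22 working days/month; base study: 4 enumerators, 2 data-entry
clerks (paper arm), 1 data supervisor, 1 hub, 2 field months.

## Interview time-use analysis

Per-pass minutes (quick list, details, quantities, optional non-standard
recipe pass, review, plus the electronic arm's menu screen) are summarised
as mean and sample (n − 1) SD per country × modality × site stratum; SD is
undefined at n = 1 and empty strata are skipped with a warning. Modality
comparisons use a two-sided two-sample t test; the default flavour is
Welch's with Satterthwaite degrees of freedom because the observed total
SDs differ clearly between arms (15 vs. 10 minutes in Viet Nam), with the
pooled flavour available for sensitivity. Both flavours coincide when group
variances and sizes are equal. Results are annotated at the 5 % and 10 %
levels; no multiple-testing adjustment is applied across passes, and report
footnotes say so. Summary-statistic input (n, mean, SD per group) is
accepted alongside raw minutes, since published tables print only
summaries. A total-vs-segment-sum mismatch beyond 1 minute on externally
recorded logs is flagged, not corrected.

## Synthetic data

**Random ledgers** (`generate_ledger`) draw two-arm ledgers from targets:
activity shares (must sum to 1), an overall personnel share, an equipment
list with useful lives drawn from {2, 3, 4, 10} years, a backup fraction,
and an international wage premium. Reference-data preparation is generated
once as shared items. Amounts receive small multiplicative jitter and are
renormalised, keeping realised activity shares within two percentage points
of target; a slice of non-personnel costs is expressed in local currency to
exercise the normalisation path. Generators are pure functions of
(spec, seed).

**Interview timings** (`generate_timings`) draw per-respondent totals from
a normal truncated at zero with the configured mean/SD (a moment-matched
lognormal is available by flag) and split them into segments with
Dirichlet-weighted shares, so totals are exact segment sums. The menu
segment exists only in the electronic arm and its expected share is
menu-mean/total-mean. Default calibration: 39 (SD 15) vs. 44 (SD 10)
minutes in Viet Nam, 47 (18) vs. 50 (20) in Burkina Faso, menu means 10 and
18 minutes. At these coefficients of variation the zero-truncation biases
the mean by well under half a minute, which the parameter-recovery tests
budget for explicitly.

**Calibrated fixtures** (`generate_paper_fixture`) are deterministic ledger
pairs whose *valued* arm totals equal the reference study's published
totals to the dollar ($111,004/$120,483 for Viet Nam; $78,105/$79,456 for
Burkina Faso — where the study's abstract and results disagree by $9 on one
total, the results-section figure is used), with reference-data,
survey-preparation and administration shares matching the published
percentages within one point and personnel cost-centre shares inside the
published 67–83 % band. Calibration proceeds in three solved steps: a
field-staff execution item absorbs each arm's residual so totals are exact;
one international personnel item per arm is sized so localisation lands on
the published localized per-respondent figures; and the fixed/variable
split of a small execution/cleaning pool is solved so the national
projection lands on the published national totals. The wage table prices
in-country leadership roles at exactly one tenth of the international
rates, which keeps all four arms' personnel shares inside the published
band after these constraints. **The item-level amounts are synthetic
allocations consistent with the published aggregates, not a reconstruction
of the study's actual (unpublished) expenditure ledger** — tests passing on
the fixture demonstrate that the engine reproduces the published aggregate
arithmetic, not that it recovers true item-level costs. Likewise the
generators emulate share structure and duration moments, not real-data
features such as enumerator learning effects, heaping of recorded minutes,
or correlated cost shocks, so passing tests say nothing about those.

## Numerical choices and degenerate inputs

Float arithmetic throughout; calibration residuals are at machine precision
(totals asserted to the dollar, internal checks at 1e−9 relative). Zero
amounts, zero respondents in a stratum, empty ledger slices and
zero-variance t-test inputs are all defined behaviour (zero totals with a
warning, omission with a warning, or the degenerate t = 0/p = 1,
respectively); genuinely invalid configurations (negative fractions,
capital without a useful life, missing wages or macro entries, missing
variability tags in a national projection) raise with the offending item or
key named. Ledger validation is a reporting operation that returns all
violations rather than stopping at the first.

## Problem sizes

The packaged analyses run at the reference-study sizes: ~50-item ledgers
per country, 147/147 and 145/146 respondents per arm, 30-per-arm timing
samples, national projections at n = 4,376 and 6,500. Property tests use
1,000 random annuity draws, random ledgers up to 50 items, and timing
samples of 800–2,000 across three seeds.

## Known limitations

* Only two currencies beyond USD and two years of macro series ship as
  defaults; users supply their own series for other contexts (no PPP
  adjustment, no inflation forecasting).
* The respondent perspective covers recruitment, consent and the recall
  module only — a lower bound when surveys add modules (e.g.
  anthropometry).
* The national staffing model has no hub-placement or scheduling
  optimisation; hubs are interchangeable and collection is simultaneous.
* One published participation cost ($0.89, Viet Nam paper arm) is not
  reproducible from the published rounded inputs under any monthly-hours
  convention that reproduces the other three; the engine reports the value
  computed from its inputs ($0.88).
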