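# recallcost

Activity-based costing of 24-hour dietary recall (24HR) surveys.

Individual-level dietary data in low- and middle-income countries are
usually collected by interviewer-administered 24HR, either electronically
(computer-assisted personal interviewing, CAPI — here the INDDEX24 mobile
platform) or with pen and paper (PAPI). Deciding between the two modalities
requires knowing what each one costs, per survey and per respondent, and how
those costs change with context and scale. `recallcost` is a costing engine
for exactly that question, aimed at survey planners, health economists and
nutrition researchers budgeting dietary data collection.

## The model

The engine implements an activity- and ingredients-based costing model. A
survey is decomposed into a closed set of activities — preparation of
dietary reference data, survey preparation, training, survey execution, data
entry, data cleaning/processing, administration — and every input
("ingredient") of every activity is a ledger item with an activity, a cost
centre (personnel, equipment, per diem, …), a modality (`inddex24`, `papi`,
or `shared` for inputs serving both arms), a payer, and a price.

Valuation follows standard health-economics conventions:

* **Normalisation.** Every amount is expressed in base-year (2019) US
  dollars. Local-currency amounts are first deflated *in local currency*
  with the local GDP implicit price deflator, then converted at the
  base-year average exchange rate; US-dollar amounts are deflated with the
  US series only.
* **Annualisation.** A capital purchase *K* with useful life *n* years is
  charged its equivalent annual cost *E* = *K*/*A*(*r*, *n*), where
  *A*(*r*, *n*) = (1 − (1 + *r*)⁻ⁿ)/*r* is the annuity factor at discount
  rate *r* (3 % by default). Useful lives: food scales 2 y, tablets and
  computers 3 y, portable hard drives 4 y, cabinets and standard weights 10 y.
* **Time valuation.** Staff time is priced at the daily wage of the role
  (person-minutes / 480 × wage/day). From the societal perspective,
  respondents' participation time (interview plus ~15 min recruitment and
  consent) is valued at the region-specific minimum monthly wage spread over
  168 working hours per month.

Cost efficiency is total cost divided by respondents; arm differences are
reported as CAPI minus PAPI from unrounded per-respondent values. Three
counterfactual engines re-price the ledger: borrowing a fraction of the
dietary reference data from a shared repository (the Global Food Matters
Database), replacing internationally based staff with in-country
equivalents, and projecting to a national-scale survey through a staffing
model (enumerator FTEs from effective interviews, 1:6 field supervisors,
data-entry clerks — paper arm only — with 1:10 data supervisors) plus a
fixed/variable classification of every item. Interview durations are
compared per pass with Welch two-sample *t* tests (pooled-variance optional).

No study ledger is public, so the package ships seeded generators: a random
ledger generator with controllable activity/personnel shares, and a
deterministic *calibrated fixture* whose valued totals land exactly on the
published two-country validation-study figures (the item-level detail is a
synthetic allocation, not the study's actual expenditures).

## Worked example

```bash
recallcost simulate --country vietnam --paper-fixture --seed 1 --out-dir demo
recallcost run --ledger demo/ledger.csv --wages demo/wages.csv \
    --macro demo/macro.csv --country vietnam --n-inddex24 147 --n-papi 147
```

prints the primary cost analysis for Viet Nam:

```
                             activity  inddex24_usd  papi_usd  difference_usd
Preparation of dietary reference data       41900.0   41900.0             0.0
                   Survey preparation       15000.0   11800.0          3200.0
                             Training        6000.0    7500.0         -1500.0
                     Survey execution       27906.0   24186.0          3720.0
                           Data entry        1200.0   10200.0         -9000.0
         Data cleaning and processing        5998.0   13397.0         -7399.0
                       Administration       13000.0   11500.0          1500.0
                                Total      111004.0  120483.0         -9479.0
                  Cost per respondent         755.0     820.0           -64.0
per_respondent inddex24 755
per_respondent papi 820
per_respondent_difference -64
```

Reading the table: producing a clean, analysable 24HR dataset for 147
respondents cost $111,004 with the electronic platform and $120,483 on
paper — $755 vs. $820 per respondent, so CAPI was $64 per respondent
cheaper. The electronic arm spends more up front (equipment and a mobile
platform subscription in survey preparation, execution) and earns it back in
data entry and cleaning, which electronic capture largely eliminates.
Dietary reference data (food lists, standard recipes, conversion factors),
used by both arms, are counted in both totals.

Scenario engines, from the same inputs:

```bash
recallcost scenario localize --ledger demo/ledger.csv --wages demo/wages.csv \
    --macro demo/macro.csv --country vietnam --n-inddex24 147 --n-papi 147
# inddex24: 755 -> 498 per respondent (a 34% decrease)
# papi: 820 -> 448 per respondent (a 45% decrease)
```

and `recallcost compare --timings demo/timings.csv` tests the interview
durations between arms (on the simulated 30-per-arm sample of seed 1:
40.7 vs. 45.0 min, Welch t = −1.34, p = 0.19, not significant).

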