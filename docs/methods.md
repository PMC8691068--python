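# Methods

## Model structure

The model is a single-pass probability tree over a one-year horizon: each
simulated woman — a Medicaid-enrolled woman with opioid use disorder (OUD) —
takes exactly one root-to-terminal path, with an independent categorical
draw at every non-terminal state. There is no re-entry (no relapse-then-
retreatment cycle within the year) and no interaction between women; a
cohort is therefore an i.i.d. sample over the finite set of complete paths,
and every cohort statistic has an exact closed form by path enumeration.
The enumeration module is kept as a first-class oracle: every Monte Carlo
estimate in the test suite is checked against it.

The default tree has 71 states and 46 complete paths, staged as

1. **pregnancy** — pregnant this year or not;
2. **treatment entry** (pregnant women) — OUD identified in prenatal care →
   enrols in treatment services → receives a treatment slot; failure at any
   step routes to an untreated birth branch;
3. **treatment modality** — methadone (50%), buprenorphine (30%),
   detoxification (12%), psychological support (8%);
4. **treatment outcome** — completes or drops out;
5. **birth outcome** — NAS or not, with probability depending on the
   end-state of the cascade;
6. **postpartum survival** — overdose death or alive at year end.
   Non-pregnant women face only the overdose/living-with-OUD split.

Topology is data, not code: states, transitions, outcome-flag definitions
(sets of state ids) and intervention modifiers all live in one YAML file,
so a differently shaped cascade is a config change, not a code change.

## Calibration of the default parameters

Transition probabilities are derived algebraically from published baseline
marginals for this population (per replication of 200,000 women): 7925.4
pregnancies, 570.7 treatment starts, 418.34 completions, 3697.32 NAS
births, equivalently 15.4 NAS cases per 1000 of 239,200 reference Medicaid
births. Reading those counts at simulation scale is the internally
consistent interpretation: it implies 7.2% treatment entry among pregnant
women with OUD, 73.3% completion among starters, and a 46.7% NAS rate among
opioid-exposed births — all within clinically reported ranges.

Quantities the marginals do not pin down were fixed once, as follows:

* the cascade split `identified × enrols × slot = 0.30 × 0.40 × 0.600` is a
  structural choice (only the product is identified by the data);
* NAS risk by end-state: 0.08 after completed treatment, 0.35 after
  dropout, 0.48759 for identified-but-untreated women; the
  unidentified-untreated risk (≈ 0.492) is solved so the weighted baseline
  NAS probability is exact. The near-equality of the identified and
  unidentified untreated risks is itself an inference: it is what makes the
  published single-intervention NAS reductions for testing (−12%),
  navigators (−5%) and capacity (−1%) come out of the tree simultaneously;
* overdose risk: 0.55% (non-pregnant year), 1% postpartum untreated or
  dropout, 0.2% after completion;
* each intervention's modifier is an odds-ratio on the one transition it
  targets, sized so the single intervention reproduces its published effect
  on the count it drives (e.g. testing: treatment starts ×3.19).

Costs use representative US literature-scale values (hospital $1500/day,
NAS treatment $2000/day, 17-day stay, MAT episodes $1.5k–$6.6k, $15k/yr
incremental OUD healthcare cost, $13k special education, flat $50k earnings
to retirement at 65, 3%/yr productivity discount). They are configuration,
not findings; the published cost tables print totals whose unit scale is
not stated, so the package reproduces those tables' *arithmetic* (component
sums, integer percent differences) exactly as printed and reports its own
simulated costs in plain dollars, without attempting to reconcile the
scales (`money_scale` records, but never applies, any interpretation).

## What is, and is not, reproduced

Exactly reproduced: all printed component-sum identities (one published
row's components sum to one unit above its printed total — an independent-
rounding artifact that the checks document rather than hide), all 60
printed integer percent-difference cells, the 15.4-per-1000 truncated NAS
rate, the baseline marginals, the single-intervention effects on treatment
starts (+219/+95/+19%), completion (+13% for coaches), and NAS for
testing/navigators/capacity (−12/−5/−1%).

Not reproduced, by construction: the coaches NAS reduction (published −3%)
— moving ~57 women per replication from dropout to completion cannot remove
~121 NAS births unless the per-woman NAS probability falls by more than 1,
so the published figure must involve couplings beyond a completion shift;
this model yields ≈ −0.4%. Combination effects compose multiplicatively
under sequential modifier application with proportional renormalization,
which is explicit and validated but stronger than the published interaction
pattern (e.g. testing+navigators starts come out near +520% rather than
+312%); the per-intervention trees that govern those interactions are not
part of the published record this package builds on. Both divergences are
surfaced by the analysis outputs, not silenced.

## Randomness, replication and variance reduction

One root seed drives everything. Replication *r* uses the child stream
`SeedSequence(root_seed, spawn_key=(r,))`; with common random numbers (the
default) every scenario shares these per-replication streams, while
independent mode keys streams by `(scenario_index, r)`. The vectorized
sampler advances the whole cohort through the tree one depth at a time,
drawing one uniform per woman per depth (terminal women included) and
inverting each state's branch CDF — marginally the exact path multinomial,
but with stream consumption identical across scenarios, so shared streams
couple scenarios decision-by-decision and paired differences have reduced
variance. A no-op intervention therefore reproduces baseline *exactly*
under CRN, which the tests assert. A literal per-woman sampler (one
categorical draw per visited state, age drawn per woman) is kept for small
cohorts and as the reference implementation. Branch order is file order,
making runs bit-stable.

Ages matter only through the productivity-loss valuation of overdose
deaths; the vectorized sampler draws ages only for the women who die
(identical in distribution). When the NAS length of stay is configured as a
distribution rather than a fixed number of days, the vectorized sampler
prices stays at the expected value; the per-woman sampler samples them.

CIs are `mean ± 1.96·SD/√n_replications` per scenario; significance versus
baseline is a Welch two-sample t-test on replication values at α = 0.05
(the published tables flag non-significance without naming a test; the CI
mode used is recorded in result metadata). Percent differences round half
away from zero to integers — verified against every printed cell — and the
NAS rate per 1000 births is truncated (not rounded) to one decimal, forced
by the printed 15.4 from 3697/239,200 (arithmetically 15.456).

## Claims validation

The claims pathway mirrors state-Medicaid validation logic: among members
with a delivery in the target year (first delivery anchors), a woman is
OUD-identified if any F11.* diagnosis falls in the inclusive 365-day
lookback window ending at delivery, and treated if a treatment code falls
in the same window. "Within 1 year" is ambiguous at the boundary; day 365
is in, day 366 is out, and the tests pin the convention. Both
treated/identified and treated/untreated ratios are computed (published
prose alternates between them); treated/identified is validated by
default, at a 4.8% relative tolerance and 0.5-per-1000 NAS-rate tolerance
matching the published validation gaps (15.4 simulated vs 15.2 claims).
The shipped ICD-10 code lists are configurable placeholders, not an
authoritative ontology.

The synthetic claims generator samples per-member truth labels at
configured rates and places true codes strictly inside, and decoys strictly
outside, the lookback window, so extraction must recover truth counts
exactly (a closed-loop test). Truth labels are written to a sidecar file,
never into the claims table. The validation configuration emulates the
published context: 100,000 deliveries, 6.6% claims-identified OUD, 7.55%
of those treated, 15.2 NAS per 1000. What the generator does **not**
emulate: realistic code ontologies, enrollment spans, multiple gestations,
or the under-recognition bias the published discussion itself flags (claims
ratios are biased relative to simulation truth; the report shows both
numbers uncorrected).

## Numerical choices and degenerate inputs

Sibling probabilities must sum to 1 within 1e-9; transcribed groups summing
to 0.99–1.01 are renormalized on load with a warning (published tables are
rounded), anything worse is a validation error. Validation never raises on
parseable input — it returns the complete violation list. Modifiers that
would push a probability above 1 raise naming the transition (no silent
clamping); `multiply_odds` is the preferred mode precisely because it
cannot overflow. Enumeration has a configurable path cap (default 10⁶).
Zero-denominator ratios (empty claims cohorts, zero baseline means) are
explicit errors or flagged zeros, never NaNs.

## Problem sizes used in the checks

The shipped test suite runs the full published design (500 × 200,000) for
the baseline acceptance checks (~20 s vectorized) and scaled designs
elsewhere: 50 × 20,000 for enumeration-consistency, 10⁵ single-replication
draws for sampler convergence, 10⁴ outcomes for the exact cost identities,
and 10⁴-member claims cohorts for the closed loop. The acceptance script
runs baseline plus the four single interventions at full size.

## Known limitations

Single-pass tree (no within-year relapse/retreatment); interactions between
combined interventions are a composition rule, not estimated; costs are
point values (no probabilistic sensitivity analysis); age affects only the
productivity-loss valuation, not pregnancy, treatment or NAS risk; the
claims pathway handles synthetic CSV claims only (no payer formats, no
PHI); no QALYs or ICERs — the outputs are costs and counts, as in the
published tables; miscarriage and non-special-education child-morbidity
costs are excluded.
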