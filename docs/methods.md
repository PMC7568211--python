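# Methods

## Costing model

`costkit` implements provider-perspective incremental microcosting with the
activity-based ingredients approach. The unit of account is one priced
resource line (`CostIngredient`): `quantity x unit_price`, tagged by
facility, trial arm (`two_way`, `one_way`, or `both` for resources shared by
arms), programme activity and input category, cost nature (one-time vs
recurrent) and sharing scope (facility vs project). The admissible
(activity, input-category) pairs form a fixed taxonomy: the four start-up
activities (planning, system development, initial training, sensitization)
carry the `startup` category; service delivery and supervision carry
personnel (service delivery also equipment); communication delivery carries
communication (and equipment); overhead/administration carries overhead.
Activities are mutually exclusive, so summing activity totals never double
counts. Research-only lines (including international staff time) stay in the
table for documentation but are excluded from every incremental total at
aggregation — the same file can therefore describe the full trial budget and
the implementation cost.

The pipeline (`run_costing`) proceeds in five steps:

1. **Currency.** Line amounts in KES are converted at a fixed official rate
   (103.25 KES/USD, the 2017 rate) at line level. With a single fixed rate
   the conversion order (line vs aggregate) cannot change any total.
2. **Annualization.** Equipment is annuitized — annual cost =
   price / *A(r, n)*, *A(r, n) = (1 − (1+r)^−n)/r*, continuity limit *n* at
   *r* = 0 — with *r* = 0.03/yr and *n* = 10 yr by default (a line's own
   useful life overrides the default). One-time start-up lines are amortized
   straight-line over 5 years by default; since published figures cannot
   adjudicate between straight-line and annuitized amortization for start-up
   outlays, both are supported (`startup_amortization`) and the packaged
   dataset is calibrated under straight-line. Recurrent lines enter at
   quantity × unit price for the one-year analytic horizon.
3. **Allocation.** Project-scoped lines (facility_id `PROJECT`) are split
   across facilities in proportion to annual clients served (falling back to
   beneficiary counts, with a log message, where client volume is missing).
   When `project_total_clients` exceeds the costed facilities' summed
   weights — the study costed 2 of 6 sites holding 232 of 548 clients — the
   complement stays unallocated: it belongs to the uncosted sites and is
   reported as `unallocated_usd`, never silently dropped. With no external
   denominator the allocation is exactly conservative.
4. **Arm splitting.** `both`-arm lines are split by the facility's per-arm
   beneficiary counts (the same beneficiary-based weighting used elsewhere);
   a facility with beneficiaries in a single arm assigns the line entirely
   to that arm, which is what makes single-arm scenario runs coherent.
5. **Aggregation and unit costs.** Totals per facility × arm by activity, by
   input category, and as a fixed/variable split; then cost per beneficiary
   and per contact (contacts = automated + nurse messages), computed on
   unrounded totals. Cross-facility averages weight facilities by
   beneficiary count, which makes the weighted cost per beneficiary equal
   the pooled ratio by algebra. For cost per contact the beneficiary-
   weighted mean and the pooled ratio differ in the second decimal and
   neither is canonical, so both are reported
   (`cost_per_contact_usd`, `cost_per_contact_pooled_usd`).

**Fixed vs variable.** The fixed side is the annualized one-time start-up
activities; the variable side is the recurrent input categories. The source
study's Results prose swaps the two labels relative to its own taxonomy
table (its "variable" figure equals the start-up sum, and vice versa); this
package follows the taxonomy and leaves the prose discrepancy alone.

**Rounding.** All arithmetic is double precision; rounding (decimal
half-up) is applied only at report time — whole USD for totals and
per-beneficiary costs, two decimals for per-contact costs, one decimal for
percentage shares, matching the precision such studies print.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `discount_rate` | 0.03 /yr | annuitization of capital |
| `equipment_life_years` | 10 yr | useful life of phones/laptops/furniture |
| `startup_life_years` | 5 yr | useful life of one-time start-up outlays |
| `exchange_rate_kes_per_usd` | 103.25 | 2017 official rate |
| `startup_amortization` | `straight_line` | or `annuitized` |
| `project_total_clients` | none | allocation denominator across all sites |

## Scenarios

`apply_scenario` is a pure transformation of the tables. Under scale-up,
one-time start-up lines and project-scoped lines are kept once and
re-allocated over the enlarged facility set (one-time facility lines are
promoted to project scope — at scale they are shared network investments);
facility-scoped variable lines are replicated for added facilities from a
template facility. Communication lines whose quantity tracks message volume
(SMS fees, airtime) scale with beneficiary counts instead of replicating
flat, since message volume grows with enrolment. Salary substitution swaps
the monthly unit price of service-delivery personnel roles (roles are the
`...__<role>` suffix of a line id) for `annual_salary / 12` from a
role → salary table, preserving the person-time quantity; supervision and
coordination staff are deliberately untouched. Comparisons report percent
decreases `(base − alt)/base × 100`, rounded to whole percent.

## Economics

ICERs divide an explicit incremental cost by an exogenous effect count
(dominance analysis, QALYs/DALYs and effect discounting are out of scope).
The study context prints 7084 USD as the two-facility two-way incremental
cost while its weighted figures imply a pooled 7130 (62 × 115); the module
takes the cost as an input and does not resolve that discrepancy. The budget
projection is `target_population x penetration x cost_per_beneficiary`, with
an optional share of a reference budget.

## The synthetic data

**Generator.** `generate(params)` draws multi-facility two-arm tables with
the study's structure: 39–76 beneficiaries per facility × arm, ~52 automated
messages per beneficiary-year (the weekly-message design) plus ~12 nurse
messages in the interactive arm, category-specific price ranges, a
project-scoped cost block, a both-arm facility line and one research-flagged
line. It returns independent per-row bookkeeping (discount factors summed
term by term) so pipeline totals can be audited against ground truth; the
same seed always yields byte-identical tables. The generator emulates cost
*structure* only — no message content, adherence outcomes, seasonality or
price correlation across facilities — so passing tests demonstrate
accounting correctness, not behavioural realism.

**Calibrated fixture.** `fixture_mobile_wachx()` reconstructs the 2017
dataset. Published facility-level throughput (beneficiaries, automated and
nurse messages, client shares 152/548 and 80/548) is used as-is. Per-facility
cost splits were not published, so the fixture solves for them from the
published facility-weighted component costs and pooled unit costs:
equipment, overhead and facility start-up components are held equal across
facilities (the study prints a single value per arm); system development is
a project-scoped line whose annual value is implied by the client-share
allocation weights; facility communication is split proportionally to
message contacts; and the two facility personnel annuals are the solution of
the remaining weighted-mean and pooled-total constraints. Four quantities
are design constants, fixed once and not published: project supervision
(300 USD/yr/arm), hosting platform (400 USD/yr/arm), project monthly
salaries (nurse 1200 USD, retention officer 600 USD) and a 70/30 personnel
split between the roles. Raw ingredient rows are then back-computed
(equipment price = annual × *A*(0.03, 10); start-up price = annual × 5;
salaries in KES), so the pipeline reproduces the published weighted
components to the USD and the pooled unit costs exactly. The per-facility
totals this implies (≈ 4062/3068 USD two-way, ≈ 2878/1919 one-way) are
reconstructions, not published values — which is why per-contact unit costs
and scenario outputs are approximate rather than exact reproductions. The
facility-A clinic room fee is modelled as one 48 USD/month both-arm line
(split per arm by its equal enrolment); facility B's fee is modelled per arm
to keep its published overhead total exact.

**Scenario calibration.** The six-facility scenario keeps the two costed
facilities at their full enrolment (152 and 80 beneficiaries, all now
interactive) and gives the four added facilities 79 beneficiaries each
(uniform split of the remaining 316 — their individual counts were not
published). Its result is structure-determined, not tuned. The MOH salary
table was not published either; per the reconstruction design it is
calibrated in closed form (a single salary ratio applied to both
service-delivery roles) so that the scenario reproduces the published
31 USD per beneficiary; the implied MOH salaries are ≈ 44% of the project
scale.

## Numerical choices and degenerate inputs

Zero discount rate uses the annuity factor's continuity limit. Zero
beneficiaries or contacts for a costed cell is an explicit error naming the
facility; an empty line set aggregates to no summaries, and writing an empty
report is an error rather than an empty file. Allocation requires a positive
weight total; scenario beneficiary counts must be positive; unknown
salary-table roles warn and no-op. Ties do not arise: allocation fractions
and arm splits are exact ratios of integer counts.

## Limitations

The analytic horizon is a single year; multi-year cost streams, probabilistic
sensitivity analysis and time-to-scale dynamics are out of scope. The
fixture's row-level detail (role salaries, person-time, price composition) is
plausible invention constrained by aggregates; conclusions that depend on
row-level realism should not be drawn from it. All test and acceptance
computations run on these small tables (≈ 40 ingredient rows, 2–6
facilities), which the pipeline processes in well under a second.
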