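# Methods

## The model

`apisim` evaluates beekeeping interventions for a smallholder apiary over a
10-year horizon by discounted cash-flow analysis. A scenario is a hive
inventory (traditional log, Kenya Top Bar (KTB), Langstroth frame hives),
an optional *Calliandra calothyrsus* planting, a honey-yield model and a
set of cost rules. Its cash flow is

- **Year 0 (investment `A`)** — hive purchases at unit cost (log $3.42,
  KTB $36.64, Langstroth $43.24), a smoker ($11.44), a bee suit ($46.21),
  airtight 20-kg storage buckets sized to the peak annual harvest ($7.84
  each), apiary-siting labour (vegetation clearing plus hive hanging, two
  labour-days each at $2/day for the 22-hive reference apiary, scaled with
  hive count), and for plantings the seedling purchase ($0.10/plant) plus
  planting labour ($0.03/plant).
- **Years 1..n (net flow `B_t − C_t`)** — revenue from honey ($2.61/kg),
  beeswax ($3.01/kg) and propolis ($4.00/kg), minus routine inspection
  labour, harvest labour, lighting (torches/batteries), gumboot
  amortisation (replacement every 3 years), marketing (10 % of revenue),
  strainer cloths (2 per 400 kg honey) and tree weeding ($0.03/plant/yr).
- **NPV** = Σ (B_t − C_t)/(1+r)^t + R_n/(1+r)^n − A at r = 10 % (a 2014
  commercial lending rate). Hives fully depreciate, so the rest value R_n
  defaults to 0. All internal amounts are USD; the 2700 UGX/USD exchange
  rate exists only at the I/O boundary.

### Yield ramp

Hive colonisation depends on wild swarms occupying empty hives, so a
scenario realises only a fraction of its potential production each year.
The default ramp is the tabulated schedule 0 %, 30 %, 45 %, 60 %, 75 %,
then a 90 % plateau through year 10. A compounding alternative
(`YieldRamp.compounding()`: 30 % in year 2, ×1.15/yr to year 6, flat to
year 8, ×0.85/yr in years 9–10) is provided because the two published
descriptions of the ramp disagree; the tabulated fractions are the default
as they are the numerical record. Propolis output is held constant across
years (it is scavenged, not ramped).

### Yield models

The **baseline** uses the apiary-level survey means (13.42 kg honey,
3.51 kg comb-sold beeswax, 0.19 kg propolis per beekeeper-year at 22
hives), scaling proportionally with hive count; wax is the survey quantity
because ~71 % of baseline wax is sold in comb. All **intervention**
scenarios use national-average per-hive yields (log 8, KTB 12, Langstroth
15 kg/hive/yr) with pure-wax conversion at 10 kg honey → 1 kg beeswax,
improved management (inspection four times/month vs six times/year at
$2/visit, higher lighting spend) and a 10 %/yr escalator on harvest
labour. Marketing is defined as exactly 10 % of revenue every year, so the
escalator applies to harvest labour only.

### Forage model

Per-plant annual sugar = nectar volume/flower (35 μl/day) × flowers/plant
(17/day) × 365 days × sugar concentration calibration
`y = 0.00266 + 0.00937x + 0.0000585x²` (mg sugar/μl at refractometer
reading x %, 20 % default), converted mg → kg: 0.046 kg/plant/yr at three
decimals. When scaling to plantings the per-plant value is carried at that
printed 3-decimal precision by default (`plant_sugar_decimals=3`), so
field-guide arithmetic is reproduced exactly (1500 trees → 69 kg; × 60 %
competition → 41.4 kg); set it to `None` for full precision. Sugar mass is
equated 1:1 with harvestable honey (`honey_conversion_efficiency = 1.0`).
Maturation discounts output to 60 % in project years 1–2 and 80 %
thereafter; competition (other insects, bats) leaves 60 % of nectar to the
bees. Both discounts are multiplicative and always applied in the
cash-flow layer. Spacing is 2.25 m²/plant (1500 trees ≈ 0.34 ha); a
scenario's land budget (default 3.7 ha, the surveyed mean holding) rejects
plantings that do not fit.

A published figure of 0.2162 mg sugar/μl at 20 % concentration is
inconsistent with the calibration polynomial (0.21346), which is the value
that reproduces the 0.046 kg/plant total; the polynomial is used.

## Synthetic survey generator

The generator emulates the household survey the baseline parameters came
from (166 respondents). Each numeric field is drawn from a normal
distribution truncated at zero; count fields (hive counts, experience,
equipment) are additionally rounded half-up to integers. Because several
marginals are strongly right-spread (beeswax 3.51 ± 16.10 kg), truncating
a normal centred on the survey mean would inflate the generated mean well
above it. The location of each marginal is therefore solved numerically
(Brent's method) so that the mean of the *generated* distribution —
truncated, and rounded where integral — equals the configured mean; the
configured sd remains the spread parameter. Consequences a user should
know:

- recovered sample means converge to the configured means (the
  parameter-recovery tests check within 3 SE at n = 10,000);
- recovered sample sds of strongly truncated fields are smaller than the
  configured sds — the nominal sd is a spread parameter, not a promise
  about the realised sd;
- only marginals are emulated by default; field correlations are zero
  unless a correlation matrix is supplied, in which case a Gaussian copula
  couples the fields while preserving the truncated marginals.

Years of experience has no published mean/sd; the default 5 ± 4 yrs was
chosen once because it roughly reproduces the published adopter-category
shares (44 % late, 31 % early, 25 % innovator) and is not tuned further.
The adopter partition assigns 0–3 yrs → late and ≥8 yrs → innovator so the
published category labels ("1 to 3", "4 to 7", ">8") extend to a total
partition of the non-negative integers.

What passing these tests does **not** show about real data: real survey
fields are correlated (more experienced beekeepers own more hives), yields
are likely over-dispersed rather than truncated-normal, and equipment
ownership is highly zero-inflated. The generator is a parameter-recovery
harness, not a demographic model.

## Monte-Carlo layer

For each scenario the NPV is bracketed by re-evaluating the full cash flow
with stochastic inputs at pessimistic/optimistic settings: product prices
at mean ∓ 1 sd (survey sds: honey 1.72, beeswax 1.13, propolis 2.66
USD/kg) and honey yields scaled by 1 ∓ CV, with the survey honey
coefficient of variation (17.80/13.42 ≈ 1.33) as default; lower bounds
floor at zero. 10,000 draws `U(max − min) + min` are summarised as mean
and standard error (sample sd/√n), and scenarios are ranked by descending
mean, ties broken by lower initial investment, then name.

Two caveats are deliberate:

- The bound construction is this package's documented choice; the source
  analysis does not state how its NPV intervals were derived, so published
  mean-NPV magnitudes are not reproduction targets. The *ordering* the
  default configuration produces (20 Langstroth first, baseline last and
  negative) matches the published ranking qualitatively, and the
  stochastic layer is validated by its properties: draws confined to
  [min, max], mean within 3 SE of the midpoint, degenerate bounds
  collapsing to the deterministic NPV, ranking a seed-deterministic
  permutation.
- The sampling formula is uniform even though it is sometimes described as
  triangular; it is implemented as stated, with a true
  `triangular(min, mode = deterministic NPV, max)` sampler available via
  `distribution: triangular`.

Per-scenario draw streams are keyed on (seed, scenario name), so adding or
removing a scenario never perturbs another scenario's draws.

## Numerical choices

- Monetary arithmetic is full double precision; rounding happens only at
  the reporting boundary (CSV formatting, printed-table comparisons round
  half-up to the table's decimals).
- Count rounding is half-up (`floor(x + 0.5)`), matching how survey hive
  counts are recorded.
- Bucket and strainer needs use ceiling arithmetic (20 kg/bucket, 2 cloths
  per 400 kg); zero honey needs zero consumables.
- `npv` validates `r > −1`; at `r = 0` it reduces to the undiscounted sum.
- The truncated-normal location solve uses `brentq` on a bracket of
  `[mean − 50·sd, mean + sd + 1]` with `xtol = 1e-10`, cached per
  (mean, sd) pair.

## Problem sizes

Default runs use the study's own sizes: 166 survey records, 18 scenarios,
a 10-year horizon and 10,000 Monte-Carlo iterations per scenario; the full
pipeline completes in about a second. Parameter-recovery checks use
10,000-record surveys.

## Known limitations

- Single-forage model: one carbohydrate source, no pollen/diet diversity,
  no pollination ecosystem-service valuation.
- Interventions compose additively only; no published cash flow anchors
  combined scenarios (e.g. trees + hives), though the API accepts them.
- No taxation, inflation indexing or loan amortisation; the lending rate
  enters only as the discount rate.
- Table-level inconsistencies in the source cost table (a fixed-cost total
  typo, one beeswax sales figure inconsistent with the 10:1 conversion,
  swapped seedling cost row labels, an unexplained year-10 uptick in net
  flows) are documented here and not reproduced; unit costs and the stated
  conversion rules govern.
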