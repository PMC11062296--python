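# Methods

## The scheme

The model prices the CO2-equivalent embodied in fish biomass ("blue
carbon") removed from the ocean by fishing. Mean historical landings define
the fleet's initial sequestration allowances (the *cap*, tCO2e per year).
For each landings record — the dataset's native entry at species x year x
FAO area x EEZ x fishing country x sector x gear resolution — the
withdrawal price is

    withdrawal_price = factor(sector) * value_usd / co2e
                     = factor(sector) * market_price / carbon_content

in US$ per tCO2e. The record is removed (carbon sold instead of fish
landed) when the withdrawal price is strictly below the carbon price; ties
keep fishing by default (`tie_rule` is configurable). Removal is
all-or-nothing per record; the decision is evaluated per year-level record
and results are reported as annual means over the year span.

Assumptions inherited by everything downstream:

- the decision is static — no feedback from reduced fishing onto future
  stock sizes or prices;
- prices are real 2010 US$ throughout; the 2022 ETS price is used as given;
- the carbon embodied in a record is tonnes x species content, with
  discards, recreational and subsistence catch outside the data;
- the factor is the share of landed value compensable as return to
  capital: 1 for artisanal fleets, 0.14 for industrial fleets
  (normal-profit share), with 0.33 and 1 as sensitivity variants.

## Income bases: net-of-costs vs gross

Two income definitions for removed records are maintained side by side.

- **Gross**: the carbon revenue replaces the whole landed value
  (`income = carbon_price * co2e`). Opportunity-cost terms under this basis
  can be negative for industrial records, since removal triggers whenever
  revenue exceeds only the *factored* share of value.
- **Net-of-costs** (default): only the factored profit share of the landed
  value is forgone — the remaining share (crew payments, running costs) is
  cost avoided when the vessel stays in port — so
  `income = carbon_price * co2e + (1 - factor) * value_usd`, which is at
  least the status-quo value for every removed record by the removal rule
  itself.

The net basis is the economically coherent one for a factor that is
defined as a profit share, and it is the only basis under which the
scheme's aggregate efficiency numbers (opportunity cost as a small positive
share of landed value, with the mean-price uplift equal to that share) are
mutually consistent at realistic price distributions. `opportunity_cost`
reports all three numbers (net-of-costs, gross signed, gross positive
part); `mean_price_with_scheme` and `country_income` accept
`basis="net"|"gross"`. Both mean prices use the status-quo landed tonnage
as denominator, so uplift = opportunity cost / status-quo value is an
identity on either basis.

## Carbon-content imputation

Missing species contents are filled by the unweighted mean of measured
species at the lowest available taxonomic level: genus first, then family,
then the global measured mean. "Lowest level" is read as genus-first; the
`imputation_level` column (measured/genus/family/global) makes the
alternative auditable. Donor means are unweighted across species, not
landings-weighted. Imputation is idempotent; a table with no measured
content at all is an unrecoverable error. Contents are consumed directly
as tCO2e per tonne landed; any upstream conversion from body-composition
carbon fractions is outside the package's scope.

## Supply curve

Each record is removed on the open half-line of carbon prices above its
withdrawal price, so the supply curve is a step function whose jumps sit
exactly at the records' withdrawal prices and whose total jump mass is the
cap. The implementation sorts records by withdrawal price once and reads
cumulative sums at each grid price (`searchsorted`, side chosen by the tie
rule); this is exactly equal to re-running the per-record rule at every
grid point, which the tests verify by brute force. The default grid is 0
to 600 US$/tCO2e in unit steps with the four scenario prices inserted
exactly.

## Inequality

Country income is the sum of record incomes (chosen basis) grouped by flag
state — high-seas records accrue to the fleet's flag state — divided by
the years covered, and spread uniformly over the country's population
(single reference year). Countries are sorted ascending by income per
capita; the Lorenz curve is the piecewise-linear interpolation of
cumulative population share vs cumulative income share and the Gini
coefficient is one minus twice its trapezoid area. For block-uniform
incomes this equals the population-weighted pairwise mean-absolute-
difference formula, which the tests check to 1e-9. Within-country
distribution is ignored: no finer data exist at this resolution.

## Sensitivity

The factor grid re-runs the full removal rule per variant
(industrial 0.14/0.33/1 with artisanal 1, plus artisanal-as-industrial
0.14/0.14). Inter-annual uncertainty is the standard error of the mean of
per-year totals: sample standard deviation (n-1 denominator) over the
years divided by sqrt(n). A single year is a degenerate sample and an
error.

## Synthetic data generator

The generator emulates the record structure of reconstructed global catch
statistics. What it reproduces, with defaults chosen once to the study
window's reported global magnitudes:

- **scale**: 0.106 Gt landed per year over 2011-2018, global annual totals
  scattered with CV 0.22 (matching the reported inter-annual SEM of about
  0.008 Gt on a 0.106 Gt mean);
- **species mix**: 250 species with rank-power tonnage shares
  (concentration 0.85), putting ~11% of tonnage on the top species;
  taxonomy of ~3 species per genus, ~4 genera per family;
- **sectors**: per-record artisanal fraction Beta-distributed with mean
  0.25 (concentration 10), giving a quarter of tonnage to artisanal
  fleets;
- **prices**: species-level lognormal ex-vessel prices, location 7.33 and
  scale 0.9, with lognormal EEZ (0.2) and year (0.05) dispersion — shared
  across sectors and gears, matching the withdrawal-price formula's
  subscripting. The scale was set by closed-form lognormal quantile
  arithmetic so that the tonnage-weighted price distribution straddles the
  industrial removal thresholds at the ETS and 2050 carbon prices the way
  the reported removal shares (roughly 17% and 76% of the cap) imply,
  with a tonnage-weighted mean near US$2.1k/t;
- **carbon contents**: lognormal with mean 1.5 tCO2e/t and CV 0.3; 30% of
  species left unmeasured, with multi-species genera always keeping a
  measured donor so genus-level imputation is exercised (monotypic genera
  may fall through to family or global means);
- **space**: 60 EEZs owned round-robin by 40 countries, plus a "High
  Seas" zone taking 3% of every species' tonnage with income accruing to a
  capacity-weighted flag state; 8 FAO-area labels; gears drawn from a
  six-label set (pelagic trawl, hand lines, encircling nets, purse seine,
  harpoon, other);
- **countries**: lognormal fishing-capacity weights (sigma 0.7) drive the
  allocation of species to EEZs; lognormal populations (median 5M, sigma
  0.85) give a country-level status-quo Gini in the mid-0.5 range.

What it does not emulate: the real species list and price series, spatial
geometry, within-record price-quantity correlation, gear-specific price or
content profiles, and any trend structure across years (year effects are
i.i.d.). Passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the machinery and the plausibility
of the calibrated magnitudes — not a reproduction of the real fishery's
values, which require the original reconstructed-catch extraction.

All generation is driven by `numpy.random.default_rng` substreams derived
from a single seed; identical seeds give identical tables regardless of
call order.

## Numerical choices

- Removal ties (withdrawal price exactly equal to the carbon price) keep
  fishing by default, matching the strict-inequality reading of the
  decision rule; `tie_rule="remove"` flips the `searchsorted` side and the
  comparison operator consistently.
- Lorenz ties in per-capita income are broken by stable sort; the Gini is
  unaffected by the order within a tie block.
- Summaries and the supply curve are pure sums — additivity across any
  full partition holds to floating-point rounding, and tests assert it at
  1e-12 relative.
- Rounding happens only at display time; all CSVs and the JSON report are
  full precision.
- Problem sizes: the bundled study-scale configuration produces ~24,000
  records, which the full pipeline (601-point price grid, four scenarios,
  all summaries, Lorenz curves and the factor grid) processes in about a
  second; property suites use 120-1,000-record tables and <=200-country
  income tables.

## Known limitations

- The withdrawal-price formula divides by the record's total CO2e, the
  only reading dimensionally comparable to a US$/tCO2e carbon price; a
  per-tonne-content reading differs only by the same cancellation of
  tonnage and is algebraically identical.
- No biomass dynamics: the scheme is deliberately independent of stock
  sizes, so the package makes no claim about how removals propagate to
  future catches.
- Country-level income blocks understate within-country inequality; the
  reported Gini is a lower bound in that sense.
- The 2022 ETS price is not deflated to 2010 US$; scenario prices are
  taken as given inputs.
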