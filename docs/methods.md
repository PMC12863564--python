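# Methods

## Scope and state

The simulator evolves a cigarette market one calendar year at a time
from a base-year snapshot. State per segment and year: nominal and
real retail price, real excise, nominal net-of-tax (NOT) price, and
consumption in million packs. Derived outcomes — tax shares, revenue,
prevalence, consumer counts, intensity — are pure functions of those
paths. Everything is deterministic; the only randomness in the package
lives in the synthetic-fixture generators, each driven by one explicit
integer seed.

## Prices

The retail price identity for a taxed segment is
P = (NOT + E)(1 + v), with E the specific excise per pack and v the
VAT rate on the pre-VAT value. Two pass-through regimes are modelled:

* **Full pass-through (θ = 1).** The real NOT price is held at its
  base-year value; equivalently the nominal NOT price is indexed to
  inflation. Real retail then moves one-for-one (grossed up by VAT)
  with the real excise.
* **Over-shifting (θ > 1).** The nominal NOT price is indexed to
  inflation *and* raised by (θ − 1) times each year's nominal excise
  increment. This nominal-increment recursion reduces exactly to full
  pass-through at θ = 1 (a tested identity). Alternative bookkeepings
  (real-increment, multiplicative) were considered and rejected because
  they do not reproduce the relative price increases the calibration is
  anchored to; a residual ~0.2% ambiguity in the over-shifted price
  level remains and is treated as irreducible.

The illicit segment pays no excise or VAT and is pegged at a fixed
ratio of a legal segment's real price (0.5 × economy in the packaged
market), so legal tax rises propagate into the illicit price. Pegs may
chain; cycles are rejected at load time.

The CPI is compounded from annual inflation at full floating-point
precision and never rounded internally; published CPI tables rounded to
two decimals are display artefacts, and using them would move terminal
real prices by several tenths of a percent. Prices are likewise never
rounded during simulation (display rounding is two decimals).

## Demand

Annual factors per segment: own-price, cross-price, income, population.
Cross-price wiring defaults to adjacency down the price ladder (each
segment responds to the next more expensive one); it can be overridden
per segment. Two elasticity application forms are provided:

* `linear` (default): F = 1 + ε · %Δ. This is the form whose
  status-quo consumption, revenue series and decomposition match the
  calibration's reference outputs most closely.
* `power`: F = (ratio)^ε, the constant-elasticity form, which is
  better behaved for the very large price jumps of the stringent
  scenarios (a 55–94% real price rise over five years); its stringent-
  scenario totals sit 3–4% above the linear ones.

The two agree to first order (tested: < 0.02% divergence for sub-1%
annual shocks). The honest position, taken throughout, is that with
annual price jumps of 30–45% the functional form is a genuine modelling
choice that moves stringent-scenario totals by ~4%; both forms are
first-class and the choice is an explicit argument everywhere
(`demand_form`), defaulting to `linear`.

A factor ≤ 0 (elasticity × shock too extreme for an annual step)
raises a simulation error rather than producing negative consumption.

### Decomposition

Each year's total consumption change is attributed additively:
population and income contributions are first-order
(C_pop = Q·n, C_inc = Q·ε_y·g on the previous year's consumption), and
the price bucket is the exact remainder, carrying the own- and
cross-price effects plus all interaction terms (second-order in annual
growth rates). The buckets therefore sum to the realised change to
machine precision, per year and cumulatively — a tested invariant. A
sequential attribution (population, then income on the
population-scaled base, then price) was considered; it is equally
additive but loads the pop × income interaction onto the income bucket,
which distorts the small price bucket badly in near-neutral scenarios.

## Outcomes

* **Tax shares.** Excise share = real excise / real retail; VAT share
  = v/(1+v), constant; total = sum. For over-shifted segments a
  reporting variant is also produced in which the VAT term of the total
  share is valued at the counterfactual full-pass-through price — a
  convention some spreadsheet implementations use; both numbers are
  reported side by side.
* **Revenue.** Real excise × legal consumption plus the VAT fraction
  of legal real retail value, in million currency units. The VAT rate
  used for revenue aggregation (`vat_rate_revenue`, default 17%) is
  deliberately separate from the 16% embedded in the price identity:
  statutory VAT changed near the calibration's base year, and the two
  conventions are both in circulation. Both are exposed; the default
  reproduces the calibration's revenue series, the 16% option shifts
  totals by ~2–3%.
* **Prevalence.** Smokers are anchored by dividing baseline legal
  consumer counts by their market shares (the counts must agree within
  2% or a warning is raised), and the adult (15+) population level by
  the baseline prevalence rate — for the packaged market, ≈1.706
  million smokers and ≈17.40 million adults in 2023, the population
  thereafter growing at the macro rate. Smokers then scale with
  (Q_t/Q_{t−1})^s where s = 0.5 is the share of a consumption change
  borne by smoker numbers; the geometric form telescopes to
  (Q_T/Q_0)^0.5, a tested closed form. An arithmetic variant
  (1 + s·g) is available; differences are second-order.
* **Consumers and intensity.** Segment consumers = total smokers ×
  segment share of consumption; intensity = segment packs × 20 / 52 /
  total smokers (cigarettes per smoker per week). Consumers sum to
  smokers and intensity × smokers × 52/20 sums back to total packs
  (tested identities).

## Sensitivity

Elasticities are perturbed by shared per-type deltas — every own-price
elasticity together, every income elasticity together, every
cross-price elasticity together — over the full low/central/high grid
(≤ 27 runs). Defaults: ±0.2 for own-price and income, −0.05/+0.1 for
cross-price. Shifted own-price elasticities are clipped at 0 from
above, cross-price at 0 from below. Envelopes are element-wise extrema
over corners, so low ≤ central ≤ high holds by construction; corners
whose demand factors turn non-positive are excluded with a warning.
Per-type (rather than per-segment) deltas mirror how elasticity
uncertainty is usually reported — one band per elasticity type — and
keep the grid tiny; independent per-segment perturbation would widen
envelopes slightly.

## Synthetic fixtures

`fixtures.generate_market` / `generate_macro` draw structurally valid
markets (2–6 strictly price-ordered segments, Dirichlet shares pinned
to sum exactly to one, a uniform excise below every taxed pre-VAT
price, optional pegged untaxed cheapest segment) and macro paths from
ranges bracketing typical low-/middle-income cigarette-market values:
own-price elasticities in [−1.2, −0.2], income in [−0.6, 0.8], cross in
[0, 0.3], inflation 0–15%, income growth −5–12%, population growth
0–4%, horizons of 3–10 years. They exist to make every invariant
property-testable off-calibration; they do not attempt realistic
country calibrations (no correlation structure between elasticities and
price levels, no serial correlation in macro rates), so passing
property tests demonstrates structural correctness, not forecasting
skill on real markets.

## Numerical choices

* Shares must sum to 1 within 1e-9; violations are rejected, never
  renormalised.
* Real/nominal consistency (real × CPI = nominal) is maintained to
  1e-12 relative and tested.
* Ties and degenerate inputs: equal segment prices, share sums off by
  more than tolerance, cross-sources pointing at cheaper segments, and
  pegged-but-taxed segments are all load-time errors naming the
  offending segment and field.
* The test-suite and acceptance problem size is the packaged six-year,
  four-segment calibration plus fixture markets up to six segments and
  ten years; every full run is milliseconds, and the sensitivity grid
  is ≤ 27 such runs.

## Known limitations

* θ is exogenous; there is no endogenous industry pricing response.
* No ad valorem or tiered tax structures; the excise is a single
  uniform specific rate across taxed segments.
* No age-structured initiation/cessation dynamics and no health-outcome
  modelling; prevalence follows the aggregate half-split rule only.
* The illicit segment responds only through its pegged price and
  elasticities; there is no supply-side smuggling model.
* Segment-level consumer counts under large price changes depend on
  substitution bookkeeping choices that aggregate outcomes are
  insensitive to; the envelopes are the more robust output at segment
  level.
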