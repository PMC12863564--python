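# Mozambique cigarette market, 2023 baseline.
# Four price segments (most expensive first); prices in MZN per pack of 20,
# consumption in million packs per year, macro rates in percent.
currency: MZN
base_year: 2023

segments:
  - name: imported
    market_share: 0.02
    consumption: 2.15
    retail_price: 155.00
    excise: 10.00
    vat_rate: 0.16
    income_elasticity: 0.30
    price_elasticity: -0.50
  - name: most-sold
    market_share: 0.51
    consumption: 54.75
    retail_price: 68.00
    excise: 10.00
    vat_rate: 0.16
    income_elasticity: 0.40
    price_elasticity: -0.60
    cross_price_elasticity: 0.05
  - name: economy
    market_share: 0.42
    consumption: 45.09
    retail_price: 40.00
    excise: 10.00
    vat_rate: 0.16
    income_elasticity: 0.50
    price_elasticity: -0.70
    cross_price_elasticity: 0.10
  - name: illicit
    market_share: 0.05
    consumption: 5.37
    retail_price: 20.00
    excise: 0.00
    vat_rate: 0.00
    income_elasticity: -0.50
    price_elasticity: -0.70
    cross_price_elasticity: 0.10
    taxed: false
    price_peg: {source: economy, ratio: 0.5}

macro:
  years: [2023, 2024, 2025, 2026, 2027, 2028]
  inflation: [4.30, 4.70, 5.50, 5.50, 5.50, 5.50]
  income_growth: [3.50, 2.50, 2.50, 1.50, 10.60, 9.60]
  population_growth: [2.50, 2.50, 2.50, 2.50, 2.50, 2.50]

# Three policy scenarios: the legislated path with full pass-through, a
# stringent rule (excise grows by inflation + income growth + 30 points a
# year) with full pass-through, and the same stringent rule with the tax
# over-shifted on the premium segments.
scenarios:
  - name: status-quo
    rule: explicit_then_growth
    values: {2024: 10.40, 2025: 10.80}
    growth: 4.0
    pass_through: 1.0
  - name: stringent
    rule: formula
    premium: 30.0
    start_year: 2024
    pass_through: 1.0
  - name: over-shift
    rule: formula
    premium: 30.0
    start_year: 2024
    pass_through: {imported: 1.5, most-sold: 1.3, economy: 1.0}

# Anchors for the smoking-prevalence model: the age-standardised adult
# (15+) cigarette-smoking rate and the baseline legal consumer counts
# (thousands) that pin down the implied number of smokers.
prevalence:
  baseline_rate: 0.098
  legal_consumers_thousands: {imported: 34.1, most-sold: 869.9, economy: 716.4}
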