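"""Annual consumption dynamics from price, income and population effects.

Each segment's consumption is evolved one year at a time by four
multiplicative factors:

    Q[t] = Q[t-1] * F_own * F_cross * F_income * F_population

Own- and cross-price factors respond to the year-on-year change in
*real* retail prices; the income factor to real per-capita income
growth; the population factor (common to all segments) to population
growth.  Two functional forms are supported:

``linear`` (default)
    F = 1 + elasticity * percentage_change, the standard first-order
    elasticity application.
``power``
    F = (ratio) ** elasticity (constant-elasticity form); for income,
    (1 + g) ** elasticity.

The two agree to first order in the shock; the choice matters only for
the large price jumps of stringent tax scenarios.

The decomposition attributes each year's consumption change to
population, income and price (own + cross) buckets; population and
income enter at first order and the price bucket absorbs the exact
remainder, so the buckets add up to the total change exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import MacroPath, Market

__all__ = [
    "SimulationError",
    "cross_wiring",
    "demand_factors",
    "simulate_consumption",
    "decompose",
    "DEMAND_FORMS",
]

DEMAND_FORMS = ("linear", "power")

FACTOR_COLUMNS = ["own_price", "cross_price", "income", "population"]


class SimulationError(RuntimeError):
    """A dynamic step produced a meaningless state (e.g., factor <= 0)."""


def cross_wiring(
    market: Market, overrides: Mapping[str, str] | None = None
) -> dict[str, str | None]:
    """Map each segment to the more expensive segment whose price it tracks.

    Default wiring is adjacency down the price ladder: every segment
    responds to the next more expensive one, and the most expensive
    responds to nothing.  Explicit ``cross_source`` fields on segments,
    then ``overrides``, take precedence.
    """
    wiring: dict[str, str | None] = {}
    previous: str | None = None
    for segment in market.segments:  # price-descending order
        wiring[segment.name] = segment.cross_source or previous
        previous = segment.name
    if overrides:
        price_of = {s.name: s.baseline_retail_price for s in market.segments}
        for name, source in overrides.items():
            if name not in wiring or source not in price_of:
                raise KeyError(f"unknown segment in cross-wiring override: {name!r}")
            if price_of[source] <= price_of[name]:
                raise ValueError(
                    f"cross source {source!r} must be more expensive than {name!r}"
                )
            wiring[name] = source
    return wiring


def _price_factor(elasticity: float, ratio: float, form: str) -> float:
    if form == "linear":
        return 1.0 + elasticity * (ratio - 1.0)
    if form == "power":
        return float(ratio**elasticity)
    raise ValueError(f"unknown demand form {form!r}; expected one of {DEMAND_FORMS}")


def demand_factors(
    market: Market,
    paths: Mapping[str, pd.DataFrame],
    macro: MacroPath,
    form: str = "linear",
    wiring: Mapping[str, str | None] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-segment annual demand factors (years after the base year).

    Returns a mapping segment -> DataFrame with columns ``own_price``,
    ``cross_price``, ``income``, ``population``.
    """
    if form not in DEMAND_FORMS:
        raise ValueError(f"unknown demand form {form!r}; expected one of {DEMAND_FORMS}")
    wiring = dict(wiring) if wiring is not None else cross_wiring(market)
    years = macro.years[1:]
    factors: dict[str, pd.DataFrame] = {}
    for segment in market.segments:
        real = paths[segment.name]["real_retail"]
        rows = {}
        for year in years:
            own_ratio = float(real.loc[year] / real.loc[year - 1])
            own = _price_factor(segment.own_price_elasticity, own_ratio, form)
            source = wiring.get(segment.name)
            if source is not None and segment.cross_price_elasticity != 0.0:
                src = paths[source]["real_retail"]
                src_ratio = float(src.loc[year] / src.loc[year - 1])
                cross = _price_factor(segment.cross_price_elasticity, src_ratio, form)
            else:
                cross = 1.0
            g = float(macro.income_growth.loc[year])
            if form == "linear":
                income = 1.0 + segment.income_elasticity * g
            else:
                income = float((1.0 + g) ** segment.income_elasticity)
            population = 1.0 + float(macro.population_growth.loc[year])
            row = {
                "own_price": own,
                "cross_price": cross,
                "income": income,
                "population": population,
            }
            for key, value in row.items():
                if value <= 0.0:
                    raise SimulationError(
                        f"{key} factor for segment {segment.name!r} in {year} is "
                        f"{value:.4f} <= 0; the elasticity times the shock is too "
                        "extreme for an annual step — use smaller steps"
                    )
            rows[year] = row
        factors[segment.name] = pd.DataFrame.from_dict(rows, orient="index")[
            FACTOR_COLUMNS
        ].rename_axis("year")
    return factors


def simulate_consumption(
    market: Market,
    paths: Mapping[str, pd.DataFrame],
    macro: MacroPath,
    form: str = "linear",
    wiring: Mapping[str, str | None] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Evolve consumption over the horizon.

    Returns ``(consumption, factors)`` where ``consumption`` is a
    DataFrame (years x segments, million packs) whose first row is the
    baseline, and ``factors`` the per-segment annual factor tables.
    """
    factors = demand_factors(market, paths, macro, form=form, wiring=wiring)
    years = macro.years
    data = {s.name: [s.baseline_consumption] for s in market.segments}
    for year in years[1:]:
        for segment in market.segments:
            f = factors[segment.name].loc[year]
            q_prev = data[segment.name][-1]
            data[segment.name].append(
                q_prev
                * f["own_price"] * f["cross_price"] * f["income"] * f["population"]
            )
    consumption = pd.DataFrame(data, index=pd.Index(years, name="year"))
    return consumption, factors


def decompose(
    consumption: pd.DataFrame, factors: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Attribute annual consumption changes to population, income and price.

    Within each segment-year the population and income contributions
    are first-order (each evaluated on the previous year's consumption
    alone) and the price bucket takes the exact remainder:

        C_pop   = Q_prev * (F_pop - 1)
        C_inc   = Q_prev * (F_inc - 1)
        C_price = Q_prev * (F_pop * F_inc * F_own * F_cross - 1)
                  - C_pop - C_inc

    so C_pop + C_inc + C_price equals the year's change exactly; the
    price bucket carries the own- and cross-price effects together with
    every interaction term (all second-order in annual growth rates).
    The returned frame (indexed by year, market totals in million
    packs) has columns ``population``, ``income``, ``price`` and
    ``total``; sum the rows for cumulative contributions.
    """
    years = [int(y) for y in consumption.index][1:]
    rows = {}
    for year in years:
        c_pop = c_inc = c_price = 0.0
        for name in consumption.columns:
            q_prev = float(consumption[name].loc[year - 1])
            f = factors[name].loc[year]
            f_all = float(
                f["population"] * f["income"] * f["own_price"] * f["cross_price"]
            )
            pop = q_prev * (float(f["population"]) - 1.0)
            inc = q_prev * (float(f["income"]) - 1.0)
            c_pop += pop
            c_inc += inc
            c_price += q_prev * (f_all - 1.0) - pop - inc
        rows[year] = {
            "population": c_pop,
            "income": c_inc,
            "price": c_price,
            "total": c_pop + c_inc + c_price,
        }
    ledger = pd.DataFrame.from_dict(rows, orient="index").rename_axis("year")
    return ledger[["population", "income", "price", "total"]]
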