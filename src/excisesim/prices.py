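"""Per-segment retail price paths under tax pass-through rules.

For taxed segments the retail price obeys the VAT identity

    retail = (net_of_tax + excise) * (1 + vat_rate)

where net_of_tax (NOT) is the producer/retailer margin per pack.

Full pass-through (theta = 1) holds the *real* net-of-tax price at its
base-year value: the industry indexes its nominal margin to inflation
and passes every excise change straight into the retail price.

Over-shifting (theta > 1) adds (theta - 1) times each year's *nominal*
excise increment on top of the inflation-indexed nominal margin:

    NOT_nom[t] = NOT_nom[t-1] * (1 + inflation[t])
                 + (theta - 1) * (E_nom[t] - E_nom[t-1])

which reduces exactly to full pass-through at theta = 1.

A pegged segment (the illicit one) sells at a fixed ratio of another
segment's real price in every year and carries no excise or VAT.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .config import ConfigError, MacroPath, Market, SegmentSpec
from .policy import ExciseSchedule, ScenarioSpec

__all__ = [
    "net_of_tax_price",
    "full_passthrough_path",
    "overshift_path",
    "pegged_path",
    "price_paths",
    "paths_to_frame",
]

_COLUMNS = ["nominal_retail", "real_retail", "real_excise", "nominal_net_of_tax"]


def net_of_tax_price(retail: float, excise: float, vat_rate: float) -> float:
    """Producer price per pack: retail / (1 + vat) - excise.

    Raises :class:`ConfigError` when the excise exceeds the pre-VAT
    price (a negative margin is a configuration defect, not a market).
    """
    if retail <= 0:
        raise ConfigError(f"retail price must be > 0, got {retail}")
    if excise < 0 or vat_rate < 0:
        raise ConfigError("excise and vat_rate must be >= 0")
    value = retail / (1.0 + vat_rate) - excise
    if value < 0:
        raise ConfigError(
            f"excise {excise} exceeds the pre-VAT price {retail / (1.0 + vat_rate):.4f}"
        )
    return value


def _assemble(
    years: list[int],
    real_retail: pd.Series,
    real_excise: pd.Series,
    nominal_not: pd.Series,
    cpi: pd.Series,
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "nominal_retail": real_retail * cpi.loc[years],
            "real_retail": real_retail,
            "real_excise": real_excise,
            "nominal_net_of_tax": nominal_not,
        },
        index=pd.Index(years, name="year"),
    )
    return frame[_COLUMNS]


def full_passthrough_path(
    segment: SegmentSpec, schedule: ExciseSchedule, macro: MacroPath
) -> pd.DataFrame:
    """Price path with the real net-of-tax price frozen at its base value."""
    years = schedule.years
    not0 = net_of_tax_price(
        segment.baseline_retail_price, segment.excise, segment.vat_rate
    )
    real_excise = schedule.real if segment.taxed else pd.Series(0.0, index=years)
    real_retail = (not0 + real_excise) * (1.0 + segment.vat_rate)
    nominal_not = not0 * macro.cpi.loc[years]
    return _assemble(years, real_retail, real_excise, nominal_not, macro.cpi)


def overshift_path(
    segment: SegmentSpec, schedule: ExciseSchedule, macro: MacroPath, theta: float
) -> pd.DataFrame:
    """Price path with the excise over-shifted by factor ``theta``.

    The nominal producer price is indexed to inflation and raised by
    (theta - 1) times each year's nominal excise increment.
    """
    if theta < 0:
        raise ConfigError(f"pass-through theta must be >= 0, got {theta}")
    years = schedule.years
    not_nom = {years[0]: net_of_tax_price(
        segment.baseline_retail_price, segment.excise, segment.vat_rate
    )}
    for year in years[1:]:
        increment = float(schedule.nominal.loc[year] - schedule.nominal.loc[year - 1])
        not_nom[year] = (
            not_nom[year - 1] * (1.0 + float(macro.inflation.loc[year]))
            + (theta - 1.0) * increment
        )
    nominal_not = pd.Series(not_nom).sort_index()
    nominal_retail = (nominal_not + schedule.nominal) * (1.0 + segment.vat_rate)
    real_retail = nominal_retail / macro.cpi.loc[years]
    return _assemble(years, real_retail, schedule.real, nominal_not, macro.cpi)


def pegged_path(
    segment: SegmentSpec,
    source_real_retail: pd.Series,
    ratio: float,
    macro: MacroPath,
) -> pd.DataFrame:
    """Price path for a segment pegged to ``ratio`` times another's real price."""
    if ratio <= 0:
        raise ConfigError(f"peg ratio must be > 0, got {ratio}")
    years = [int(y) for y in source_real_retail.index]
    real_retail = ratio * source_real_retail
    real_excise = pd.Series(0.0, index=years)
    # no excise, no VAT: the whole price is the seller's margin
    nominal_not = real_retail * macro.cpi.loc[years]
    return _assemble(years, real_retail, real_excise, nominal_not, macro.cpi)


def price_paths(
    market: Market, scenario: ScenarioSpec, macro: MacroPath
) -> dict[str, pd.DataFrame]:
    """Simulate every segment's price path under one scenario.

    Taxed segments follow the pass-through rule at their scenario theta;
    pegged segments are resolved after their peg source.  Returns a
    mapping segment name -> DataFrame indexed by year with columns
    nominal_retail, real_retail, real_excise, nominal_net_of_tax.
    """
    paths: dict[str, pd.DataFrame] = {}
    pegged = [s for s in market.segments if s.price_peg is not None]
    for segment in market.segments:
        if segment.price_peg is not None:
            continue
        if segment.taxed:
            theta = scenario.theta(segment.name)
            if theta == 1.0:
                paths[segment.name] = full_passthrough_path(
                    segment, scenario.schedule, macro
                )
            else:
                paths[segment.name] = overshift_path(
                    segment, scenario.schedule, macro, theta
                )
        else:
            # untaxed, unpegged: real price constant at its base value
            years = scenario.schedule.years
            real_retail = pd.Series(segment.baseline_retail_price, index=years)
            paths[segment.name] = _assemble(
                years, real_retail, pd.Series(0.0, index=years),
                real_retail * macro.cpi.loc[years], macro.cpi,
            )
    # resolve pegs, allowing chains but not cycles
    remaining = list(pegged)
    while remaining:
        progressed = False
        for segment in list(remaining):
            source = segment.price_peg.source
            if source in paths:
                paths[segment.name] = pegged_path(
                    segment, paths[source]["real_retail"],
                    segment.price_peg.ratio, macro,
                )
                remaining.remove(segment)
                progressed = True
        if not progressed:
            names = [s.name for s in remaining]
            raise ConfigError(f"unresolvable price-peg cycle among {names}")
    return {s.name: paths[s.name] for s in market.segments}


def paths_to_frame(paths: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-segment paths into one tidy frame (year, segment, columns)."""
    frames = []
    for name, frame in paths.items():
        tidy = frame.reset_index()
        tidy.insert(1, "segment", name)
        frames.append(tidy)
    return pd.concat(frames, ignore_index=True)
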