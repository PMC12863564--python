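"""Market, elasticity and macroeconomic input structures.

A cigarette market is described as an ordered set of price segments
(most expensive first).  Each segment carries its baseline economics
(retail price, consumption, market share, specific excise, VAT rate)
and behavioural elasticities (own-price, income, cross-price).  The
macroeconomic path supplies year-by-year inflation, real per-capita
income growth and population growth; the CPI is derived from inflation
at full precision and is never rounded internally.

All prices are currency units per pack; consumption is million packs
per year; rates are fractions (0.16, not 16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "PricePeg",
    "SegmentSpec",
    "Market",
    "MacroPath",
    "SimulationConfig",
    "derive_cpi",
    "load_market",
    "load_macro",
    "load_config",
    "market_to_dict",
    "macro_to_dict",
]

#: absolute tolerance for market shares summing to one
SHARE_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant.

    Invalid inputs are rejected, never silently repaired; the message
    names the offending segment and field.
    """


@dataclass(frozen=True)
class PricePeg:
    """Price rule tying a segment's real price to another segment's.

    The pegged segment (typically the illicit one) sells at ``ratio``
    times the real retail price of ``source`` in every year.
    """

    source: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ConfigError(f"price peg ratio must be > 0, got {self.ratio}")


@dataclass(frozen=True)
class SegmentSpec:
    """One market segment's baseline economics and elasticities.

    Parameters
    ----------
    name
        Segment label, unique within a market.
    baseline_retail_price
        Nominal retail price per pack in the base year.
    baseline_consumption
        Base-year consumption in million packs.
    market_share
        Fraction of total packs sold; shares sum to one across a market.
    excise
        Specific excise tax per pack in the base year (0 for untaxed).
    vat_rate
        VAT as a fraction of the pre-VAT value (0 for untaxed segments).
    own_price_elasticity
        % change in quantity per 1% change in own real price (<= 0).
    income_elasticity
        % change in quantity per 1% change in real per-capita income;
        negative for inferior goods.
    cross_price_elasticity
        % increase in quantity per 1% rise in the price of a more
        expensive segment (>= 0).  Zero disables substitution.
    cross_source
        Explicit label of the more expensive segment whose price this
        one responds to; when omitted, adjacent wiring is used.
    taxed
        Whether the segment pays excise and VAT.
    price_peg
        Optional rule pegging the real price to another segment's.
    """

    name: str
    baseline_retail_price: float
    baseline_consumption: float
    market_share: float
    excise: float
    vat_rate: float
    own_price_elasticity: float
    income_elasticity: float
    cross_price_elasticity: float = 0.0
    cross_source: str | None = None
    taxed: bool = True
    price_peg: PricePeg | None = None

    def __post_init__(self) -> None:
        def bad(field_name: str, why: str) -> ConfigError:
            return ConfigError(f"segment {self.name!r}, field {field_name!r}: {why}")

        if self.baseline_retail_price <= 0:
            raise bad("baseline_retail_price", "must be > 0")
        if self.baseline_consumption < 0:
            raise bad("baseline_consumption", "must be >= 0")
        if not 0.0 <= self.market_share <= 1.0:
            raise bad("market_share", f"must lie in [0, 1], got {self.market_share}")
        if self.excise < 0:
            raise bad("excise", "must be >= 0")
        if self.vat_rate < 0:
            raise bad("vat_rate", "must be >= 0")
        if self.own_price_elasticity > 0:
            raise bad("own_price_elasticity", "must be <= 0")
        if self.cross_price_elasticity < 0:
            raise bad("cross_price_elasticity", "must be >= 0")
        if self.price_peg is not None:
            if self.taxed:
                raise bad("price_peg", "a pegged segment must be untaxed")
            if self.vat_rate != 0:
                raise bad("vat_rate", "a pegged segment must carry no VAT")
            if self.price_peg.source == self.name:
                raise bad("price_peg", "segment cannot peg to itself")


@dataclass(frozen=True)
class Market:
    """An ordered (price-descending) collection of segments."""

    base_year: int
    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ConfigError("a market needs at least one segment")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate segment names: {names}")
        prices = [s.baseline_retail_price for s in self.segments]
        if any(later >= earlier for earlier, later in zip(prices[:-1], prices[1:])):
            raise ConfigError(
                "segments must be strictly price-ordered, most expensive first; "
                f"got prices {prices}"
            )
        total_share = sum(s.market_share for s in self.segments)
        if abs(total_share - 1.0) > SHARE_TOL:
            raise ConfigError(
                f"market shares must sum to 1 (got {total_share!r})"
            )
        price_of = {s.name: s.baseline_retail_price for s in self.segments}
        for i, seg in enumerate(self.segments):
            if i == 0:
                if seg.cross_source is not None:
                    raise ConfigError(
                        f"segment {seg.name!r}: the most expensive segment "
                        "cannot have a cross-price source"
                    )
                continue
            if seg.cross_source is not None:
                src = seg.cross_source
                if src not in price_of:
                    raise ConfigError(
                        f"segment {seg.name!r}: cross_source {src!r} not in market"
                    )
                if price_of[src] <= seg.baseline_retail_price:
                    raise ConfigError(
                        f"segment {seg.name!r}: cross_source {src!r} must be "
                        "strictly more expensive"
                    )
        for seg in self.segments:
            if seg.price_peg is not None and seg.price_peg.source not in price_of:
                raise ConfigError(
                    f"segment {seg.name!r}: peg source "
                    f"{seg.price_peg.source!r} not in market"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def __getitem__(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def baseline_total_consumption(self) -> float:
        """Total base-year consumption, million packs."""
        return float(sum(s.baseline_consumption for s in self.segments))

    @property
    def taxed_segments(self) -> tuple[SegmentSpec, ...]:
        return tuple(s for s in self.segments if s.taxed)

    @property
    def base_excise(self) -> float:
        """The uniform specific excise paid by taxed segments in the base year."""
        rates = {s.excise for s in self.taxed_segments}
        if len(rates) != 1:
            raise ConfigError(
                f"taxed segments carry differing base excise rates: {sorted(rates)}"
            )
        return rates.pop()

    @property
    def most_sold(self) -> SegmentSpec:
        """The taxed segment with the largest market share (the MSB)."""
        return max(self.taxed_segments, key=lambda s: s.market_share)

    def replace_segments(self, segments: tuple[SegmentSpec, ...]) -> "Market":
        return replace(self, segments=segments)


def derive_cpi(inflation: pd.Series, base_year: int) -> pd.Series:
    """Compound an inflation series into a CPI with base value 1.0.

    ``inflation`` is a fraction-per-year series indexed by calendar year
    and must cover every year after ``base_year`` in its index; the
    base-year entry (if present) is ignored.  The index is kept at full
    precision — printed CPI tables are display-only.
    """
    years = sorted(int(y) for y in inflation.index)
    if base_year not in years:
        years = [base_year] + [y for y in years if y > base_year]
    if (inflation.loc[inflation.index != base_year] <= -1.0).any():
        raise ConfigError("inflation at or below -100% is not meaningful")
    cpi = {base_year: 1.0}
    for year in years:
        if year <= base_year:
            continue
        prev = year - 1
        if prev not in cpi:
            raise ConfigError(f"inflation series has a gap before {year}")
        cpi[year] = cpi[prev] * (1.0 + float(inflation.loc[year]))
    out = pd.Series(cpi, name="cpi").sort_index()
    return out


@dataclass(frozen=True)
class MacroPath:
    """Year-indexed macroeconomic assumptions with a derived CPI.

    All rate series are fractions per year and share a consecutive
    calendar-year index starting at ``base_year``.
    """

    base_year: int
    inflation: pd.Series
    income_growth: pd.Series
    population_growth: pd.Series
    cpi: pd.Series = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        idx = list(self.inflation.index)
        for name, series in (
            ("income_growth", self.income_growth),
            ("population_growth", self.population_growth),
        ):
            if list(series.index) != idx:
                raise ConfigError(f"{name} does not share the inflation year index")
        if not idx or idx[0] != self.base_year:
            raise ConfigError(f"macro series must start at base year {self.base_year}")
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ConfigError(f"macro years must be consecutive, got {idx}")
        object.__setattr__(self, "cpi", derive_cpi(self.inflation, self.base_year))

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.inflation.index]

    @property
    def horizon(self) -> int:
        return self.years[-1]


@dataclass(frozen=True)
class SimulationConfig:
    """A fully loaded configuration: market, macro path and scenario specs.

    ``scenarios`` holds the raw scenario definitions (parsed later by
    the tax-policy layer); ``prevalence`` holds the anchors for the
    smoking-prevalence model (baseline rate and legal consumer counts).
    """

    market: Market
    macro: MacroPath
    scenarios: tuple[Mapping[str, Any], ...] = ()
    prevalence: Mapping[str, Any] | None = None
    currency: str = ""


# ---------------------------------------------------------------------------
# loading / serialisation
# ---------------------------------------------------------------------------

_SEGMENT_KEYS = {
    "retail_price": "baseline_retail_price",
    "consumption": "baseline_consumption",
    "price_elasticity": "own_price_elasticity",
}


def _segment_from_dict(raw: Mapping[str, Any]) -> SegmentSpec:
    data = dict(raw)
    name = data.get("name", "<unnamed>")
    for alias, target in _SEGMENT_KEYS.items():
        if alias in data:
            data[target] = data.pop(alias)
    peg = data.pop("price_peg", None)
    if peg is not None:
        try:
            peg = PricePeg(source=peg["source"], ratio=float(peg["ratio"]))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"segment {name!r}: malformed price_peg {peg!r}") from exc
    known = {f.name for f in fields(SegmentSpec)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"segment {name!r}: unknown fields {sorted(unknown)}")
    required = {
        "name", "baseline_retail_price", "baseline_consumption", "market_share",
        "excise", "vat_rate", "own_price_elasticity", "income_elasticity",
    }
    missing = required - set(data)
    if missing:
        raise ConfigError(f"segment {name!r}: missing fields {sorted(missing)}")
    return SegmentSpec(price_peg=peg, **data)


def load_market(source: Mapping[str, Any]) -> Market:
    """Build and validate a :class:`Market` from a configuration mapping.

    Expects keys ``base_year`` and ``segments`` (a price-descending list
    of segment mappings).  Any invariant violation raises
    :class:`ConfigError` naming the offending segment/field.
    """
    try:
        base_year = int(source["base_year"])
        raw_segments = source["segments"]
    except KeyError as exc:
        raise ConfigError(f"market configuration missing key {exc.args[0]!r}") from None
    segments = tuple(_segment_from_dict(s) for s in raw_segments)
    return Market(base_year=base_year, segments=segments)


def load_macro(source: Mapping[str, Any], base_year: int) -> MacroPath:
    """Build a :class:`MacroPath` from a mapping with per-year rate lists.

    Rates in configuration files are given in percent (as economic
    tables print them) and converted to fractions here.
    """
    try:
        years = [int(y) for y in source["years"]]
        series = {
            key: pd.Series(
                [float(v) / 100.0 for v in source[key]], index=years, name=key
            )
            for key in ("inflation", "income_growth", "population_growth")
        }
    except KeyError as exc:
        raise ConfigError(f"macro configuration missing key {exc.args[0]!r}") from None
    lengths = {key: len(source[key]) for key in series}
    if any(n != len(years) for n in lengths.values()):
        raise ConfigError(f"macro series lengths differ from years: {lengths}")
    return MacroPath(base_year=base_year, **series)


def load_config(source: str | Path | Mapping[str, Any]) -> SimulationConfig:
    """Load a full simulation configuration from YAML (path) or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    market = load_market(raw)
    macro = load_macro(raw.get("macro", {}), base_year=market.base_year)
    scenarios = tuple(raw.get("scenarios", ()))
    return SimulationConfig(
        market=market,
        macro=macro,
        scenarios=scenarios,
        prevalence=raw.get("prevalence"),
        currency=str(raw.get("currency", "")),
    )


def market_to_dict(market: Market) -> dict[str, Any]:
    """Serialise a market back to plain configuration structures.

    Round-trips through :func:`load_market` at full float precision.
    """
    segments = []
    for s in market.segments:
        d: dict[str, Any] = {
            "name": s.name,
            "baseline_retail_price": s.baseline_retail_price,
            "baseline_consumption": s.baseline_consumption,
            "market_share": s.market_share,
            "excise": s.excise,
            "vat_rate": s.vat_rate,
            "own_price_elasticity": s.own_price_elasticity,
            "income_elasticity": s.income_elasticity,
            "cross_price_elasticity": s.cross_price_elasticity,
            "taxed": s.taxed,
        }
        if s.cross_source is not None:
            d["cross_source"] = s.cross_source
        if s.price_peg is not None:
            d["price_peg"] = {"source": s.price_peg.source, "ratio": s.price_peg.ratio}
        segments.append(d)
    return {"base_year": market.base_year, "segments": segments}


def macro_to_dict(macro: MacroPath) -> dict[str, Any]:
    return {
        "years": macro.years,
        "inflation": [v * 100.0 for v in macro.inflation],
        "income_growth": [v * 100.0 for v in macro.income_growth],
        "population_growth": [v * 100.0 for v in macro.population_growth],
    }
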