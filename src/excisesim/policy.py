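"""Excise schedules and tax-policy scenarios.

A scenario bundles a nominal excise schedule (the uniform specific tax
applied to all taxed segments, year by year) with per-segment
pass-through parameters theta (theta = 1: the tax increase is passed to
the retail price one-for-one; theta > 1: over-shifting, the industry
raises the net-of-tax price alongside the tax).

Schedule rules:

``explicit``
    Nominal excise values listed per year.
``explicit_then_growth``
    Legislated values for the first years, then a fixed nominal growth
    rate (the status-quo construction).
``fixed_growth``
    A single nominal growth rate applied every year.
``formula``
    Nominal growth each year equals inflation + real per-capita income
    growth + a fixed premium, combined additively in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Any, Mapping

import pandas as pd

from .config import ConfigError, MacroPath, Market

__all__ = [
    "ExciseSchedule",
    "ScenarioSpec",
    "schedule_explicit",
    "schedule_fixed_growth",
    "schedule_status_quo",
    "schedule_formula",
    "scenario_from_config",
    "build_scenarios",
]


@dataclass(frozen=True)
class ExciseSchedule:
    """Year-indexed nominal and real (base-year price) excise per pack."""

    nominal: pd.Series
    real: pd.Series

    @classmethod
    def from_nominal(cls, nominal: pd.Series, cpi: pd.Series) -> "ExciseSchedule":
        nominal = nominal.astype(float).sort_index()
        real = nominal / cpi.loc[nominal.index]
        return cls(nominal=nominal, real=real.rename("real_excise"))

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.nominal.index]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named tax policy: excise schedule plus pass-through parameters."""

    name: str
    schedule: ExciseSchedule
    pass_through: Mapping[str, float]

    def theta(self, segment: str) -> float:
        return float(self.pass_through.get(segment, 1.0))


def _check_base(market: Market, nominal: pd.Series) -> None:
    base = market.base_excise
    if abs(float(nominal.iloc[0]) - base) > 1e-9:
        raise ConfigError(
            f"schedule base-year excise {nominal.iloc[0]} differs from the "
            f"market's baseline excise {base}"
        )


def schedule_explicit(
    market: Market, macro: MacroPath, values: Mapping[int, float]
) -> ExciseSchedule:
    """Schedule from explicit nominal values covering every horizon year."""
    years = macro.years
    vals = {market.base_year: market.base_excise, **{int(y): float(v) for y, v in values.items()}}
    missing = [y for y in years if y not in vals]
    if missing:
        raise ConfigError(f"explicit schedule missing years {missing}")
    nominal = pd.Series({y: vals[y] for y in years}, name="nominal_excise")
    _check_base(market, nominal)
    return ExciseSchedule.from_nominal(nominal, macro.cpi)


def schedule_fixed_growth(
    market: Market, macro: MacroPath, growth: float
) -> ExciseSchedule:
    """Nominal excise growing at a fixed fractional rate every year."""
    return schedule_status_quo(market, macro, legislated={}, growth=growth)


def schedule_status_quo(
    market: Market,
    macro: MacroPath,
    legislated: Mapping[int, float],
    growth: float,
) -> ExciseSchedule:
    """Legislated nominal values for the first years, then fixed growth.

    ``legislated`` maps years immediately after the base year to their
    statutory nominal excise; later years grow at ``growth`` (fraction
    per year) from the previous year's value.
    """
    values: dict[int, float] = {market.base_year: market.base_excise}
    for year in macro.years[1:]:
        if year in legislated:
            values[year] = float(legislated[year])
        else:
            values[year] = values[year - 1] * (1.0 + growth)
    nominal = pd.Series(values, name="nominal_excise").sort_index()
    _check_base(market, nominal)
    return ExciseSchedule.from_nominal(nominal, macro.cpi)


def schedule_formula(
    market: Market,
    macro: MacroPath,
    premium: float,
    start_year: int | None = None,
    pre_start: Mapping[int, float] | None = None,
) -> ExciseSchedule:
    """Excise growing by inflation + income growth + ``premium`` each year.

    The three terms are combined additively in percentage points:
    growth(t) = inflation(t) + income_growth(t) + premium, all as
    fractions.  ``start_year`` defaults to the year after the base year,
    so the rule covers the whole horizon; if a later start is chosen the
    intervening years must be supplied in ``pre_start``.
    """
    if premium < 0:
        raise ConfigError(f"premium must be >= 0, got {premium}")
    start = start_year if start_year is not None else market.base_year + 1
    pre = dict(pre_start or {})
    values: dict[int, float] = {market.base_year: market.base_excise}
    for year in macro.years[1:]:
        if year < start:
            if year not in pre:
                raise ConfigError(
                    f"formula schedule starts in {start} but year {year} has "
                    "no explicit value; growth-rule years must leave no gaps"
                )
            values[year] = float(pre[year])
        else:
            g = float(macro.inflation.loc[year] + macro.income_growth.loc[year]) + premium
            values[year] = values[year - 1] * (1.0 + g)
    nominal = pd.Series(values, name="nominal_excise").sort_index()
    _check_base(market, nominal)
    return ExciseSchedule.from_nominal(nominal, macro.cpi)


def _normalise_pass_through(
    market: Market, raw: float | Mapping[str, float] | None
) -> Mapping[str, float]:
    taxed = [s.name for s in market.taxed_segments]
    if raw is None:
        raw = 1.0
    if isinstance(raw, Mapping):
        unknown = set(raw) - set(taxed)
        if unknown:
            raise ConfigError(
                f"pass_through names non-taxed or unknown segments {sorted(unknown)}"
            )
        theta = {name: float(raw.get(name, 1.0)) for name in taxed}
    else:
        theta = {name: float(raw) for name in taxed}
    for name, value in theta.items():
        if value < 0:
            raise ConfigError(f"pass_through for {name!r} must be >= 0, got {value}")
    return MappingProxyType(theta)


def scenario_from_config(
    market: Market, macro: MacroPath, cfg: Mapping[str, Any]
) -> ScenarioSpec:
    """Parse one scenario definition (see the packaged configuration).

    Growth rates and premiums in configuration are percentages.
    """
    try:
        name = str(cfg["name"])
        rule = str(cfg["rule"])
    except KeyError as exc:
        raise ConfigError(f"scenario missing key {exc.args[0]!r}") from None
    if rule == "explicit":
        schedule = schedule_explicit(market, macro, cfg.get("values", {}))
    elif rule == "explicit_then_growth":
        schedule = schedule_status_quo(
            market, macro,
            legislated={int(y): float(v) for y, v in cfg.get("values", {}).items()},
            growth=float(cfg.get("growth", 0.0)) / 100.0,
        )
    elif rule == "fixed_growth":
        schedule = schedule_fixed_growth(
            market, macro, growth=float(cfg.get("rate", 0.0)) / 100.0
        )
    elif rule == "formula":
        schedule = schedule_formula(
            market, macro,
            premium=float(cfg.get("premium", 0.0)) / 100.0,
            start_year=cfg.get("start_year"),
            pre_start={int(y): float(v) for y, v in cfg.get("values", {}).items()},
        )
    else:
        raise ConfigError(f"scenario {name!r}: unknown rule {rule!r}")
    theta = _normalise_pass_through(market, cfg.get("pass_through"))
    return ScenarioSpec(name=name, schedule=schedule, pass_through=theta)


def build_scenarios(
    market: Market,
    macro: MacroPath,
    scenario_configs: tuple[Mapping[str, Any], ...],
) -> list[ScenarioSpec]:
    """Parse every scenario definition of a loaded configuration."""
    scenarios = [scenario_from_config(market, macro, cfg) for cfg in scenario_configs]
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate scenario names: {names}")
    return scenarios
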