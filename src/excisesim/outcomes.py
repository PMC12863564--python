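"""Derived outcomes: tax shares, revenue, prevalence, consumers, intensity.

Tax shares follow the WHO convention: the excise share is the specific
excise as a fraction of the retail price; the VAT share of a
VAT-inclusive price at rate v is the constant v / (1 + v).

Revenue is aggregated over taxed segments in real (base-year) currency.
The VAT rate used for revenue aggregation is configurable separately
from the rate embedded in the price identity, because statutory rates
can change between the year the price data refer to and the years the
revenue projection covers.

Smoking prevalence is evolved from total consumption (legal plus
illicit) under the empirical rule that about half of a change in
consumption shows up as a change in the number of smokers and half as a
change in smoking intensity.  The default implementation is geometric:

    smokers[t] = smokers[t-1] * (Q[t] / Q[t-1]) ** split

which telescopes to smokers[T] = smokers[0] * (Q[T]/Q[0]) ** split.
An arithmetic variant (1 + split * growth) is available; the two agree
to second order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigError, MacroPath, Market

__all__ = [
    "PrevalenceModel",
    "tax_shares",
    "total_share_fullpass_vat",
    "revenue",
    "smokers_baseline",
    "smokers_path",
    "prevalence_path",
    "consumers_by_segment",
    "intensity",
    "DEFAULT_VAT_RATE_REVENUE",
]

#: default VAT fraction applied when aggregating revenue (rate, not share)
DEFAULT_VAT_RATE_REVENUE = 0.17

#: cigarettes per pack and weeks per year, for smoking intensity
PACK_SIZE = 20
WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class PrevalenceModel:
    """Anchors for the smoking-prevalence projection.

    ``baseline_smokers`` and ``adult_population`` are in thousands of
    people; ``intensity_split`` is the fraction of a consumption change
    borne by smoker numbers (the rest lowers smoking intensity).
    """

    baseline_prevalence: float
    baseline_smokers: float
    adult_population: float
    intensity_split: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ConfigError("baseline prevalence must lie in (0, 1)")
        if self.baseline_smokers <= 0 or self.adult_population <= 0:
            raise ConfigError("smoker and population counts must be > 0")
        if not 0.0 <= self.intensity_split <= 1.0:
            raise ConfigError("intensity split must lie in [0, 1]")


def tax_shares(path: pd.DataFrame, vat_rate: float) -> pd.DataFrame:
    """Excise, VAT and total tax shares of the retail price, per year.

    ``path`` is one segment's price path (columns ``real_retail`` and
    ``real_excise``).
    """
    real_retail = path["real_retail"]
    if (real_retail <= 0).any():
        raise ConfigError("retail price must be > 0 to form tax shares")
    excise_share = path["real_excise"] / real_retail
    vat_share = pd.Series(vat_rate / (1.0 + vat_rate), index=path.index)
    return pd.DataFrame(
        {
            "excise_share": excise_share,
            "vat_share": vat_share,
            "total_share": excise_share + vat_share,
        }
    )


def total_share_fullpass_vat(
    overshift: pd.DataFrame, fullpass: pd.DataFrame, vat_rate: float
) -> pd.Series:
    """Total tax share with the VAT term valued at the full-pass-through price.

    A reporting variant for over-shifted segments: the excise share uses
    the over-shifted retail price, while the VAT amount in the numerator
    is taken from the counterfactual full-pass-through price.
    """
    vat_amount = vat_rate / (1.0 + vat_rate) * fullpass["real_retail"]
    return (overshift["real_excise"] + vat_amount) / overshift["real_retail"]


def revenue(
    consumption: pd.DataFrame,
    paths: Mapping[str, pd.DataFrame],
    market: Market,
    vat_rate_revenue: float = DEFAULT_VAT_RATE_REVENUE,
) -> pd.DataFrame:
    """Real excise, VAT and total tax revenue per year (million currency).

    Only taxed segments contribute.  ``consumption`` is in million
    packs, prices in currency per pack, so revenue comes out in million
    currency units at base-year prices.
    """
    years = consumption.index
    excise_rev = pd.Series(0.0, index=years)
    vat_rev = pd.Series(0.0, index=years)
    vat_fraction = vat_rate_revenue / (1.0 + vat_rate_revenue)
    for segment in market.taxed_segments:
        q = consumption[segment.name]
        path = paths[segment.name]
        excise_rev += path["real_excise"] * q
        vat_rev += path["real_retail"] * q * vat_fraction
    return pd.DataFrame(
        {
            "excise_revenue": excise_rev,
            "vat_revenue": vat_rev,
            "total_revenue": excise_rev + vat_rev,
        }
    ).rename_axis("year")


def smokers_baseline(
    legal_consumers: Mapping[str, float],
    market: Market,
    baseline_prevalence: float,
    intensity_split: float = 0.5,
) -> PrevalenceModel:
    """Anchor the prevalence model on baseline legal consumer counts.

    Each legal segment's consumer count (thousands) divided by its
    market share estimates the total number of smokers; the counts are
    averaged and checked for mutual consistency (> 2% spread warns).
    The adult population level is then implied by the baseline
    prevalence rate.
    """
    implied = []
    for name, count in legal_consumers.items():
        share = market[name].market_share
        if share <= 0:
            raise ConfigError(f"segment {name!r} has zero market share")
        implied.append(count / share)
    implied = np.asarray(implied, dtype=float)
    total_smokers = float(implied.mean())
    spread = float(implied.max() / implied.min() - 1.0) if len(implied) > 1 else 0.0
    if spread > 0.02:
        warnings.warn(
            f"legal consumer counts imply inconsistent smoker totals "
            f"(spread {spread:.1%}): {implied.round(1).tolist()}",
            stacklevel=2,
        )
    return PrevalenceModel(
        baseline_prevalence=baseline_prevalence,
        baseline_smokers=total_smokers,
        adult_population=total_smokers / baseline_prevalence,
        intensity_split=intensity_split,
    )


def smokers_path(
    total_consumption: pd.Series,
    model: PrevalenceModel,
    variant: str = "geometric",
) -> pd.Series:
    """Number of smokers (thousands) per year from total consumption.

    ``total_consumption`` must include every segment, legal and illicit.
    """
    if (total_consumption <= 0).any():
        raise ConfigError("total consumption must be > 0 to evolve smokers")
    years = [int(y) for y in total_consumption.index]
    smokers = {years[0]: model.baseline_smokers}
    split = model.intensity_split
    for year in years[1:]:
        ratio = float(total_consumption.loc[year] / total_consumption.loc[year - 1])
        if variant == "geometric":
            factor = ratio**split
        elif variant == "arithmetic":
            factor = 1.0 + split * (ratio - 1.0)
        else:
            raise ValueError(f"unknown smokers-path variant {variant!r}")
        smokers[year] = smokers[year - 1] * factor
    return pd.Series(smokers, name="smokers").sort_index()


def prevalence_path(
    total_consumption: pd.Series,
    macro: MacroPath,
    model: PrevalenceModel,
    variant: str = "geometric",
) -> pd.Series:
    """Smoking prevalence (fraction of adults) per year.

    The adult population grows at the macro population-growth rate from
    the level implied by the baseline smoker count and prevalence.
    """
    smokers = smokers_path(total_consumption, model, variant=variant)
    population = {macro.base_year: model.adult_population}
    for year in macro.years[1:]:
        population[year] = population[year - 1] * (
            1.0 + float(macro.population_growth.loc[year])
        )
    adults = pd.Series(population).sort_index()
    return (smokers / adults.loc[smokers.index]).rename("prevalence")


def consumers_by_segment(
    smokers: pd.Series, consumption: pd.DataFrame
) -> pd.DataFrame:
    """Consumers per segment (thousands): smokers times consumption share."""
    total = consumption.sum(axis=1)
    shares = consumption.div(total, axis=0)
    return shares.mul(smokers, axis=0)


def intensity(
    consumption: pd.DataFrame,
    smokers: pd.Series,
    pack_size: int = PACK_SIZE,
    weeks: int = WEEKS_PER_YEAR,
) -> pd.DataFrame:
    """Cigarettes smoked per smoker per week, per segment-year.

    ``consumption`` in million packs, ``smokers`` in thousands; the
    denominator is the total smoker count, so segment rows sum to the
    market-wide intensity.
    """
    if (smokers <= 0).any():
        raise ConfigError("smoker counts must be > 0 to compute intensity")
    cigarettes_per_week = consumption * pack_size * 1000.0 / weeks
    return cigarettes_per_week.div(smokers, axis=0)
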