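"""Randomised but structurally valid markets and macro paths.

These generators exist so that every engine can be property-tested on
markets other than the packaged calibration: shares always sum to one,
prices are strictly ordered, elasticities carry the right signs, and an
optional cheapest segment is untaxed and price-pegged.  A single
integer seed drives each draw; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, MacroPath, Market, PricePeg, SegmentSpec

__all__ = ["FixtureSpec", "generate_market", "generate_macro"]


@dataclass(frozen=True)
class FixtureSpec:
    """Ranges the generators draw from.

    Elasticity and macro ranges bracket values typical of cigarette
    demand studies in low- and middle-income countries.
    """

    n_segments: int = 4
    include_pegged: bool = True
    base_year: int = 2023
    horizon_years: int = 5
    price_range: tuple[float, float] = (15.0, 200.0)
    total_consumption_range: tuple[float, float] = (20.0, 200.0)
    share_concentration: float = 2.0
    vat_range: tuple[float, float] = (0.05, 0.20)
    own_price_range: tuple[float, float] = (-1.2, -0.2)
    income_range: tuple[float, float] = (-0.6, 0.8)
    cross_range: tuple[float, float] = (0.0, 0.3)
    peg_ratio_range: tuple[float, float] = (0.3, 0.7)
    inflation_range: tuple[float, float] = (0.0, 0.15)
    income_growth_range: tuple[float, float] = (-0.05, 0.12)
    pop_growth_range: tuple[float, float] = (0.0, 0.04)
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not 2 <= self.n_segments <= 6:
            raise ConfigError("n_segments must lie in 2..6")
        if not 3 <= self.horizon_years <= 10:
            raise ConfigError("horizon_years must lie in 3..10")


def _draw_market(spec: FixtureSpec, rng: np.random.Generator) -> Market:
    n = spec.n_segments
    lo, hi = spec.price_range
    prices = np.sort(rng.uniform(lo, hi, size=n))[::-1]
    if len(np.unique(prices)) != n:
        raise ConfigError("tied prices")  # triggers a retry

    shares = rng.dirichlet(np.full(n, spec.share_concentration))
    shares = shares / shares.sum()
    # pin the last share so the sum is exactly 1.0 in floating point
    shares[-1] = 1.0 - float(shares[:-1].sum())
    if shares[-1] <= 0:
        raise ConfigError("degenerate share draw")
    total_q = rng.uniform(*spec.total_consumption_range)

    vat = float(rng.uniform(*spec.vat_range))
    pegged_last = spec.include_pegged and n >= 3
    n_taxed = n - 1 if pegged_last else n
    # a uniform specific excise below every taxed segment's pre-VAT price
    max_excise = min(prices[i] / (1.0 + vat) for i in range(n_taxed))
    excise = float(rng.uniform(0.0, 0.8 * max_excise))

    segments = []
    for i in range(n):
        is_pegged = pegged_last and i == n - 1
        name = f"seg{i}" if not is_pegged else "pegged"
        peg = None
        price = float(prices[i])
        if is_pegged:
            ratio = float(rng.uniform(*spec.peg_ratio_range))
            price = ratio * float(prices[i - 1])
            if price >= prices[i - 1]:
                raise ConfigError("peg ratio produced unordered prices")
            peg = PricePeg(source=f"seg{i - 1}", ratio=ratio)
        segments.append(
            SegmentSpec(
                name=name,
                baseline_retail_price=price,
                baseline_consumption=float(total_q * shares[i]),
                market_share=float(shares[i]),
                excise=0.0 if is_pegged else excise,
                vat_rate=0.0 if is_pegged else vat,
                own_price_elasticity=float(rng.uniform(*spec.own_price_range)),
                income_elasticity=float(rng.uniform(*spec.income_range)),
                cross_price_elasticity=(
                    0.0 if i == 0 else float(rng.uniform(*spec.cross_range))
                ),
                taxed=not is_pegged,
                price_peg=peg,
            )
        )
    return Market(base_year=spec.base_year, segments=tuple(segments))


def generate_market(spec: FixtureSpec, seed: int) -> Market:
    """Draw a valid random market; deterministic in ``seed``.

    Infeasible draws (tied prices, degenerate shares) are retried up to
    ``spec.max_retries`` times before raising.
    """
    rng = np.random.default_rng(seed)
    last_error: Exception | None = None
    for _ in range(spec.max_retries):
        try:
            return _draw_market(spec, rng)
        except ConfigError as exc:
            last_error = exc
    raise ConfigError(
        f"could not draw a feasible market in {spec.max_retries} tries: {last_error}"
    )


def generate_macro(spec: FixtureSpec, seed: int) -> MacroPath:
    """Draw a random macro path over the fixture horizon; seeded."""
    rng = np.random.default_rng(seed)
    years = list(range(spec.base_year, spec.base_year + spec.horizon_years + 1))
    n = len(years)

    def draw(bounds: tuple[float, float], name: str) -> pd.Series:
        return pd.Series(rng.uniform(*bounds, size=n), index=years, name=name)

    return MacroPath(
        base_year=spec.base_year,
        inflation=draw(spec.inflation_range, "inflation"),
        income_growth=draw(spec.income_growth_range, "income_growth"),
        population_growth=draw(spec.pop_growth_range, "population_growth"),
    )
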