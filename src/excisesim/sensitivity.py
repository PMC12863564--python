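"""Elasticity-perturbation envelopes around a central scenario run.

Every own-price elasticity is shifted together by one delta, every
income elasticity by another, every cross-price elasticity by a third,
and the scenario is re-run at each grid corner of the three deltas
(low / central / high each, at most 27 runs).  Reported envelopes are
the element-wise extrema over the corners, so low <= central <= high by
construction.  Shifted own-price elasticities are clipped to stay
non-positive and cross-price elasticities to stay non-negative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .config import MacroPath, Market
from .demand import SimulationError
from .outcomes import DEFAULT_VAT_RATE_REVENUE, PrevalenceModel
from .policy import ScenarioSpec
from .run import ScenarioResult, run_scenario

__all__ = ["PerturbationSpec", "perturb_market", "envelope", "EnvelopeResult"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Elasticity deltas, in elasticity units (not percent).

    Own-price and income elasticities move by +/- their delta; the
    cross-price band is asymmetric (``cross_low`` below, ``cross_high``
    above), reflecting the thinner evidence base for substitution.
    """

    own_price_delta: float = 0.2
    income_delta: float = 0.2
    cross_low: float = 0.05
    cross_high: float = 0.10

    def corners(self) -> list[tuple[float, float, float]]:
        """All (own, income, cross) delta combinations on the grid."""
        return list(
            itertools.product(
                (-self.own_price_delta, 0.0, self.own_price_delta),
                (-self.income_delta, 0.0, self.income_delta),
                (-self.cross_low, 0.0, self.cross_high),
            )
        )


def perturb_market(
    market: Market, own_delta: float, income_delta: float, cross_delta: float
) -> Market:
    """Shift every segment's elasticities by the shared deltas, clipped.

    Own-price elasticities stay <= 0 and cross-price elasticities stay
    >= 0; income elasticities are unconstrained in sign.
    """
    segments = tuple(
        replace(
            s,
            own_price_elasticity=min(s.own_price_elasticity + own_delta, 0.0),
            income_elasticity=s.income_elasticity + income_delta,
            cross_price_elasticity=max(s.cross_price_elasticity + cross_delta, 0.0),
        )
        for s in market.segments
    )
    return market.replace_segments(segments)


@dataclass
class EnvelopeResult:
    """(low, central, high) bands for the headline outcome series.

    ``consumption`` etc. are DataFrames indexed by year with columns
    ``low``, ``central``, ``high``; ``consumers`` maps segment name to
    such a frame.  ``central`` is the unperturbed run's result.
    """

    central_run: ScenarioResult
    consumption: pd.DataFrame
    revenue: pd.DataFrame
    prevalence: pd.DataFrame | None
    consumers: dict[str, pd.DataFrame] | None
    n_corners: int
    skipped_corners: list[tuple[float, float, float]]


def _band(central: pd.Series, candidates: list[pd.Series]) -> pd.DataFrame:
    stacked = pd.concat(candidates, axis=1)
    return pd.DataFrame(
        {"low": stacked.min(axis=1), "central": central, "high": stacked.max(axis=1)}
    )


def envelope(
    market: Market,
    macro: MacroPath,
    scenario: ScenarioSpec,
    prevalence_model: PrevalenceModel | None = None,
    perturbation: PerturbationSpec | None = None,
    demand_form: str = "linear",
    vat_rate_revenue: float = DEFAULT_VAT_RATE_REVENUE,
) -> EnvelopeResult:
    """Run a scenario at every elasticity-delta corner and band the outcomes."""
    perturbation = perturbation or PerturbationSpec()
    central = run_scenario(
        market, macro, scenario, prevalence_model,
        demand_form=demand_form, vat_rate_revenue=vat_rate_revenue,
    )

    totals: list[pd.Series] = []
    revenues: list[pd.Series] = []
    prevalences: list[pd.Series] = []
    consumers: dict[str, list[pd.Series]] = {
        name: [] for name in (central.consumers.columns if central.consumers is not None else [])
    }
    skipped: list[tuple[float, float, float]] = []
    corners = perturbation.corners()
    for deltas in corners:
        if deltas == (0.0, 0.0, 0.0):
            result = central
        else:
            perturbed = perturb_market(market, *deltas)
            try:
                result = run_scenario(
                    perturbed, macro, scenario, prevalence_model,
                    demand_form=demand_form, vat_rate_revenue=vat_rate_revenue,
                )
            except SimulationError as exc:
                warnings.warn(
                    f"corner {deltas} excluded from the envelope: {exc}",
                    stacklevel=2,
                )
                skipped.append(deltas)
                continue
        totals.append(result.total_consumption)
        revenues.append(result.revenue["total_revenue"])
        if result.prevalence is not None:
            prevalences.append(result.prevalence)
            for name in consumers:
                consumers[name].append(result.consumers[name])

    return EnvelopeResult(
        central_run=central,
        consumption=_band(central.total_consumption, totals),
        revenue=_band(central.revenue["total_revenue"], revenues),
        prevalence=(
            _band(central.prevalence, prevalences) if prevalences else None
        ),
        consumers=(
            {
                name: _band(central.consumers[name], series)
                for name, series in consumers.items()
            }
            if central.consumers is not None
            else None
        ),
        n_corners=len(corners) - len(skipped),
        skipped_corners=skipped,
    )
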