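"""Scenario orchestration: one call from configuration to all outcomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import demand, outcomes, prices
from .config import MacroPath, Market, SimulationConfig
from .outcomes import DEFAULT_VAT_RATE_REVENUE, PrevalenceModel
from .policy import ScenarioSpec

__all__ = ["ScenarioResult", "run_scenario", "prevalence_model_from_config"]


@dataclass
class ScenarioResult:
    """Everything one scenario run produces.

    Consumption is in million packs, revenue in million currency units
    at base-year prices, smokers/consumers in thousands, prevalence as a
    fraction, intensity in cigarettes per smoker per week.
    """

    scenario: ScenarioSpec
    prices: dict[str, pd.DataFrame]
    consumption: pd.DataFrame
    factors: dict[str, pd.DataFrame]
    decomposition: pd.DataFrame
    shares: dict[str, pd.DataFrame]
    revenue: pd.DataFrame
    smokers: pd.Series | None
    prevalence: pd.Series | None
    consumers: pd.DataFrame | None
    intensity: pd.DataFrame | None
    demand_form: str
    vat_rate_revenue: float
    total_share_variant: pd.Series | None = None

    @property
    def total_consumption(self) -> pd.Series:
        return self.consumption.sum(axis=1)

    @property
    def legal_consumption(self) -> pd.Series:
        legal = [c for c in self.consumption.columns if c in self.shares]
        return self.consumption[legal].sum(axis=1)

    @property
    def decomposition_cumulative(self) -> pd.Series:
        return self.decomposition.sum(axis=0)

    def summary(self, msb: str) -> dict[str, float]:
        """Headline numbers for the most-sold brand and market totals."""
        first, last = self.consumption.index[0], self.consumption.index[-1]
        out = {
            "real_price_msb_final": float(self.prices[msb]["real_retail"].loc[last]),
            "excise_share_msb_final": float(self.shares[msb]["excise_share"].loc[last]),
            "total_share_msb_final": float(self.shares[msb]["total_share"].loc[last]),
            "consumption_base": float(self.total_consumption.loc[first]),
            "consumption_final": float(self.total_consumption.loc[last]),
            "revenue_base_bn": float(self.revenue["total_revenue"].loc[first] / 1000.0),
            "revenue_final_bn": float(self.revenue["total_revenue"].loc[last] / 1000.0),
        }
        out["revenue_growth_pct"] = 100.0 * (
            out["revenue_final_bn"] / out["revenue_base_bn"] - 1.0
        )
        if self.prevalence is not None:
            out["prevalence_base_pct"] = float(self.prevalence.loc[first] * 100.0)
            out["prevalence_final_pct"] = float(self.prevalence.loc[last] * 100.0)
        return out


def prevalence_model_from_config(
    config: SimulationConfig,
) -> PrevalenceModel | None:
    """Build the prevalence model from a loaded configuration, if anchored."""
    raw = config.prevalence
    if not raw:
        return None
    return outcomes.smokers_baseline(
        legal_consumers=raw["legal_consumers_thousands"],
        market=config.market,
        baseline_prevalence=float(raw["baseline_rate"]),
        intensity_split=float(raw.get("intensity_split", 0.5)),
    )


def run_scenario(
    market: Market,
    macro: MacroPath,
    scenario: ScenarioSpec,
    prevalence_model: PrevalenceModel | None = None,
    demand_form: str = "linear",
    vat_rate_revenue: float = DEFAULT_VAT_RATE_REVENUE,
    cross_overrides: Mapping[str, str] | None = None,
) -> ScenarioResult:
    """Simulate one scenario end to end.

    Prevalence, consumer and intensity outputs are produced only when a
    ``prevalence_model`` is supplied.
    """
    paths = prices.price_paths(market, scenario, macro)
    wiring = demand.cross_wiring(market, overrides=cross_overrides)
    consumption, factors = demand.simulate_consumption(
        market, paths, macro, form=demand_form, wiring=wiring
    )
    ledger = demand.decompose(consumption, factors)
    shares = {
        s.name: outcomes.tax_shares(paths[s.name], s.vat_rate)
        for s in market.taxed_segments
    }
    rev = outcomes.revenue(consumption, paths, market, vat_rate_revenue)

    variant = None
    overshifted = [s for s in market.taxed_segments if scenario.theta(s.name) != 1.0]
    if overshifted:
        msb = market.most_sold
        if scenario.theta(msb.name) != 1.0:
            fullpass = prices.full_passthrough_path(msb, scenario.schedule, macro)
            variant = outcomes.total_share_fullpass_vat(
                paths[msb.name], fullpass, msb.vat_rate
            )

    smokers = prevalence = consumers = intens = None
    if prevalence_model is not None:
        total = consumption.sum(axis=1)
        smokers = outcomes.smokers_path(total, prevalence_model)
        prevalence = outcomes.prevalence_path(total, macro, prevalence_model)
        consumers = outcomes.consumers_by_segment(smokers, consumption)
        intens = outcomes.intensity(consumption, smokers)

    return ScenarioResult(
        scenario=scenario,
        prices=paths,
        consumption=consumption,
        factors=factors,
        decomposition=ledger,
        shares=shares,
        revenue=rev,
        smokers=smokers,
        prevalence=prevalence,
        consumers=consumers,
        intensity=intens,
        demand_form=demand_form,
        vat_rate_revenue=vat_rate_revenue,
        total_share_variant=variant,
    )
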