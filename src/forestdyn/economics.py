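"""Cost and benefit ledgers for the management scenarios.

All ledger values are carried in hundred-million KRW (억원, 1e8 KRW) per
year; US-dollar figures are display-only conversions.  Costs follow the
Korea Forest Service budget structure:

* no-management scenarios carry the baseline tending budget (A) and
  reforestation budget (B); the climate-change scenario adds a
  vulnerability-management line priced per cumulative vulnerable
  hectare;
* management scenarios carry thinning, clear-cut felling, logging
  overhead, yarding (30% product collection share) and reforestation
  lines, each an accumulated-area (or volume) total divided by the
  accumulation years (15 for the 2030 period, 35 for 2050).

Benefits are carbon-credit revenue on cumulative sequestration plus log
trading revenue on harvested volume.  Carbon credit and log prices are
not part of the published budget tables and are configurable
placeholders.

``KOREA_REFERENCE_COST_LINES`` ships the national-scale reference
ledger line items (Korea Forest Service budget analysis, 2030/2050
accounting periods) used to validate the ledger arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SpeciesTable, species_table

__all__ = [
    "UnitPrices",
    "CostLedger",
    "BenefitLedger",
    "line_cost",
    "scenario_total_cost",
    "benefits",
    "cost_benefit_series",
    "krw_usd",
    "build_cost_ledger",
    "build_benefit_ledger",
    "KOREA_REFERENCE_COST_LINES",
    "KOREA_REFERENCE_TOTALS",
]

#: Cost line kinds understood by :func:`line_cost`.
LINE_KINDS = (
    "thinning", "clearcut", "logging_overhead", "yarding",
    "reforestation", "vulnerability",
)

MANAGEMENT_LINES = (
    "thinning", "clearcut", "logging_overhead", "yarding", "reforestation",
)


@dataclass(frozen=True)
class UnitPrices:
    """Unit prices; ledger lines are hundred-million KRW (1e8 KRW).

    The baseline budgets and per-ha averages mirror the national budget
    tables; carbon and log prices are placeholders (not published in
    the budget analysis) and must be reviewed for any real costing.
    """

    tending_budget: float = 2090.0  # (A) 1e8 KRW/yr
    reforestation_budget: float = 1122.0  # (B) 1e8 KRW/yr
    thinning_unit: float = 0.0316  # (B') 1e8 KRW/ha
    vulnerability_unit: float = 0.0021  # (D) 1e8 KRW/ha
    logging_overhead_unit: float = 0.0021  # (G') 1e8 KRW/ha
    yarding_unit: float = 0.0003  # (I') 1e8 KRW/ha
    yarding_share: float = 0.30
    krw_per_usd: float = 1200.0
    carbon_price_krw_per_tco2: float = 28000.0  # placeholder (offset credit)

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"unit price {name} must be >= 0")


@dataclass
class CostLedger:
    """Cost line items (1e8 KRW/yr) for one scenario and period."""

    scenario_id: int
    period: str  # '2030' or '2050'
    accumulation_years: int
    lines: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return scenario_total_cost(self, self.scenario_id)


@dataclass
class BenefitLedger:
    """Benefit line items (1e8 KRW/yr) for one scenario and period."""

    scenario_id: int
    period: str
    accumulation_years: int
    carbon_revenue: float = 0.0
    log_revenue: float = 0.0

    def total(self) -> float:
        return self.carbon_revenue + self.log_revenue


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def line_cost(
    kind: str,
    cum_area: float,
    unit: float,
    years: float,
    avg_volume: float | None = None,
    unit_volume_cost: float | None = None,
    yarding_share: float = 0.30,
) -> float:
    """One cost line (1e8 KRW/yr) from a cumulative area and unit price.

    thinning / logging_overhead / reforestation / vulnerability:
    ``area · unit / years``;  clearcut: ``area · avg_volume ·
    unit_volume_cost / years``;  yarding: ``(area / years) · unit ·
    share``.
    """
    if kind not in LINE_KINDS:
        raise ValueError(f"unknown cost line kind {kind!r}; known: {LINE_KINDS}")
    if cum_area < 0:
        raise ValueError("cum_area must be >= 0")
    if years <= 0:
        raise ValueError("accumulation years must be > 0")
    if kind == "clearcut":
        if avg_volume is None or unit_volume_cost is None:
            raise ValueError("clearcut line needs avg_volume and unit_volume_cost")
        return cum_area * avg_volume * unit_volume_cost / years
    if kind == "yarding":
        return cum_area / years * unit * yarding_share
    return cum_area * unit / years


def scenario_total_cost(ledger: CostLedger, scenario_id: int) -> float:
    """Total potential cost (1e8 KRW/yr), rounded half-up to an integer.

    Scenario 1 carries the baseline budgets A+B; scenario 2 adds the
    vulnerability line; scenarios 3-4 total only the five management
    lines (the baseline A+B is budgeted separately in the national
    accounting and excluded from the management totals).
    """
    lines = ledger.lines
    if scenario_id == 1:
        needed = ["baseline_mgmt", "baseline_reforest"]
    elif scenario_id == 2:
        needed = ["baseline_mgmt", "baseline_reforest", "vulnerability"]
    elif scenario_id in (3, 4):
        needed = list(MANAGEMENT_LINES)
    else:
        raise ValueError(f"scenario id must be 1-4, got {scenario_id}")
    missing = [k for k in needed if k not in lines]
    if missing:
        raise ValueError(f"cost ledger is missing lines: {missing}")
    return float(_round_half_up(sum(lines[k] for k in needed)))


def benefits(
    cum_seq_tco2: float,
    harvested_volume_by_species: dict[str, float],
    prices: UnitPrices,
    years: float,
    species: SpeciesTable | None = None,
    scenario_id: int = 0,
    period: str = "",
) -> BenefitLedger:
    """Benefit ledger from cumulative sequestration and harvested volume.

    ``carbon_revenue = price · ΣCO₂ / years``; ``log_revenue = Σ_species
    volume · log price / years`` (both converted to 1e8 KRW/yr).
    """
    sp = species or species_table()
    carbon = prices.carbon_price_krw_per_tco2 * cum_seq_tco2 / years / 1e8
    log_rev = 0.0
    for code, vol in harvested_volume_by_species.items():
        if code not in sp:
            raise ValueError(f"no log price available for species {code!r}")
        log_rev += vol * sp[code].log_price_krw_m3
    log_rev /= years * 1e8
    return BenefitLedger(
        scenario_id=scenario_id, period=period, accumulation_years=int(years),
        carbon_revenue=carbon, log_revenue=log_rev,
    )


def cost_benefit_series(
    costs: pd.Series, benefits_series: pd.Series
) -> pd.DataFrame:
    """Per-year benefit/cost ratios with a fitted linear trend.

    Years with zero cost are flagged undefined (NaN ratio) and excluded
    from the trend fit.  Returns a frame with columns ``cost, benefit,
    ratio`` and attrs ``slope``/``intercept`` (ratio per year).
    """
    idx = costs.index.intersection(benefits_series.index)
    if len(idx) == 0:
        raise ValueError("cost and benefit series do not overlap")
    c = costs.loc[idx].astype(float)
    b = benefits_series.loc[idx].astype(float)
    ratio = b.where(c != 0) / c.where(c != 0)
    out = pd.DataFrame({"cost": c, "benefit": b, "ratio": ratio})
    valid = ratio.dropna()
    if len(valid) >= 2:
        slope, intercept = np.polyfit(valid.index.astype(float), valid.to_numpy(), 1)
    else:
        slope, intercept = np.nan, np.nan
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    return out


def krw_usd(amount_1e8_krw: float, rate: float) -> float:
    """Convert hundred-million KRW to million USD at ``rate`` KRW/USD."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_1e8_krw * 1e8 / rate / 1e6


# ---------------------------------------------------------------------------
# simulation-driven ledgers

def build_cost_ledger(
    scenario_id: int,
    period: str,
    accumulation_years: int,
    prices: UnitPrices,
    cum_thinned_ha: float = 0.0,
    cum_clearcut_ha: float = 0.0,
    avg_clearcut_volume: float = 0.0,
    clearcut_unit_cost_1e8_m3: float = 0.0,
    avg_reforest_unit_1e8_ha: float = 0.0,
    cum_vulnerable_ha: float = 0.0,
) -> CostLedger:
    """Assemble a scenario cost ledger from accumulated simulation outputs."""
    prices.validate()
    y = accumulation_years
    lines: dict[str, float] = {
        "baseline_mgmt": prices.tending_budget,
        "baseline_reforest": prices.reforestation_budget,
    }
    if scenario_id == 2:
        lines["vulnerability"] = line_cost(
            "vulnerability", cum_vulnerable_ha, prices.vulnerability_unit, y
        )
    if scenario_id in (3, 4):
        lines["thinning"] = line_cost("thinning", cum_thinned_ha, prices.thinning_unit, y)
        lines["clearcut"] = line_cost(
            "clearcut", cum_clearcut_ha, None, y,
            avg_volume=avg_clearcut_volume,
            unit_volume_cost=clearcut_unit_cost_1e8_m3,
        )
        lines["logging_overhead"] = line_cost(
            "logging_overhead", cum_clearcut_ha, prices.logging_overhead_unit, y
        )
        lines["yarding"] = line_cost(
            "yarding", cum_clearcut_ha, prices.yarding_unit, y,
            yarding_share=prices.yarding_share,
        )
        lines["reforestation"] = line_cost(
            "reforestation", cum_clearcut_ha, avg_reforest_unit_1e8_ha, y
        )
    return CostLedger(
        scenario_id=scenario_id, period=period,
        accumulation_years=y, lines=lines,
    )


def build_benefit_ledger(
    scenario_id: int,
    period: str,
    accumulation_years: int,
    prices: UnitPrices,
    cum_seq_tco2: float,
    harvested_volume_by_species: dict[str, float],
    species: SpeciesTable | None = None,
) -> BenefitLedger:
    return benefits(
        cum_seq_tco2, harvested_volume_by_species, prices,
        accumulation_years, species, scenario_id, period,
    )


# ---------------------------------------------------------------------------
# national reference ledger (Korea Forest Service budget analysis)

#: Reference cost line items (1e8 KRW/yr) by (scenario, period), as
#: published in the national budget analysis; used to validate the
#: ledger combination and rounding rules.
KOREA_REFERENCE_COST_LINES: dict[tuple[int, str], dict[str, float]] = {
    (1, "2030"): {"baseline_mgmt": 2090.0, "baseline_reforest": 1122.0},
    (1, "2050"): {"baseline_mgmt": 2090.0, "baseline_reforest": 1122.0},
    (2, "2030"): {
        "baseline_mgmt": 2090.0, "baseline_reforest": 1122.0,
        "vulnerability": 968.6,
    },
    (2, "2050"): {
        "baseline_mgmt": 2090.0, "baseline_reforest": 1122.0,
        "vulnerability": 1323.0,
    },
    (3, "2030"): {
        "thinning": 5217.0, "clearcut": 4.472, "logging_overhead": 32.83,
        "yarding": 1.462, "reforestation": 1143.0,
    },
    (3, "2050"): {
        "thinning": 3979.0, "clearcut": 4.430, "logging_overhead": 32.83,
        "yarding": 1.441, "reforestation": 1044.0,
    },
    (4, "2030"): {
        "thinning": 5217.0, "clearcut": 11.03, "logging_overhead": 65.14,
        "yarding": 3.343, "reforestation": 1926.0,
    },
    (4, "2050"): {
        "thinning": 3979.0, "clearcut": 12.91, "logging_overhead": 71.69,
        "yarding": 4.164, "reforestation": 2117.0,
    },
}

#: Published totals (1e8 KRW/yr) the reference lines must reproduce.
KOREA_REFERENCE_TOTALS: dict[tuple[int, str], int] = {
    (1, "2030"): 3212, (1, "2050"): 3212,
    (2, "2030"): 4181, (2, "2050"): 4535,
    (3, "2030"): 6399, (3, "2050"): 5062,
    (4, "2030"): 7223, (4, "2050"): 6185,
}

#: Reference accumulated areas (ha) behind the management cost lines.
KOREA_REFERENCE_AREAS: dict[str, dict[str, float]] = {
    "thinning_cum_ha": {"2030": 2_474_000.0, "2050": 4_402_900.0},
    "clearcut_cum_ha_s3": {"2030": 225_000.0, "2050": 525_000.0},
    "clearcut_cum_ha_s4": {"2030": 446_400.0, "2050": 1_146_400.0},
    "vulnerable_cum_ha": {"2030": 6_637_600.0, "2050": 21_154_400.0},
}

#: Reference per-ha reforestation averages (1e8 KRW/ha) by scenario/period.
KOREA_REFERENCE_REFOREST_UNIT: dict[tuple[int, str], float] = {
    (3, "2030"): 0.0762, (3, "2050"): 0.0696,
    (4, "2030"): 0.0647, (4, "2050"): 0.0646,
}
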