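"""IPCC stock-change carbon accounting.

Carbon stock per hectare converts growing stock volume with
country-specific factors::

    C = V · D · BEF · (1 + RS) · CF        [tC/ha]

with basic wood density ``D`` (t/m³), biomass expansion factor ``BEF``,
root/shoot ratio ``RS`` (the ``1 + RS`` term adds belowground live
biomass) and carbon fraction ``CF = 0.5``.  Annual stock change is the
year-over-year difference, and CO₂ sequestration applies the molar
ratio 44/12.  Dead organic matter, soil carbon and harvested wood
products are outside the accounted pools.

National sequestration is computed from the *biological* stock change:
the standing-stock difference with harvest removals credited back (net
of mortality, gross of harvest).  Harvested carbon is neither counted
as an instantaneous emission nor tracked further — consistent with an
accounting that excludes harvest-related emissions.  The strict
standing-stock alternative (harvest drops flowing through the stock
change) is available via ``net_of_harvest=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .management import SimulationResult
from .params import SpeciesTable, species_table

__all__ = [
    "CARBON_FRACTION",
    "CO2_PER_C",
    "CarbonLedger",
    "carbon_stock_per_ha",
    "annual_stock_change",
    "co2_sequestration",
    "build_carbon_ledger",
    "national_sequestration",
    "decade_mean",
    "DECADE_WINDOWS",
]

#: IPCC default carbon fraction of dry biomass.
CARBON_FRACTION = 0.5

#: Stoichiometric mass ratio of CO₂ to C.
CO2_PER_C = 44.0 / 12.0

#: Named analysis windows (inclusive year ranges).
DECADE_WINDOWS = {"base": (2010, 2015), "2030s": (2026, 2035), "2050s": (2046, 2055)}


def carbon_stock_per_ha(v, species) -> float | np.ndarray:
    """Carbon stock (tC/ha) for a growing stock volume ``v`` (m³/ha)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("carbon_stock_per_ha: volume must be >= 0")
    c = (
        v * species.wood_density * species.bef
        * (1.0 + species.root_shoot) * CARBON_FRACTION
    )
    return c if c.ndim else float(c)


def annual_stock_change(cs_t, cs_t1, t: int, t1: int):
    """Annual change in carbon stock (tC/ha/yr) between years t < t1."""
    if t1 <= t:
        raise ValueError(f"annual_stock_change: t1 ({t1}) must exceed t ({t})")
    return (np.asarray(cs_t1, dtype=float) - np.asarray(cs_t, dtype=float)) / (t1 - t)


def co2_sequestration(dcs):
    """Convert a carbon stock change (tC) to CO₂ (t), ratio 44/12."""
    return np.asarray(dcs, dtype=float) * CO2_PER_C


@dataclass
class CarbonLedger:
    """Per-cell and national carbon series for one scenario run."""

    years: np.ndarray
    cell_stock: np.ndarray  # (n_years, n_cells) tC/ha
    national_stock_tC: pd.Series  # total tC per year
    national_seq_tCO2: pd.Series  # tCO2/yr, biological stock change
    national_seq_net_tCO2: pd.Series  # tCO2/yr, harvest drops netted
    cell_seq_tCO2_ha: np.ndarray  # (n_years-1, n_cells) tCO2/ha/yr, biological


def _species_factor_matrix(result: SimulationResult, sp: SpeciesTable) -> np.ndarray:
    """Per-cell-year conversion factor C/V = D·BEF·(1+RS)·CF."""
    factors = {
        p.code: p.wood_density * p.bef * (1.0 + p.root_shoot) * CARBON_FRACTION
        for p in sp
    }
    lut = np.vectorize(factors.__getitem__, otypes=[float])
    return lut(result.cell_species.astype(str))


def build_carbon_ledger(
    result: SimulationResult, species: SpeciesTable | None = None
) -> CarbonLedger:
    """Carbon bookkeeping for a scenario run.

    The biological sequestration of the interval t → t+1 credits the
    harvested volume back at the factors of the species standing at t;
    the net variant is the plain stock difference.
    """
    sp = species or species_table()
    fac = _species_factor_matrix(result, sp)
    stock = result.cell_volumes * fac  # tC/ha
    area = result.cell_area
    national_stock = pd.Series(stock.sum(axis=1) * area, index=result.years)

    dstock = np.diff(stock, axis=0)  # tC/ha/yr (consecutive years)
    harvested_c = result.cell_harvested * fac[:-1]
    bio = dstock + harvested_c
    seq_bio = pd.Series(bio.sum(axis=1) * area * CO2_PER_C, index=result.years[1:])
    seq_net = pd.Series(dstock.sum(axis=1) * area * CO2_PER_C, index=result.years[1:])
    return CarbonLedger(
        years=result.years,
        cell_stock=stock,
        national_stock_tC=national_stock,
        national_seq_tCO2=seq_bio,
        national_seq_net_tCO2=seq_net,
        cell_seq_tCO2_ha=bio * CO2_PER_C,
    )


def national_sequestration(
    result: SimulationResult,
    species: SpeciesTable | None = None,
    net_of_harvest: bool = False,
) -> pd.Series:
    """National CO₂ sequestration series (tCO₂/yr) for a scenario run."""
    ledger = build_carbon_ledger(result, species)
    return ledger.national_seq_net_tCO2 if net_of_harvest else ledger.national_seq_tCO2


def decade_mean(series: pd.Series, window) -> float:
    """Arithmetic mean of an annual series over a named or explicit
    inclusive year window ('base' = 2010-2015, '2030s' = 2026-2035,
    '2050s' = 2046-2055)."""
    if isinstance(window, str):
        try:
            lo, hi = DECADE_WINDOWS[window]
        except KeyError:
            raise ValueError(
                f"unknown window {window!r}; known: {sorted(DECADE_WINDOWS)}"
            ) from None
    else:
        lo, hi = window
    wanted = list(range(int(lo), int(hi) + 1))
    missing = [y for y in wanted if y not in series.index]
    if missing:
        raise ValueError(f"series does not cover window years: {missing}")
    return float(series.loc[wanted].mean())
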