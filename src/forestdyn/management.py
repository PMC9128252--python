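"""Scenario engine and silvicultural decision algorithm.

Four study scenarios combine a climate mode with a management intensity:

==========  ========  ==============================================
scenario    climate   management
==========  ========  ==============================================
1           baseline  none ("overprotection")
2           rcp85     none
3           rcp85     clear-cut ~15,000 ha/yr (national scale),
                      30% crown thinning at ages 20 and 40,
                      climate-adapted reforestation
4           rcp85     as 3 with clear-cut ~35,000 ha/yr
==========  ========  ==============================================

Clear-cutting follows the statutory final cutting age: among manageable
cells at or above their species' cutting age, the oldest are cut first,
ties broken by higher volume then lower cell id, until the annual area
quota is filled or the eligible supply is exhausted.  Cut cells are
replanted with a species suited to the projected local temperature.
Thinning removes 30% of stems from the highest-volume manageable cells
whose age falls in a ±1-yr window around 20 or 40, up to its own annual
area quota; each stand is thinned at most once per window.

National quotas are expressed as annual fractions of the managed
landscape's area, so a desk-scale landscape reproduces the national
area ratios (15,000 or 35,000 ha/yr and the thinning programme on a
6,056,400-ha estate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import growth
from .params import SpeciesTable, species_table
from .synthetic import ClimateScenario, Landscape

__all__ = [
    "ScenarioConfig",
    "HarvestRecord",
    "SimulationResult",
    "SuitabilityRule",
    "DEFAULT_SUITABILITY_RULE",
    "NATIONAL_FOREST_AREA_HA",
    "potential_clearcut_area",
    "schedule_clearcut",
    "apply_clearcut",
    "schedule_thinning",
    "apply_thinning",
    "choose_reforestation_species",
    "run_scenario",
    "scenario_preset",
]

#: Stocked forest area of the national analysis (ha); used to scale the
#: published annual quotas down to synthetic landscapes.
NATIONAL_FOREST_AREA_HA = 6_056_400.0

#: Published annual clear-cut quotas (ha/yr at national scale).
NATIONAL_CLEARCUT_HA = {3: 15_000.0, 4: 35_000.0}

#: National cumulative thinned area over the first 15 management years,
#: back-calculated from the published cost ledger; fixes the annual
#: thinning quota ratio.
NATIONAL_THINNING_CUM_HA_15YR = 2_474_000.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Climate mode plus management intensity for one scenario."""

    id: int
    climate_mode: str  # 'baseline' or 'rcp85'
    clearcut_frac: float = 0.0  # fraction of landscape area per year
    thin_enabled: bool = False
    thin_ages: tuple[int, ...] = (20, 40)
    thin_fraction: float = 0.30
    thin_frac_area: float = 0.0  # fraction of landscape area per year
    reforest: bool = False
    management_start_year: int = 2016

    def __post_init__(self):
        if self.climate_mode not in ("baseline", "rcp85"):
            raise ValueError(f"unknown climate mode {self.climate_mode!r}")
        if self.clearcut_frac < 0 or self.thin_frac_area < 0:
            raise ValueError("quota fractions must be >= 0")
        if self.id in (1, 2) and (self.clearcut_frac or self.thin_enabled or self.reforest):
            raise ValueError(f"scenario {self.id} is no-management by definition")

    @property
    def managed(self) -> bool:
        return self.clearcut_frac > 0 or self.thin_enabled

    def clearcut_quota_ha(self, total_area: float) -> float:
        return self.clearcut_frac * total_area

    def thinning_quota_ha(self, total_area: float) -> float:
        return self.thin_frac_area * total_area


def scenario_preset(scenario_id: int, **overrides) -> ScenarioConfig:
    """Build one of the four study scenarios with national quota ratios."""
    thin_frac = NATIONAL_THINNING_CUM_HA_15YR / 15.0 / NATIONAL_FOREST_AREA_HA
    presets = {
        1: dict(id=1, climate_mode="baseline"),
        2: dict(id=2, climate_mode="rcp85"),
        3: dict(
            id=3, climate_mode="rcp85",
            clearcut_frac=NATIONAL_CLEARCUT_HA[3] / NATIONAL_FOREST_AREA_HA,
            thin_enabled=True, thin_frac_area=thin_frac, reforest=True,
        ),
        4: dict(
            id=4, climate_mode="rcp85",
            clearcut_frac=NATIONAL_CLEARCUT_HA[4] / NATIONAL_FOREST_AREA_HA,
            thin_enabled=True, thin_frac_area=thin_frac, reforest=True,
        ),
    }
    if scenario_id not in presets:
        raise ValueError(f"scenario id must be 1-4, got {scenario_id}")
    cfg = presets[scenario_id]
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


@dataclass(frozen=True)
class HarvestRecord:
    """One harvest action on one cell in one year."""

    year: int
    cell_id: int
    action: str  # 'clearcut' or 'thinning'
    area_ha: float
    removed_volume_m3: float
    species: str

    def __post_init__(self):
        if self.removed_volume_m3 < 0:
            raise ValueError("removed volume must be >= 0")
        if self.action not in ("clearcut", "thinning"):
            raise ValueError(f"unknown harvest action {self.action!r}")


@dataclass(frozen=True)
class SuitabilityRule:
    """Temperature bands mapping projected climate to planting species.

    ``bands`` is a sequence of ``(upper_bound_degC, keep, fallback)``
    sorted by upper bound, the last bound being ``inf``.  A cell whose
    projected temperature ``t`` satisfies ``t < upper`` of band *i* (and
    not of any earlier band) keeps its current species if that species
    is in ``keep``, else is replanted with ``fallback``.  A temperature
    exactly on a boundary belongs to the warmer band (half-open
    intervals).
    """

    bands: tuple[tuple[float, frozenset, str], ...]

    def __post_init__(self):
        uppers = [b[0] for b in self.bands]
        if uppers != sorted(uppers):
            raise ValueError("suitability bands must be sorted by upper bound")
        if not np.isinf(uppers[-1]):
            raise ValueError(
                "suitability bands leave a gap: last upper bound must be +inf"
            )

    def choose(self, current_species: str, temp: float) -> str:
        for upper, keep, fallback in self.bands:
            if temp < upper:
                return current_species if current_species in keep else fallback
        raise AssertionError("unreachable: bands cover the whole line")


#: Default suitability: cool sites keep/receive the montane conifers,
#: temperate sites the pines, warm sites shift to the oaks (conifer
#: growth declines under warming).
DEFAULT_SUITABILITY_RULE = SuitabilityRule(
    bands=(
        (9.0, frozenset({"larch", "korean_pine"}), "larch"),
        (11.5, frozenset({"red_pine", "korean_pine", "larch", "mixed_a", "mixed_b"}), "red_pine"),
        (float("inf"), frozenset({"cork_oak", "mongolian_oak"}), "mongolian_oak"),
    )
)


@dataclass
class SimulationResult:
    """Output of one scenario run.

    Per-year arrays are indexed by ``years``; per-cell matrices have
    shape ``(n_years, n_cells)`` (state at the end of each year) or
    ``(n_years - 1, n_cells)`` for interval quantities (the step from
    year ``t`` to ``t+1``).
    """

    scenario: ScenarioConfig
    years: np.ndarray
    cell_ids: np.ndarray
    cell_area: float
    manageable: np.ndarray
    # end-of-year state
    cell_volumes: np.ndarray  # m3/ha
    cell_species: np.ndarray  # (n_years, n_cells) of species codes
    cell_ages: np.ndarray
    # interval quantities (per ha of the cell)
    cell_harvested: np.ndarray  # m3/ha removed in the interval
    cell_gross_growth: np.ndarray  # m3/ha pre-mortality growth
    cell_mortality: np.ndarray  # m3/ha lost to mortality
    harvest_records: list[HarvestRecord] = field(default_factory=list)
    final_landscape: Landscape | None = None
    climate: ClimateScenario | None = None
    seed: int | None = None
    config_hash: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    def national_volume(self) -> pd.Series:
        """Area-weighted mean standing volume (m³/ha) per year."""
        return pd.Series(self.cell_volumes.mean(axis=1), index=self.years)

    def cell_growth(self) -> np.ndarray:
        """Per-cell annual growth (m³/ha/yr): stock change with harvest
        removals credited back (net of mortality, gross of harvest)."""
        return np.diff(self.cell_volumes, axis=0) + self.cell_harvested

    def national_growth(self) -> pd.Series:
        """Area-weighted mean annual growth (m³/ha/yr), indexed by the
        end year of each interval."""
        return pd.Series(self.cell_growth().mean(axis=1), index=self.years[1:])

    def harvest_frame(self) -> pd.DataFrame:
        cols = ["year", "cell_id", "action", "area_ha", "removed_volume_m3", "species"]
        if not self.harvest_records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([r.__dict__ for r in self.harvest_records])[cols]

    def cumulative_harvest_area(self, action: str, through_year: int) -> float:
        return sum(
            r.area_ha for r in self.harvest_records
            if r.action == action and r.year <= through_year
        )


# ---------------------------------------------------------------------------
# harvest scheduling

def _cutting_ages(cells: pd.DataFrame, sp: SpeciesTable) -> np.ndarray:
    return np.array([sp[s].cutting_age for s in cells["species"]], dtype=float)


def potential_clearcut_area(landscape: Landscape, species: SpeciesTable | None = None) -> float:
    """Total area (ha) of manageable cells at or above their statutory
    final cutting age."""
    sp = species or species_table()
    c = landscape.cells
    eligible = c["manageable"].to_numpy() & (
        c["age"].to_numpy() >= _cutting_ages(c, sp)
    )
    return float(eligible.sum() * landscape.cell_area)


def schedule_clearcut(
    landscape: Landscape,
    quota_ha: float,
    species: SpeciesTable | None = None,
) -> list[int]:
    """Select cells for clear-cut up to the annual area quota.

    Eligible cells (manageable, age ≥ species cutting age) are ranked by
    age descending, then volume descending, then cell id ascending, and
    taken while the selected area is below the quota (so the selection
    may overshoot by at most one cell).  Returns selected cell ids.
    """
    if quota_ha < 0:
        raise ValueError("quota_ha must be >= 0")
    sp = species or species_table()
    c = landscape.cells
    eligible = c[
        c["manageable"].to_numpy() & (c["age"].to_numpy() >= _cutting_ages(c, sp))
    ]
    ranked = eligible.sort_values(
        ["age", "volume", "cell_id"], ascending=[False, False, True], kind="mergesort"
    )
    selected: list[int] = []
    area = 0.0
    for cid in ranked["cell_id"]:
        if area >= quota_ha:
            break
        selected.append(int(cid))
        area += landscape.cell_area
    return selected


def apply_clearcut(
    cell: growth.GridCellState,
    reforest_species: str,
    species: SpeciesTable | None = None,
    cell_area: float = 100.0,
    year: int = 0,
) -> tuple[HarvestRecord, growth.GridCellState]:
    """Clear-cut one cell and replant it.

    The record captures the whole pre-cut standing volume times the cell
    area; the new state restarts at age 0 with the planting density of
    the replanted species and zero volume.
    """
    sp = species or species_table()
    if not cell.manageable:
        raise ValueError(f"cell {cell.cell_id} is restricted: clear-cut not allowed")
    if cell.age < sp[cell.species].cutting_age:
        raise ValueError(
            f"cell {cell.cell_id}: age {cell.age} below cutting age "
            f"{sp[cell.species].cutting_age}"
        )
    rec = HarvestRecord(
        year=year, cell_id=cell.cell_id, action="clearcut",
        area_ha=cell_area, removed_volume_m3=cell.volume * cell_area,
        species=cell.species,
    )
    new = replace(
        cell, species=reforest_species, age=0.0,
        nha=sp[reforest_species].planting_density,
        dbh=0.0, hm=growth.BREAST_HEIGHT, volume=0.0,
    )
    return rec, new


def schedule_thinning(
    landscape: Landscape,
    thin_ages: Sequence[int] = (20, 40),
    annual_quota_ha: float = 0.0,
    age_window: int = 1,
    already_thinned: np.ndarray | None = None,
) -> list[int]:
    """Select cells for crown thinning up to the annual area quota.

    Eligible cells are manageable, within ``±age_window`` years of one of
    the thinning ages, and not flagged in ``already_thinned``.  They are
    ranked by volume descending (ties by cell id) and taken while the
    selected area is below the quota.
    """
    if annual_quota_ha < 0:
        raise ValueError("annual_quota_ha must be >= 0")
    c = landscape.cells
    age = c["age"].to_numpy()
    in_window = np.zeros(len(c), dtype=bool)
    for t in thin_ages:
        in_window |= np.abs(age - t) <= age_window
    mask = c["manageable"].to_numpy() & in_window
    if already_thinned is not None:
        mask &= ~np.asarray(already_thinned, dtype=bool)
    ranked = c[mask].sort_values(
        ["volume", "cell_id"], ascending=[False, True], kind="mergesort"
    )
    selected: list[int] = []
    area = 0.0
    for cid in ranked["cell_id"]:
        if area >= annual_quota_ha:
            break
        selected.append(int(cid))
        area += landscape.cell_area
    return selected


def apply_thinning(
    cell: growth.GridCellState,
    fraction: float = 0.30,
    species: SpeciesTable | None = None,
    cell_area: float = 100.0,
    year: int = 0,
) -> tuple[HarvestRecord, growth.GridCellState]:
    """Remove a stem fraction from one cell (stand-mean crown thinning).

    Density drops by ``fraction`` with mean DBH unchanged; since the
    volume equation is linear in density, post-thin volume is exactly
    ``(1 − fraction)`` times the pre-thin volume.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("thinning fraction must be in (0, 1)")
    if not cell.manageable:
        raise ValueError(f"cell {cell.cell_id} is restricted: thinning not allowed")
    sp = species or species_table()
    new_nha = cell.nha * (1.0 - fraction)
    new_vol = growth.stand_volume(cell.dbh, cell.hm, new_nha, sp[cell.species])
    rec = HarvestRecord(
        year=year, cell_id=cell.cell_id, action="thinning",
        area_ha=cell_area, removed_volume_m3=(cell.volume - new_vol) * cell_area,
        species=cell.species,
    )
    return rec, replace(cell, nha=new_nha, volume=new_vol)


def choose_reforestation_species(
    cell: growth.GridCellState,
    projected_temp: float,
    rule: SuitabilityRule = DEFAULT_SUITABILITY_RULE,
) -> str:
    """Pick the planting species for a cut cell from the projected local
    mean temperature in the cut year (deterministic band lookup)."""
    return rule.choose(cell.species, projected_temp)


# ---------------------------------------------------------------------------
# scenario engine

def _config_hash(cfg: ScenarioConfig, seed) -> str:
    payload = json.dumps({"scenario": cfg.__dict__, "seed": seed},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_scenario(
    landscape: Landscape,
    climate: ClimateScenario,
    scenario: ScenarioConfig,
    species: SpeciesTable | None = None,
    end_year: int | None = None,
    suitability: SuitabilityRule = DEFAULT_SUITABILITY_RULE,
    seed: int | None = None,
) -> SimulationResult:
    """Run one scenario: an annual loop of grow → thin → clear-cut.

    The landscape's calendar year must match the first climate year.
    Growth uses the temperature anomaly of the year being grown into;
    management acts after growth, only from the scenario's management
    start year on.  Returns the full per-cell trajectory plus the
    harvest ledger.
    """
    sp = species or species_table()
    if climate.mode != scenario.climate_mode:
        raise ValueError(
            f"climate mode {climate.mode!r} does not match scenario "
            f"{scenario.id} ({scenario.climate_mode!r})"
        )
    if climate.temps.shape[1] != landscape.n_cells:
        raise ValueError("climate grid does not match landscape")
    if landscape.year != int(climate.years[0]):
        raise ValueError(
            f"landscape year {landscape.year} != first climate year {climate.years[0]}"
        )
    end_year = int(end_year if end_year is not None else climate.years[-1])
    years = np.arange(landscape.year, end_year + 1)
    n = landscape.n_cells

    c = landscape.cells
    cell_ids = c["cell_id"].to_numpy().copy()
    manageable = c["manageable"].to_numpy().copy()
    age = c["age"].to_numpy(dtype=float).copy()
    si = c["si"].to_numpy(dtype=float).copy()
    nha = c["nha"].to_numpy(dtype=float).copy()
    dbh = c["dbh"].to_numpy(dtype=float).copy()
    hm = c["hm"].to_numpy(dtype=float).copy()
    vol = c["volume"].to_numpy(dtype=float).copy()
    codes = c["species"].to_numpy().copy().astype(object)

    ny = len(years)
    volumes = np.zeros((ny, n))
    species_mat = np.empty((ny, n), dtype=object)
    ages = np.zeros((ny, n))
    harvested = np.zeros((ny - 1, n))
    gross = np.zeros((ny - 1, n))
    mort = np.zeros((ny - 1, n))
    volumes[0], species_mat[0], ages[0] = vol, codes, age
    thinned_flags = np.zeros(n, dtype=bool)  # reset when the age window is left
    records: list[HarvestRecord] = []
    quota_cc = scenario.clearcut_quota_ha(landscape.total_area)
    quota_thin = scenario.thinning_quota_ha(landscape.total_area)
    pos = {int(cid): i for i, cid in enumerate(cell_ids)}

    def state_of(i: int) -> growth.GridCellState:
        return growth.GridCellState(
            cell_id=int(cell_ids[i]), species=codes[i], age=age[i], si=si[i],
            nha=nha[i], dbh=dbh[i], hm=hm[i], volume=vol[i],
            manageable=bool(manageable[i]),
        )

    def write_back(i: int, s: growth.GridCellState) -> None:
        codes[i], age[i], nha[i] = s.species, s.age, s.nha
        dbh[i], hm[i], vol[i] = s.dbh, s.hm, s.volume

    for step, year in enumerate(years[1:]):
        anom = (
            climate.anomaly(year)
            if climate.mode == "rcp85"
            else np.zeros(n)
        )
        # 1. grow
        for code in np.unique(codes.astype(str)):
            m = codes == code
            a, nh, d, h, v, diag = growth.step_arrays(
                age[m], si[m], nha[m], dbh[m], hm[m], anom[m], sp[code]
            )
            age[m], nha[m], dbh[m], hm[m], vol[m] = a, nh, d, h, v
            gross[step, m] = diag.gross_growth
            mort[step, m] = diag.mortality_volume

        manage = scenario.managed and year >= scenario.management_start_year
        if manage:
            snapshot = pd.DataFrame(
                {
                    "cell_id": cell_ids, "species": codes, "age": age,
                    "volume": vol, "manageable": manageable,
                }
            )
            ls_now = Landscape(
                cells=snapshot.assign(
                    row=landscape.cells["row"].to_numpy(),
                    col=landscape.cells["col"].to_numpy(),
                    si=si, nha=nha, dbh=dbh, hm=hm,
                ),
                cell_area=landscape.cell_area, year=int(year),
            )
            # 2. thinning
            if scenario.thin_enabled and quota_thin > 0:
                in_window = np.zeros(n, dtype=bool)
                for t in scenario.thin_ages:
                    in_window |= np.abs(age - t) <= 1
                thinned_flags &= in_window  # forget flags once out of window
                for cid in schedule_thinning(
                    ls_now, scenario.thin_ages, quota_thin,
                    already_thinned=thinned_flags,
                ):
                    i = pos[cid]
                    rec, s = apply_thinning(
                        state_of(i), scenario.thin_fraction, sp,
                        landscape.cell_area, int(year),
                    )
                    write_back(i, s)
                    thinned_flags[i] = True
                    harvested[step, i] += rec.removed_volume_m3 / landscape.cell_area
                    records.append(rec)
                ls_now.cells.loc[:, "volume"] = vol
                ls_now.cells.loc[:, "age"] = age
            # 3. clear-cut + reforestation
            if quota_cc > 0:
                for cid in schedule_clearcut(ls_now, quota_cc, sp):
                    i = pos[cid]
                    cell = state_of(i)
                    if scenario.reforest:
                        new_sp = choose_reforestation_species(
                            cell, float(climate.temp(year)[i]), suitability
                        )
                    else:
                        new_sp = cell.species
                    rec, s = apply_clearcut(
                        cell, new_sp, sp, landscape.cell_area, int(year)
                    )
                    write_back(i, s)
                    thinned_flags[i] = False
                    harvested[step, i] += rec.removed_volume_m3 / landscape.cell_area
                    records.append(rec)

        volumes[step + 1] = vol
        species_mat[step + 1] = codes
        ages[step + 1] = age

    final_cells = landscape.cells.copy()
    final_cells["species"] = codes
    final_cells["age"] = age
    final_cells["si"] = si
    final_cells["nha"] = nha
    final_cells["dbh"] = dbh
    final_cells["hm"] = hm
    final_cells["volume"] = vol
    final = replace(landscape, cells=final_cells, year=int(years[-1]))

    return SimulationResult(
        scenario=scenario, years=years, cell_ids=cell_ids,
        cell_area=landscape.cell_area, manageable=manageable,
        cell_volumes=volumes, cell_species=species_mat, cell_ages=ages,
        cell_harvested=harvested, cell_gross_growth=gross, cell_mortality=mort,
        harvest_records=records, final_landscape=final, climate=climate,
        seed=seed, config_hash=_config_hash(scenario, seed),
    )
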