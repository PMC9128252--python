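"""End-to-end orchestration: config → landscape → scenarios → reports.

A single run configuration (YAML or dict) drives the whole pipeline:
generate the synthetic landscape and climate, run the four scenarios
(plus baseline-climate twins of the managed scenarios for sensitivity
pairing), account carbon, build cost/benefit ledgers for the 2030 and
2050 accounting periods, and write plain-text artifacts (CSV series,
ASCII-grid rasters, a JSON summary).  Every output is a pure function
of (config, seed); the config hash is stamped into each CSV header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import economics
from .carbon import CarbonLedger, build_carbon_ledger, decade_mean
from .management import (
    ScenarioConfig,
    SimulationResult,
    run_scenario,
    scenario_preset,
)
from .params import SpeciesTable, species_table
from .synthetic import (
    ClimateScenario,
    Landscape,
    generate_climate,
    generate_landscape,
    write_ascii_grid,
)
from .vulnerability import (
    SensitivityMap,
    growth_sensitivity,
    vulnerable_cumulative_area,
)

__all__ = ["RunConfig", "ScenarioOutput", "run_all", "run", "report"]

log = logging.getLogger("forestdyn")

#: Accounting periods: label -> (through-year, accumulation years).
PERIODS = {"2030": (2030, 15), "2050": (2050, 35)}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    n_cells: int = 10_000
    species_mix: dict | None = None
    age_dist: dict | None = None
    si_range: tuple[float, float] = (10.0, 18.0)
    manageable_fraction: float = 0.5248
    cell_area: float = 100.0
    start_year: int = 2010
    end_year: int = 2055
    warming_rate: float = 0.55
    noise_sd: float = 0.3
    scenarios: tuple[int, ...] = (1, 2, 3, 4)
    raster_years: tuple[int, ...] = (2030, 2050)
    prices: economics.UnitPrices = field(default_factory=economics.UnitPrices)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kw = dict(raw)
        if "prices" in kw and isinstance(kw["prices"], dict):
            kw["prices"] = economics.UnitPrices(**kw["prices"])
        for key in ("si_range", "scenarios", "raster_years"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        if "age_dist" in kw and kw["age_dist"]:
            kw["age_dist"] = {int(k): float(v) for k, v in kw["age_dist"].items()}
        return cls(**kw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScenarioOutput:
    """Everything computed for one scenario."""

    result: SimulationResult
    carbon: CarbonLedger
    sensitivity: SensitivityMap | None
    costs: dict[str, economics.CostLedger]
    benefits: dict[str, economics.BenefitLedger]


def _cost_inputs(
    result: SimulationResult,
    sp: SpeciesTable,
    through_year: int,
) -> dict:
    """Accumulated harvest quantities feeding the cost ledger."""
    recs = [r for r in result.harvest_records if r.year <= through_year]
    thin_ha = sum(r.area_ha for r in recs if r.action == "thinning")
    cc = [r for r in recs if r.action == "clearcut"]
    cc_ha = sum(r.area_ha for r in cc)
    cc_vol = sum(r.removed_volume_m3 for r in cc)
    avg_vol = cc_vol / cc_ha if cc_ha else 0.0
    if cc_vol > 0:
        unit_cost = sum(
            r.removed_volume_m3
            * (sp[r.species].felling_cost_krw_m3 + sp[r.species].transport_cost_krw_m3)
            for r in cc
        ) / cc_vol / 1e8
    else:
        unit_cost = 0.0
    # replanted species = species standing after each clearcut year
    if cc_ha > 0:
        reforest_total = 0.0
        pos = {int(cid): i for i, cid in enumerate(result.cell_ids)}
        yindex = {int(y): i for i, y in enumerate(result.years)}
        for r in cc:
            new_code = result.cell_species[yindex[r.year], pos[r.cell_id]]
            reforest_total += sp[str(new_code)].reforest_price_krw_ha * r.area_ha
        reforest_unit = reforest_total / cc_ha / 1e8
    else:
        reforest_unit = 0.0
    return dict(
        cum_thinned_ha=thin_ha,
        cum_clearcut_ha=cc_ha,
        avg_clearcut_volume=avg_vol,
        clearcut_unit_cost_1e8_m3=unit_cost,
        avg_reforest_unit_1e8_ha=reforest_unit,
    )


def _benefit_inputs(
    result: SimulationResult,
    carbon: CarbonLedger,
    start_year: int,
    through_year: int,
) -> tuple[float, dict[str, float]]:
    seq = carbon.national_seq_tCO2
    window = seq.loc[(seq.index > start_year) & (seq.index <= through_year)]
    cum_seq = float(np.clip(window, 0.0, None).sum())
    vols: dict[str, float] = {}
    for r in result.harvest_records:
        if start_year < r.year <= through_year:
            vols[r.species] = vols.get(r.species, 0.0) + r.removed_volume_m3
    return cum_seq, vols


def run_all(
    config: RunConfig, species: SpeciesTable | None = None
) -> dict[int, ScenarioOutput]:
    """Run the configured scenarios and build all derived ledgers."""
    sp = species or species_table()
    log.info("generating landscape: %d cells, seed %d", config.n_cells, config.seed)
    landscape = generate_landscape(
        n_cells=config.n_cells,
        species_mix=config.species_mix,
        age_dist=config.age_dist,
        si_range=tuple(config.si_range),
        manageable_fraction=config.manageable_fraction,
        seed=config.seed,
        cell_area=config.cell_area,
        year=config.start_year,
        species=sp,
    )
    climates: dict[str, ClimateScenario] = {
        mode: generate_climate(
            landscape, mode, config.start_year, config.end_year,
            warming_rate=config.warming_rate, noise_sd=config.noise_sd,
            seed=config.seed,
        )
        for mode in ("baseline", "rcp85")
    }

    outputs: dict[int, ScenarioOutput] = {}
    reference: SimulationResult | None = None  # current-climate no-management run

    def reference_run() -> SimulationResult:
        nonlocal reference
        if reference is None:
            reference = run_scenario(
                landscape.copy(), climates["baseline"], scenario_preset(1), sp,
                seed=config.seed,
            )
        return reference

    for sid in config.scenarios:
        cfg = scenario_preset(sid)
        log.info("running scenario %d (%s)", sid, cfg.climate_mode)
        if sid == 1:
            result = reference_run()
        else:
            result = run_scenario(
                landscape.copy(), climates[cfg.climate_mode], cfg, sp,
                seed=config.seed,
            )
        carbon = build_carbon_ledger(result, sp)

        sens = None
        if cfg.climate_mode == "rcp85":
            # sensitivity is graded against the current-climate,
            # no-management reference; short horizons fall back to the
            # last simulated decade
            if config.end_year >= 2055:
                window = "2050s"
            else:
                window = (max(config.start_year + 1, config.end_year - 9),
                          config.end_year)
            sens = growth_sensitivity(reference_run(), result, window=window)

        costs: dict[str, economics.CostLedger] = {}
        bens: dict[str, economics.BenefitLedger] = {}
        mgmt_start = cfg.management_start_year - 1
        for label, (through, acc_years) in PERIODS.items():
            kw = _cost_inputs(result, sp, through)
            if sid == 2 and sens is not None:
                # the vulnerability cost line accrues every year a cell is
                # vulnerable: accumulated area-years through the period end
                thr = min(through, int(result.years[-1]))
                kw["cum_vulnerable_ha"] = float(
                    sens.cumulative_area_years.loc[:thr].iloc[-1]
                )
            costs[label] = economics.build_cost_ledger(
                sid, label, acc_years, config.prices, **kw
            )
            cum_seq, vols = _benefit_inputs(result, carbon, mgmt_start, through)
            bens[label] = economics.build_benefit_ledger(
                sid, label, acc_years, config.prices, cum_seq, vols, sp
            )
        outputs[sid] = ScenarioOutput(
            result=result, carbon=carbon, sensitivity=sens,
            costs=costs, benefits=bens,
        )
    return outputs


def _interval_decade_mean(series: pd.Series, period: str) -> float:
    """Decade mean of an interval series, clipped to the simulated
    coverage (the first defined year is the end of the first simulated
    step; short horizons truncate the window)."""
    from .carbon import DECADE_WINDOWS

    lo, hi = DECADE_WINDOWS[period]
    lo = max(lo, int(series.index.min()))
    hi = min(hi, int(series.index.max()))
    if hi < lo:
        return float("nan")
    return decade_mean(series, (lo, hi))


def report(outputs: dict[int, ScenarioOutput]) -> pd.DataFrame:
    """Comparison table: one row per scenario × period.

    Columns: decade-mean growth (m³/ha/yr), decade-mean sequestration
    (tCO₂/yr), total cost and benefit (1e8 KRW/yr where applicable).
    """
    missing = [s for s in (1, 2, 3, 4) if s not in outputs]
    if missing:
        raise ValueError(f"report needs all four scenarios; missing {missing}")
    rows = []
    for sid, out in sorted(outputs.items()):
        growth_series = out.result.national_growth()
        seq = out.carbon.national_seq_tCO2
        for period in ("base", "2030s", "2050s"):
            row = {
                "scenario": sid,
                "period": period,
                "growth_m3_ha_yr": _interval_decade_mean(growth_series, period),
                "seq_tco2_yr": _interval_decade_mean(seq, period),
            }
            ledger_key = {"2030s": "2030", "2050s": "2050"}.get(period)
            if ledger_key:
                row["cost_1e8krw_yr"] = out.costs[ledger_key].total()
                row["benefit_1e8krw_yr"] = out.benefits[ledger_key].total()
            rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, header_meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_meta + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run(config_path_or_cfg, out_dir) -> Path:
    """Execute a full configured run and write artifacts to ``out_dir``.

    Writes per-scenario annual series and harvest logs (CSV), ASCII-grid
    volume rasters at the configured years, ledger CSVs and a JSON
    summary with the decade means.  Returns the output directory.
    """
    if isinstance(config_path_or_cfg, RunConfig):
        config = config_path_or_cfg
    elif isinstance(config_path_or_cfg, dict):
        config = RunConfig.from_dict(config_path_or_cfg)
    else:
        config = RunConfig.from_yaml(config_path_or_cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = f"# forestdyn config_hash={config.hash()} seed={config.seed}"
    outputs = run_all(config)

    ledger_rows = []
    summary: dict = {"config_hash": config.hash(), "seed": config.seed, "scenarios": {}}
    for sid, o in outputs.items():
        res = o.result
        growth_series = res.national_growth()
        seq = o.carbon.national_seq_tCO2
        series = pd.DataFrame(
            {
                "year": res.years,
                "national_volume_m3_ha": res.national_volume().to_numpy(),
                "national_growth_m3_ha": np.concatenate(
                    [[np.nan], growth_series.to_numpy()]
                ),
                "national_seq_tco2": np.concatenate([[np.nan], seq.to_numpy()]),
            }
        )
        _write_csv(series, out / f"scenario{sid}_series.csv", meta)
        _write_csv(res.harvest_frame(), out / f"scenario{sid}_harvest.csv", meta)
        for y in config.raster_years:
            if res.final_landscape is not None and y in res.years:
                snap = res.final_landscape.copy()
                yi = int(np.flatnonzero(res.years == y)[0])
                snap.cells["volume"] = res.cell_volumes[yi]
                write_ascii_grid(snap, "volume", out / f"scenario{sid}_volume_{y}.asc")
        sc_sum = {
            "growth": {
                p: _interval_decade_mean(growth_series, p)
                for p in ("base", "2030s", "2050s")
            },
            "sequestration": {
                p: _interval_decade_mean(seq, p)
                for p in ("base", "2030s", "2050s")
            },
            "costs": {p: o.costs[p].total() for p in o.costs},
            "benefits": {p: o.benefits[p].total() for p in o.benefits},
        }
        if o.sensitivity is not None:
            sc_sum["vulnerable_cum_ha_2050"] = vulnerable_cumulative_area(
                o.sensitivity, min(2050, int(res.years[-1]))
            )
            vuln = pd.DataFrame(
                {
                    "year": o.sensitivity.annual_vulnerable_area.index,
                    "annual_vulnerable_ha": o.sensitivity.annual_vulnerable_area.to_numpy(),
                    "cumulative_area_years_ha": o.sensitivity.cumulative_area_years.to_numpy(),
                }
            )
            _write_csv(vuln, out / f"scenario{sid}_vulnerability.csv", meta)
            if res.final_landscape is not None:
                snap = res.final_landscape.copy()
                snap.cells["grade"] = o.sensitivity.grade
                write_ascii_grid(snap, "grade", out / f"scenario{sid}_grade.asc")
        summary["scenarios"][str(sid)] = sc_sum
        for p, ledger in o.costs.items():
            for line, val in ledger.lines.items():
                ledger_rows.append(
                    {
                        "scenario": sid, "period": p, "kind": "cost", "line": line,
                        "value_1e8krw": val,
                        "value_musd": economics.krw_usd(val, config.prices.krw_per_usd),
                    }
                )
        for p, bl in o.benefits.items():
            for line, val in (
                ("carbon_revenue", bl.carbon_revenue), ("log_revenue", bl.log_revenue)
            ):
                ledger_rows.append(
                    {
                        "scenario": sid, "period": p, "kind": "benefit", "line": line,
                        "value_1e8krw": val,
                        "value_musd": economics.krw_usd(val, config.prices.krw_per_usd),
                    }
                )
    _write_csv(pd.DataFrame(ledger_rows), out / "ledgers.csv", meta)
    if set(outputs) == {1, 2, 3, 4}:
        _write_csv(report(outputs), out / "report.csv", meta)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
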