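"""Harvest scheduling, silvicultural operations and the scenario engine."""

import dataclasses
import itertools

import numpy as np
import pytest

import forestdyn as fd
from forestdyn import growth
from forestdyn.management import (
    DEFAULT_SUITABILITY_RULE,
    ScenarioConfig,
    SuitabilityRule,
    apply_clearcut,
    apply_thinning,
    choose_reforestation_species,
    potential_clearcut_area,
    run_scenario,
    scenario_preset,
    schedule_clearcut,
    schedule_thinning,
)


def _landscape(sp, ages, manageable=None, species="red_pine", seed=1):
    ls = fd.generate_landscape(len(ages), {species: 1.0}, seed=seed, species=sp)
    ls.cells["age"] = np.asarray(ages, dtype=float)
    if manageable is not None:
        ls.cells["manageable"] = np.asarray(manageable, dtype=bool)
    return ls


# ----------------------------------------------------------- potential area

def test_potential_area_counts_mature_manageable(sp):
    ls = _landscape(sp, [65, 65, 65, 40], manageable=[1, 1, 1, 1])
    assert potential_clearcut_area(ls, sp) == 300.0
    ls2 = _landscape(sp, [65, 65, 65], manageable=[0, 0, 0])
    assert potential_clearcut_area(ls2, sp) == 0.0
    ls3 = _landscape(sp, [10, 20, 59], manageable=[1, 1, 1])
    assert potential_clearcut_area(ls3, sp) == 0.0


# --------------------------------------------------------------- scheduling

def test_schedule_clearcut_zero_quota(sp):
    ls = _landscape(sp, [70, 70], manageable=[1, 1])
    assert schedule_clearcut(ls, 0.0, sp) == []


def test_schedule_clearcut_oldest_first_volume_tiebreak(sp):
    ls = _landscape(sp, [70, 80, 80, 65, 90], manageable=[1] * 5)
    ls.cells["volume"] = [100.0, 50.0, 200.0, 300.0, 10.0]
    got = schedule_clearcut(ls, 200.0, sp)  # two cells
    assert got == [4, 2]  # highest age first; age tie broken by volume


def test_schedule_clearcut_matches_brute_force(sp):
    """On <=10 cells the greedy selection equals exhaustive search over
    all subsets maximizing the (age, volume) lexicographic priority."""
    rng = np.random.default_rng(17)
    for trial in range(10):
        n = 8
        ls = _landscape(sp, rng.integers(40, 95, n), manageable=rng.integers(0, 2, n),
                        seed=trial)
        ls.cells["volume"] = rng.uniform(50, 350, n).round(0)
        quota = 250.0
        got = set(schedule_clearcut(ls, quota, sp))

        cells = ls.cells
        eligible = [
            int(r["cell_id"]) for _, r in cells.iterrows()
            if r["manageable"] and r["age"] >= sp[r["species"]].cutting_age
        ]
        max_cells = int(np.ceil(quota / ls.cell_area))
        take = min(max_cells, len(eligible))
        best = None
        for combo in itertools.combinations(eligible, take):
            key = sorted(
                (
                    (-cells.loc[cells.cell_id == c, "age"].iloc[0],
                     -cells.loc[cells.cell_id == c, "volume"].iloc[0], c)
                    for c in combo
                )
            )
            if best is None or key < best[0]:
                best = (key, set(combo))
        expect = best[1] if best else set()
        assert got == expect


def test_schedule_thinning_ranking_and_window(sp):
    ls = _landscape(sp, [20, 19, 41, 25, 39], manageable=[1, 1, 1, 1, 0])
    ls.cells["volume"] = [80.0, 120.0, 90.0, 500.0, 999.0]
    # eligible: cells 0,1 (age ~20), 2 (age ~41); cell 3 out of window,
    # cell 4 restricted.  Ranked by volume: 1, 2, 0
    assert schedule_thinning(ls, (20, 40), 1e9) == [1, 2, 0]
    assert schedule_thinning(ls, (20, 40), 150.0) == [1, 2]
    assert schedule_thinning(ls, (20, 40), 0.0) == []


def test_schedule_thinning_respects_already_thinned(sp):
    ls = _landscape(sp, [20, 20], manageable=[1, 1])
    assert schedule_thinning(ls, (20, 40), 1e9,
                             already_thinned=np.array([True, False])) == [1]


# ------------------------------------------------------------- applications

def test_apply_clearcut_record_and_reset(sp):
    cell = growth.GridCellState(
        cell_id=7, species="red_pine", age=65, si=14, nha=900,
        dbh=25.0, hm=17.0, volume=250.0, manageable=True,
    )
    rec, new = apply_clearcut(cell, "mongolian_oak", sp, cell_area=100.0, year=2030)
    assert rec.removed_volume_m3 == pytest.approx(25_000.0)
    assert rec.action == "clearcut" and rec.species == "red_pine"
    assert new.age == 0 and new.volume == 0.0 and new.species == "mongolian_oak"
    assert new.nha == sp["mongolian_oak"].planting_density
    # next-year volume of the replanted stand is ~0 (saplings below
    # breast height carry no stem volume)
    stepped = growth.step_stand(new, 0.0, sp["mongolian_oak"])
    assert stepped.volume < 1.0


def test_apply_clearcut_rejects_ineligible(sp):
    young = growth.GridCellState(
        cell_id=1, species="red_pine", age=30, si=14, nha=900,
        dbh=15.0, hm=12.0, volume=150.0, manageable=True,
    )
    with pytest.raises(ValueError, match="cutting age"):
        apply_clearcut(young, "red_pine", sp)
    restricted = dataclasses.replace(young, age=70, manageable=False)
    with pytest.raises(ValueError, match="restricted"):
        apply_clearcut(restricted, "red_pine", sp)


def test_apply_thinning_exact_linearity(sp):
    p = sp["cork_oak"]
    vol = growth.stand_volume(18.0, 14.0, 1000.0, p)
    cell = growth.GridCellState(
        cell_id=3, species="cork_oak", age=40, si=14, nha=1000.0,
        dbh=18.0, hm=14.0, volume=vol, manageable=True,
    )
    rec, new = apply_thinning(cell, 0.30, sp, cell_area=100.0, year=2020)
    assert new.nha == pytest.approx(700.0)
    assert new.volume == pytest.approx(0.7 * vol, rel=1e-12)  # Eq. linear in N
    assert rec.removed_volume_m3 == pytest.approx(0.3 * vol * 100.0, rel=1e-12)
    assert new.dbh == cell.dbh
    with pytest.raises(ValueError, match="fraction"):
        apply_thinning(cell, 1.0)


def test_thinning_releases_growth(sp):
    """The thinned stand's subsequent DBH increment exceeds its
    unthinned twin's (density release)."""
    p = sp["red_pine"]
    base = growth.GridCellState(
        cell_id=0, species="red_pine", age=20, si=14, nha=2000.0,
        dbh=10.0, hm=9.0, volume=growth.stand_volume(10.0, 9.0, 2000.0, p),
        manageable=True,
    )
    _, thinned = apply_thinning(base, 0.30, sp)
    for _ in range(5):
        base = growth.step_stand(base, 0.0, p)
        thinned = growth.step_stand(thinned, 0.0, p)
    assert thinned.dbh > base.dbh


# ------------------------------------------------------------- reforestation

def test_reforestation_identity_band(sp):
    cell = growth.GridCellState(
        cell_id=0, species="red_pine", age=60, si=14, nha=900,
        dbh=22.0, hm=16.0, volume=200.0, manageable=True,
    )
    assert choose_reforestation_species(cell, 10.0) == "red_pine"


def test_reforestation_warm_band_returns_oak(sp):
    cell = growth.GridCellState(
        cell_id=0, species="red_pine", age=60, si=14, nha=900,
        dbh=22.0, hm=16.0, volume=200.0, manageable=True,
    )
    assert choose_reforestation_species(cell, 14.0) == "mongolian_oak"


def test_reforestation_boundary_goes_to_warmer_band(sp):
    cell = growth.GridCellState(
        cell_id=0, species="red_pine", age=60, si=14, nha=900,
        dbh=22.0, hm=16.0, volume=200.0, manageable=True,
    )
    # exactly on the conifer/oak boundary -> warmer (oak) band
    upper = DEFAULT_SUITABILITY_RULE.bands[1][0]
    assert choose_reforestation_species(cell, upper) == "mongolian_oak"
    assert choose_reforestation_species(cell, upper - 1e-9) == "red_pine"


def test_suitability_gap_rejected_at_construction():
    with pytest.raises(ValueError, match="gap"):
        SuitabilityRule(bands=((9.0, frozenset({"larch"}), "larch"),))


# ---------------------------------------------------------------- scenarios

def test_scenario_presets():
    s3, s4 = scenario_preset(3), scenario_preset(4)
    assert s3.clearcut_frac < s4.clearcut_frac
    assert s3.thin_fraction == 0.30 and s3.thin_ages == (20, 40)
    for i in (1, 2):
        s = scenario_preset(i)
        assert not s.managed and not s.reforest
    with pytest.raises(ValueError, match="no-management"):
        ScenarioConfig(id=1, climate_mode="baseline", clearcut_frac=0.1)


def test_scenarios_1_and_2_coincide_without_warming(sp):
    ls = fd.generate_landscape(80, seed=21, species=sp)
    cb = fd.generate_climate(ls, "baseline", 2010, 2030, seed=21)
    cr = fd.generate_climate(ls, "rcp85", 2010, 2030,
                             warming_rate=0.0, noise_sd=0.0, seed=21)
    r1 = run_scenario(ls.copy(), cb, scenario_preset(1), sp)
    r2 = run_scenario(ls.copy(), cr, scenario_preset(2), sp)
    np.testing.assert_allclose(r1.cell_volumes, r2.cell_volumes, rtol=1e-12)


def test_engine_invariants(sp, default_outputs):
    """Quota cap, restricted-cell protection, and volume conservation
    over a full scenario-4 run."""
    out = default_outputs[4]
    res = out.result
    cfg = res.scenario
    quota = cfg.clearcut_quota_ha(res.total_area)
    years_elapsed = res.years[-1] - cfg.management_start_year + 1
    cum = res.cumulative_harvest_area("clearcut", int(res.years[-1]))
    assert cum <= (quota + res.cell_area) * years_elapsed

    restricted = set(res.cell_ids[~res.manageable])
    assert all(r.cell_id not in restricted for r in res.harvest_records)

    # conservation: net stock change + mortality + harvest = gross growth
    lhs = np.diff(res.cell_volumes, axis=0).sum() \
        + res.cell_mortality.sum() + res.cell_harvested.sum()
    rhs = res.cell_gross_growth.sum()
    assert abs(lhs - rhs) <= 1e-6 * abs(rhs)


def test_supply_limited_harvest(sp):
    """When eligible supply is below the quota, cumulative area falls
    short of quota x years."""
    ls = _landscape(sp, [70, 10, 10, 10], manageable=[1, 1, 1, 1], seed=3)
    clim = fd.generate_climate(ls, "rcp85", 2010, 2030, seed=3)
    cfg = ScenarioConfig(id=4, climate_mode="rcp85", clearcut_frac=0.5,
                         reforest=True, management_start_year=2011)
    res = run_scenario(ls, clim, cfg, sp)
    quota = cfg.clearcut_quota_ha(400.0)
    years = 20
    assert res.cumulative_harvest_area("clearcut", 2030) < quota * years
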