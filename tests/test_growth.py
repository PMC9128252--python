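"""Stand-level growth operations: allometry, height, self-thinning,
mortality, and the annual step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestdyn import growth
from forestdyn.growth import (
    GridCellState,
    annual_growth,
    dbh_increment,
    height_from_site_index,
    max_stand_density,
    mortality_count,
    stand_volume,
    step_stand,
)
from forestdyn.params import BASE_AGE
import dataclasses

import forestdyn as fd


# --------------------------------------------------------------------- volume

def test_stand_volume_hand_value(sp):
    # 0.000201 * 20^1.7593 * 15^0.6583 * 1000, evaluated independently
    assert stand_volume(20, 15, 1000, sp["red_pine"]) == pytest.approx(
        232.44435552922357, rel=1e-12
    )


def test_stand_volume_empty_stand(sp):
    for code in sp.codes:
        assert stand_volume(37.0, 21.0, 0.0, sp[code]) == 0.0


@given(
    dbh=st.floats(1, 60), hm=st.floats(2, 30), nha=st.floats(1, 4000)
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_stand_volume_linear_in_density(sp, dbh, hm, nha):
    p = sp["cork_oak"]
    assert stand_volume(dbh, hm, 2 * nha, p) == pytest.approx(
        2 * stand_volume(dbh, hm, nha, p), rel=1e-12
    )


def test_stand_volume_mixed_is_component_mean(sp):
    v = stand_volume(20, 15, 1000, sp["mixed_b"])
    parts = [stand_volume(20, 15, 1000, c) for c in sp["mixed_b"].components]
    assert v == pytest.approx(sum(parts) / 2, rel=1e-12)


def test_stand_volume_rejects_negative(sp):
    with pytest.raises(ValueError, match="non-negative"):
        stand_volume(-1, 15, 1000, sp["red_pine"])


# --------------------------------------------------------------------- height

@pytest.mark.parametrize("code", ["red_pine", "mongolian_oak", "mixed_a"])
@pytest.mark.parametrize("si", [10.0, 14.0, 18.0])
def test_height_anchored_at_base_age(sp, code, si):
    assert height_from_site_index(si, BASE_AGE, sp[code]) == pytest.approx(si)


def test_height_floor_and_monotone(sp):
    p = sp["larch"]
    assert height_from_site_index(14, 0, p) == pytest.approx(growth.BREAST_HEIGHT)
    ages = np.arange(0, 120)
    h = height_from_site_index(14.0, ages, p)
    assert np.all(np.diff(h) > 0)
    # bounded by the curve asymptote
    asym = growth.BREAST_HEIGHT + (14 - growth.BREAST_HEIGHT) / (
        1 - np.exp(-p.h_rate * BASE_AGE)
    ) ** p.h_shape
    assert h[-1] < asym


def test_height_rejects_negative_age(sp):
    with pytest.raises(ValueError, match="age"):
        height_from_site_index(14, -1, sp["red_pine"])


# ----------------------------------------------------------------- max density

def test_nmax_self_thinning_monotone(sp):
    p = sp["red_pine"]
    assert max_stand_density(20, 15, p) > max_stand_density(30, 15, p)


def test_nmax_loglog_slope_recovers_exponent(sp):
    """A log-log regression over the implemented curve recovers the
    Reineke-type slope k2 = -1.605."""
    p = sp["korean_pine"]
    d = np.linspace(8, 45, 80)
    n = max_stand_density(d, 16.0, p)
    slope = np.polyfit(np.log(d), np.log(n), 1)[0]
    assert slope == pytest.approx(p.nmax_k2, abs=1e-9)


def test_nmax_continuous(sp):
    p = sp["mongolian_oak"]
    d = np.linspace(5, 40, 2000)
    n = max_stand_density(d, 14.0, p)
    assert np.abs(np.diff(n)).max() < 0.02 * n.max()


def test_nmax_rejects_nonpositive(sp):
    with pytest.raises(ValueError):
        max_stand_density(0.0, 15.0, sp["red_pine"])


# ------------------------------------------------------------------ mortality

def test_mortality_zero_when_ceiling_static(sp):
    assert mortality_count(1200, 1500, 1500, sp["red_pine"]) == 0.0


def test_mortality_hand_value(sp):
    # a * exp(b * N/Nmax) * dNmax = 0.1 * e^{1.6} * 50
    p = dataclasses.replace(sp["red_pine"], mort_a=0.1, mort_b=2.0)
    got = mortality_count(800, 1000, 950, p)
    assert got == pytest.approx(0.1 * np.exp(1.6) * 50, rel=1e-12)


def test_mortality_clipped_to_stand(sp):
    p = dataclasses.replace(sp["red_pine"], mort_a=10.0, mort_b=5.0)
    assert mortality_count(30, 1000, 500, p) == 30.0
    assert mortality_count(0, 1000, 500, p) == 0.0


def test_mortality_rejects_rising_ceiling(sp):
    with pytest.raises(ValueError, match="self-thinning"):
        mortality_count(800, 900, 1000, sp["red_pine"])


# -------------------------------------------------------------- dbh increment

def test_increment_climate_modifier_normalised(sp):
    p = sp["red_pine"]
    assert dbh_increment(30, 14, 1000, 0.0, p) == pytest.approx(
        (p.dbh_asym * (1 - np.exp(-p.dbh_rate * 31)) ** p.dbh_shape
         - p.dbh_asym * (1 - np.exp(-p.dbh_rate * 30)) ** p.dbh_shape)
    )


@pytest.mark.parametrize("code", ["red_pine", "korean_pine", "larch"])
def test_conifer_warming_penalty(sp, code):
    p = sp[code]
    base = dbh_increment(30, 14, 1000, 0.0, p)
    warm = dbh_increment(30, 14, 1000, 2.5, p)
    assert warm < base


def test_increment_density_suppression(sp):
    p = sp["cork_oak"]
    assert dbh_increment(30, 14, 2000, 0.0, p) < dbh_increment(30, 14, 500, 0.0, p)


@given(
    age=st.floats(0, 120), si=st.floats(8, 25),
    nha=st.floats(0, 5000), anom=st.floats(-4, 4),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_increment_nonnegative(sp, age, si, nha, anom):
    assert dbh_increment(age, si, nha, anom, sp["mixed_b"]) >= 0


# -------------------------------------------------------------------- stepping

def _cell(sp, code="red_pine", **kw):
    defaults = dict(cell_id=0, species=code, age=30.0, si=14.0, nha=1500.0,
                    dbh=12.0, hm=13.0)
    defaults.update(kw)
    defaults["volume"] = growth.stand_volume(
        defaults["dbh"], defaults["hm"], defaults["nha"], sp[code]
    )
    return GridCellState(**defaults)


def test_step_empty_stand_only_ages(sp):
    s = GridCellState(cell_id=0, species="red_pine", age=10, si=14,
                      nha=0.0, dbh=5.0, hm=4.0, volume=0.0)
    out = step_stand(s, 0.0, sp["red_pine"])
    assert out.age == 11 and out.volume == 0.0 and out.nha == 0.0
    assert out.dbh == s.dbh


def test_step_pure_function(sp):
    s = _cell(sp)
    assert step_stand(s, 1.0, sp["red_pine"]) == step_stand(s, 1.0, sp["red_pine"])


def test_step_preserves_invariants(sp):
    s = _cell(sp, nha=3000.0, dbh=9.0)
    for _ in range(30):
        s = step_stand(s, 0.5, sp["red_pine"])
        s.validate()
        nmax = growth.max_stand_density(
            s.dbh, growth.DOMINANT_HEIGHT_RATIO * s.hm, sp["red_pine"]
        )
        assert s.nha <= nmax * (1 + 1e-9)


def test_century_trajectory_unimodal_growth(sp):
    """Volume is increasing-then-saturating over a century: annual
    volume growth peaks at an intermediate age and is much smaller in
    old age."""
    s = GridCellState(cell_id=0, species="red_pine", age=0, si=14,
                      nha=3000.0, dbh=0.0, hm=growth.BREAST_HEIGHT, volume=0.0)
    vols = [0.0]
    for _ in range(100):
        s = step_stand(s, 0.0, sp["red_pine"])
        vols.append(s.volume)
    d = np.diff(vols)
    assert np.all(d >= -1e-9)  # volume never shrinks
    peak = int(np.argmax(d))
    assert 5 < peak < 60
    assert d[-20:].mean() < 0.5 * d[peak]


def test_step_mass_balance(sp):
    """Per-cell, per-year: dV = gross growth - mortality volume."""
    age = np.array([25.0, 40.0, 70.0])
    si = np.array([12.0, 14.0, 16.0])
    nha = np.array([2500.0, 1400.0, 900.0])
    dbh = np.array([8.0, 15.0, 22.0])
    p = sp["larch"]
    hm = growth.height_from_site_index(si, age, p)
    v0 = growth.stand_volume(dbh, hm, nha, p)
    for _ in range(20):
        age, nha, dbh, hm, v1, diag = growth.step_arrays(
            age, si, nha, dbh, hm, 0.0, p
        )
        np.testing.assert_allclose(
            v1 - v0, diag.gross_growth - diag.mortality_volume, rtol=1e-9, atol=1e-9
        )
        v0 = v1


# -------------------------------------------------------------- annual growth

def test_annual_growth_identical_landscapes_zero(small_landscape):
    b = small_landscape.copy()
    b.year += 1
    per_cell, national = annual_growth(small_landscape, b)
    assert np.all(per_cell == 0) and national == 0.0


def test_annual_growth_brute_force_oracle(sp):
    ls = fd.generate_landscape(10, seed=11, species=sp)
    nxt = ls.copy()
    nxt.year += 1
    rng = np.random.default_rng(5)
    bump = rng.uniform(0, 5, 10)
    nxt.cells["volume"] = nxt.cells["volume"].to_numpy() + bump
    harv = rng.uniform(0, 2, 10)
    per_cell, national = annual_growth(ls, nxt, harvested_per_ha=harv)
    # independent summation oracle
    expect_cells = [
        (nxt.cells["volume"].iloc[i] - ls.cells["volume"].iloc[i]) + harv[i]
        for i in range(10)
    ]
    expect_national = sum(v * ls.cell_area for v in expect_cells) / (10 * ls.cell_area)
    np.testing.assert_allclose(per_cell, expect_cells, rtol=1e-12)
    assert national == pytest.approx(expect_national, rel=1e-12)


def test_annual_growth_grid_mismatch(sp, small_landscape):
    other = fd.generate_landscape(49, seed=3, species=sp)
    other.year = small_landscape.year + 1
    with pytest.raises(ValueError, match="grid"):
        annual_growth(small_landscape, other)
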