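"""Synthetic landscape and climate generation.

The real analysis runs on a 1 km × 1 km national raster built from the
Korean National Forest Inventory and forest-type map, driven by a
regional RCP 8.5 temperature projection.  Neither input is public, so
this module generates landscapes and climate series with the same
structure: every cell is one homogeneous 100-ha stand with a species (7
catalogued types), an age sampled as the midpoint of a 10-year age
class, a site index, a stem density, and a manageable/restricted flag;
climate is a per-cell annual mean-temperature series, either fixed at a
baseline reference or warming linearly with seeded interannual noise.

Generators are pure functions of (configuration, seed).  Initial DBH,
height, density and volume are obtained by spinning each stand up from
planting with the growth module itself, so the generated state is
internally consistent with the simulator's own dynamics.

Fixtures round-trip through plain-text files: a CSV cell table, a CSV
temperature table and a YAML metadata header.  Per-attribute rasters can
be written as ESRI ASCII grids (also plain text).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth
from .params import SITE_INDEX_BOUNDS, SpeciesTable, species_table

__all__ = [
    "Landscape",
    "ClimateScenario",
    "generate_landscape",
    "generate_climate",
    "write_fixture",
    "load_fixture",
    "write_ascii_grid",
    "read_ascii_grid",
    "DEFAULT_SPECIES_MIX",
    "DEFAULT_AGE_DIST",
    "FixtureError",
]

#: Default species composition: ~37% conifer, ~32% broadleaf (oak),
#: ~26% mixed, remainder split among the minor conifers.
DEFAULT_SPECIES_MIX = {
    "red_pine": 0.30,
    "korean_pine": 0.04,
    "larch": 0.08,
    "cork_oak": 0.14,
    "mongolian_oak": 0.18,
    "mixed_a": 0.13,
    "mixed_b": 0.13,
}

#: Default age-class distribution (classes I-IX, 10-yr bins, midpoints
#: 5..85 yr).  Mass sits on classes III-V, emulating a forest estate in
#: transition from young-matured stands to over-mature forest.
DEFAULT_AGE_DIST = {
    1: 0.03, 2: 0.07, 3: 0.28, 4: 0.30, 5: 0.22,
    6: 0.06, 7: 0.03, 8: 0.005, 9: 0.005,
}

#: Default manageable share of the landscape (the national management
#: zoning assigns ~52.48% of forest to manageable area).
DEFAULT_MANAGEABLE_FRACTION = 0.5248

NODATA = -9999.0


class FixtureError(ValueError):
    """Raised when a fixture file fails validation on load."""


@dataclass
class Landscape:
    """A gridded forest landscape: one homogeneous stand per cell.

    ``cells`` is a DataFrame with columns ``cell_id, row, col, species,
    age, si, nha, dbh, hm, volume, manageable`` ordered by ``cell_id``.
    """

    cells: pd.DataFrame
    cell_area: float = 100.0  # ha per cell (1 km x 1 km)
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 1000.0  # m
    year: int = 2010

    COLUMNS = ("cell_id", "row", "col", "species", "age", "si",
               "nha", "dbh", "hm", "volume", "manageable")

    def __post_init__(self):
        if self.cell_area <= 0:
            raise ValueError("cell_area must be > 0")
        missing = set(self.COLUMNS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"landscape table missing columns: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area(self) -> float:
        """Total landscape area (ha)."""
        return self.n_cells * self.cell_area

    def national_volume(self) -> float:
        """Area-weighted mean growing stock (m³/ha)."""
        return float(self.cells["volume"].mean())

    def copy(self) -> "Landscape":
        return replace(self, cells=self.cells.copy())

    def validate(self, species: SpeciesTable | None = None) -> None:
        sp = species or species_table()
        c = self.cells
        unknown = set(c["species"]) - set(sp.codes)
        if unknown:
            raise ValueError(f"unknown species codes in landscape: {sorted(unknown)}")
        for col in ("age", "si", "nha", "dbh", "hm", "volume"):
            bad = np.flatnonzero(c[col].to_numpy() < 0)
            if bad.size:
                raise ValueError(f"record {bad[0]}: negative {col}")
        empty = (c["nha"] == 0) & (c["volume"] != 0)
        if empty.any():
            raise ValueError(
                f"record {int(np.flatnonzero(empty)[0])}: volume > 0 with nha == 0"
            )


@dataclass
class ClimateScenario:
    """Per-cell annual mean-temperature series.

    ``temps`` has shape (n_years, n_cells); ``years`` gives the calendar
    year of each row.  In baseline mode every row equals
    ``reference_mean`` (the 2000-2010-style fixed climate); in rcp85
    mode a linear warming trend plus seeded noise is added.
    """

    mode: str
    years: np.ndarray
    temps: np.ndarray
    reference_mean: np.ndarray
    warming_rate: float = 0.0  # degC per decade

    _year_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._year_index = {int(y): i for i, y in enumerate(self.years)}

    def temp(self, year: int) -> np.ndarray:
        return self.temps[self._year_index[int(year)]]

    def anomaly(self, year: int) -> np.ndarray:
        """Temperature anomaly (°C) relative to the baseline reference."""
        return self.temp(year) - self.reference_mean


def _validate_mix(species_mix: dict, sp: SpeciesTable) -> None:
    unknown = set(species_mix) - set(sp.codes)
    if unknown:
        raise ValueError(f"species_mix contains unknown codes: {sorted(unknown)}")
    total = sum(species_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species_mix proportions sum to {total!r}, expected 1: {species_mix}")


def _largest_remainder_counts(props: list[float], n: int) -> list[int]:
    """Apportion n items to proportions exactly (largest-remainder rule)."""
    raw = [p * n for p in props]
    counts = [math.floor(r) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _spin_up(cells: pd.DataFrame, sp: SpeciesTable) -> pd.DataFrame:
    """Grow every stand from planting to its target age at zero anomaly."""
    cells = cells.copy()
    n = len(cells)
    target = cells["age"].to_numpy(dtype=float)
    si = cells["si"].to_numpy(dtype=float)
    age = np.zeros(n)
    dbh = np.zeros(n)
    hm = np.full(n, growth.BREAST_HEIGHT)
    nha = np.array([sp[s].planting_density for s in cells["species"]])
    vol = np.zeros(n)
    species_codes = cells["species"].to_numpy()
    max_age = int(target.max()) if n else 0
    for step in range(max_age):
        active = target > step
        if not active.any():
            break
        for code in np.unique(species_codes[active]):
            m = active & (species_codes == code)
            a, nh, d, h, v, _ = growth.step_arrays(
                age[m], si[m], nha[m], dbh[m], hm[m], 0.0, sp[code]
            )
            age[m], nha[m], dbh[m], hm[m], vol[m] = a, nh, d, h, v
    cells["age"] = age
    cells["nha"] = nha
    cells["dbh"] = dbh
    cells["hm"] = hm
    cells["volume"] = vol
    return cells


def generate_landscape(
    n_cells: int,
    species_mix: dict[str, float] | None = None,
    age_dist: dict[int, float] | None = None,
    si_range: tuple[float, float] = (10.0, 18.0),
    manageable_fraction: float = DEFAULT_MANAGEABLE_FRACTION,
    seed: int = 0,
    cell_area: float = 100.0,
    year: int = 2010,
    species: SpeciesTable | None = None,
) -> Landscape:
    """Generate a reproducible synthetic landscape.

    Species and the manageable flag are allocated with exact
    largest-remainder counts and a seeded shuffle, so realized
    proportions match the request to within one cell.  Ages are the
    midpoints of sampled 10-year age classes; site index is uniform on
    ``si_range``.  Initial DBH/height/density/volume come from a
    zero-anomaly spin-up with the growth module.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sp = species or species_table()
    mix = dict(species_mix or DEFAULT_SPECIES_MIX)
    _validate_mix(mix, sp)
    ages = dict(age_dist or DEFAULT_AGE_DIST)
    if abs(sum(ages.values()) - 1.0) > 1e-9:
        raise ValueError(f"age_dist proportions sum to {sum(ages.values())!r}, expected 1")
    lo, hi = si_range
    if not (SITE_INDEX_BOUNDS[0] <= lo < hi <= SITE_INDEX_BOUNDS[1]):
        raise ValueError(
            f"si_range {si_range} outside plausible bounds {SITE_INDEX_BOUNDS}"
        )
    if not 0.0 <= manageable_fraction <= 1.0:
        raise ValueError("manageable_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    codes = sorted(mix)
    counts = _largest_remainder_counts([mix[c] for c in codes], n_cells)
    species_col = np.repeat(codes, counts)
    rng.shuffle(species_col)

    n_manage = round(manageable_fraction * n_cells)
    manageable = np.zeros(n_cells, dtype=bool)
    manageable[rng.permutation(n_cells)[:n_manage]] = True

    classes = sorted(ages)
    age_class = rng.choice(classes, size=n_cells, p=[ages[c] for c in classes])
    age_col = age_class * 10.0 - 5.0  # class midpoints 5, 15, ..., 85

    si_col = rng.uniform(lo, hi, size=n_cells)

    ncol = max(1, math.ceil(math.sqrt(n_cells)))
    idx = np.arange(n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": idx,
            "row": idx // ncol,
            "col": idx % ncol,
            "species": species_col,
            "age": age_col,
            "si": si_col,
            "nha": 0.0,
            "dbh": 0.0,
            "hm": 0.0,
            "volume": 0.0,
            "manageable": manageable,
        }
    )
    cells = _spin_up(cells, sp)
    return Landscape(cells=cells, cell_area=cell_area, year=year)


def generate_climate(
    landscape: Landscape,
    mode: str,
    start_year: int,
    end_year: int,
    warming_rate: float = 0.55,
    noise_sd: float = 0.3,
    seed: int = 0,
    ref_mean: float = 11.2,
    ref_sd: float = 1.6,
) -> ClimateScenario:
    """Generate a per-cell annual mean-temperature series.

    ``baseline`` holds every year at the cell's reference mean (the
    fixed 2000-2010-style climate, ignoring ``warming_rate`` and
    ``noise_sd``); ``rcp85`` adds a linear trend of ``warming_rate/10``
    °C per year from ``start_year`` plus seeded Gaussian noise.  The
    per-cell reference means depend only on the seed, so baseline and
    warming series generated with the same seed share their reference —
    required when pairing runs for sensitivity analysis.
    """
    if mode not in ("baseline", "rcp85"):
        raise ValueError(f"unknown climate mode {mode!r}; expected 'baseline' or 'rcp85'")
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    if warming_rate < 0:
        raise ValueError("warming_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = landscape.n_cells
    ref = np.clip(rng.normal(ref_mean, ref_sd, size=n), 5.0, 16.0)
    years = np.arange(start_year, end_year + 1)
    if mode == "baseline":
        temps = np.tile(ref, (len(years), 1))
        rate = 0.0
    else:
        trend = warming_rate / 10.0 * (years - start_year)
        noise = (
            rng.normal(0.0, noise_sd, size=(len(years), n)) if noise_sd > 0
            else np.zeros((len(years), n))
        )
        temps = ref[None, :] + trend[:, None] + noise
        rate = warming_rate
    return ClimateScenario(
        mode=mode, years=years, temps=temps, reference_mean=ref, warming_rate=rate
    )


# ---------------------------------------------------------------------------
# fixtures

def write_fixture(landscape: Landscape, climate: ClimateScenario | None, path) -> None:
    """Write a landscape (and optionally a climate series) as plain text.

    Produces ``cells.csv``, ``meta.yaml`` and, when a climate is given,
    ``climate.csv`` (one row per cell: reference mean followed by the
    annual series) under ``path``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = landscape.cells.copy()
    out["manageable"] = out["manageable"].astype(int)
    out.to_csv(path / "cells.csv", index=False, float_format="%.17g")
    meta = {
        "cell_area": landscape.cell_area,
        "origin": list(landscape.origin),
        "resolution": landscape.resolution,
        "year": landscape.year,
    }
    if climate is not None:
        meta["climate"] = {
            "mode": climate.mode,
            "start_year": int(climate.years[0]),
            "end_year": int(climate.years[-1]),
            "warming_rate": climate.warming_rate,
        }
        clim = pd.DataFrame(
            climate.temps.T, columns=[f"t{int(y)}" for y in climate.years]
        )
        clim.insert(0, "cell_id", landscape.cells["cell_id"].to_numpy())
        clim.insert(1, "ref_mean", climate.reference_mean)
        clim.to_csv(path / "climate.csv", index=False, float_format="%.17g")
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_fixture(path) -> tuple[Landscape, ClimateScenario | None]:
    """Load a fixture written by :func:`write_fixture`, validating records."""
    path = Path(path)
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    cells = pd.read_csv(path / "cells.csv", float_precision="round_trip")
    for i, col in enumerate(("age", "si", "nha", "dbh", "hm", "volume")):
        if col not in cells.columns:
            raise FixtureError(f"cells.csv: missing column {col!r}")
        bad = np.flatnonzero(cells[col].to_numpy() < 0)
        if bad.size:
            raise FixtureError(f"cells.csv record {int(bad[0])}: negative {col}")
        cells[col] = cells[col].astype(float)
    cells["manageable"] = cells["manageable"].astype(bool)
    landscape = Landscape(
        cells=cells,
        cell_area=float(meta["cell_area"]),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        resolution=float(meta.get("resolution", 1000.0)),
        year=int(meta["year"]),
    )
    climate = None
    if "climate" in meta:
        cmeta = meta["climate"]
        clim = pd.read_csv(path / "climate.csv", float_precision="round_trip")
        years = np.arange(int(cmeta["start_year"]), int(cmeta["end_year"]) + 1)
        cols = [f"t{int(y)}" for y in years]
        missing = [c for c in cols if c not in clim.columns]
        if missing:
            raise FixtureError(f"climate.csv: missing year columns {missing[:3]}")
        climate = ClimateScenario(
            mode=cmeta["mode"],
            years=years,
            temps=clim[cols].to_numpy().T.copy(),
            reference_mean=clim["ref_mean"].to_numpy().copy(),
            warming_rate=float(cmeta.get("warming_rate", 0.0)),
        )
    return landscape, climate


def write_ascii_grid(landscape: Landscape, attribute: str, path) -> None:
    """Write one cell attribute as an ESRI ASCII grid (plain-text raster)."""
    c = landscape.cells
    nrow = int(c["row"].max()) + 1
    ncol = int(c["col"].max()) + 1
    grid = np.full((nrow, ncol), NODATA)
    vals = c[attribute].to_numpy(dtype=float)
    grid[c["row"].to_numpy(), c["col"].to_numpy()] = vals
    buf = io.StringIO()
    buf.write(f"ncols {ncol}\nnrows {nrow}\n")
    buf.write(f"xllcorner {landscape.origin[0]}\nyllcorner {landscape.origin[1]}\n")
    buf.write(f"cellsize {landscape.resolution}\nNODATA_value {NODATA:g}\n")
    for r in range(nrow):
        buf.write(" ".join(f"{v:.6g}" for v in grid[r]) + "\n")
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()
        header[k.lower()] = float(v)
        i += 1
    grid = np.loadtxt(lines[i:])
    grid = np.atleast_2d(grid)
    nodata = header.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    return grid
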