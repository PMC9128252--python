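"""Species parameter catalogue.

Seven Korean forest types are modelled: red pine (*Pinus densiflora*),
Korean pine (*Pinus koraiensis*), Japanese larch (*Larix kaempferi*),
cork oak (*Quercus variabilis*), Mongolian oak (*Quercus mongolica*),
and two mixed types (red pine with each oak).  Each species row carries

* the volume-equation coefficients ``V = a · DBH^b · Hm^c · N`` from the
  national stem-volume allometry (mixed types evaluate the mean of their
  two component species instead),
* country-specific carbon conversion factors: basic wood density ``D``
  (t/m³), biomass expansion factor ``BEF`` and root/shoot ratio ``RS``
  (mixed-type factors are the published component means),
* the statutory final cutting age (50 yr for larch, 60 yr otherwise),
* growth, self-thinning and mortality coefficients for the stand
  simulator (these are calibrated model defaults, not published values),
* unit prices from the Korea Forest Service budget tables (felling,
  primary transport, reforestation) and placeholder log trading prices.

The default catalogue ships as ``data/species_params.csv`` and is loaded
lazily via :func:`species_table`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import pandas as pd

__all__ = ["SpeciesParams", "SpeciesTable", "species_table", "SpeciesLookupError"]

#: Biologically plausible site-index bounds (m at base age) used for
#: validating generator configuration.
SITE_INDEX_BOUNDS = (5.0, 30.0)

#: Base age (yr) at which a stand's dominant height equals its site index.
BASE_AGE = 30

#: Ratio of dominant-tree height to stand mean height used where only the
#: mean height is tracked.
DOMINANT_HEIGHT_RATIO = 1.15


class SpeciesLookupError(KeyError):
    """Raised when a species code is not in the catalogue."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species constants for growth, carbon and cost accounting."""

    code: str
    name: str
    # volume equation V = vol_a * dbh^vol_b * hm^vol_c * nha
    vol_a: float | None
    vol_b: float | None
    vol_c: float | None
    # carbon conversion factors
    wood_density: float
    bef: float
    root_shoot: float
    cutting_age: int
    # DBH growth curve (Chapman-Richards potential, scaled by site index)
    base_si: float
    dbh_asym: float
    dbh_rate: float
    dbh_shape: float
    dens_gamma: float
    n_ref: float
    clim_opt: float
    clim_width: float
    # height curve (site-index anchored Chapman-Richards)
    h_rate: float
    h_shape: float
    # mortality and maximum stand density
    mort_a: float
    mort_b: float
    nmax_k1: float
    nmax_k2: float
    nmax_hcoef: float
    planting_density: float
    # unit prices
    felling_cost_krw_m3: float
    transport_cost_krw_m3: float
    reforest_price_krw_ha: float
    log_price_krw_m3: float
    #: resolved component species for mixed forest types (empty for pure)
    components: tuple["SpeciesParams", ...] = field(default=())

    @property
    def is_mixed(self) -> bool:
        return len(self.components) > 0


class SpeciesTable:
    """Immutable registry of :class:`SpeciesParams`, keyed by code."""

    def __init__(self, params: dict[str, SpeciesParams]):
        self._params = dict(params)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SpeciesTable":
        df = pd.read_csv(path_or_buf)
        pure: dict[str, SpeciesParams] = {}
        deferred: list[pd.Series] = []
        for _, row in df.iterrows():
            if isinstance(row["components"], str) and row["components"]:
                deferred.append(row)
            else:
                pure[row["code"]] = cls._row_to_params(row, ())
        params = dict(pure)
        for row in deferred:
            comps = tuple(pure[c] for c in row["components"].split("+"))
            params[row["code"]] = cls._row_to_params(row, comps)
        return cls(params)

    @staticmethod
    def _row_to_params(row: pd.Series, comps: tuple) -> SpeciesParams:
        def opt(key: str) -> float | None:
            v = row[key]
            return None if pd.isna(v) else float(v)

        return SpeciesParams(
            code=row["code"],
            name=row["name"],
            vol_a=opt("vol_a"),
            vol_b=opt("vol_b"),
            vol_c=opt("vol_c"),
            wood_density=float(row["wood_density"]),
            bef=float(row["bef"]),
            root_shoot=float(row["root_shoot"]),
            cutting_age=int(row["cutting_age"]),
            base_si=float(row["base_si"]),
            dbh_asym=float(row["dbh_asym"]),
            dbh_rate=float(row["dbh_rate"]),
            dbh_shape=float(row["dbh_shape"]),
            dens_gamma=float(row["dens_gamma"]),
            n_ref=float(row["n_ref"]),
            clim_opt=float(row["clim_opt"]),
            clim_width=float(row["clim_width"]),
            h_rate=float(row["h_rate"]),
            h_shape=float(row["h_shape"]),
            mort_a=float(row["mort_a"]),
            mort_b=float(row["mort_b"]),
            nmax_k1=float(row["nmax_k1"]),
            nmax_k2=float(row["nmax_k2"]),
            nmax_hcoef=float(row["nmax_hcoef"]),
            planting_density=float(row["planting_density"]),
            felling_cost_krw_m3=float(row["felling_cost_krw_m3"]),
            transport_cost_krw_m3=float(row["transport_cost_krw_m3"]),
            reforest_price_krw_ha=float(row["reforest_price_krw_ha"]),
            log_price_krw_m3=float(row["log_price_krw_m3"]),
            components=comps,
        )

    @property
    def codes(self) -> list[str]:
        return list(self._params)

    def __getitem__(self, code: str) -> SpeciesParams:
        try:
            return self._params[code]
        except KeyError:
            raise SpeciesLookupError(
                f"unknown species code {code!r}; known codes: {sorted(self._params)}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._params

    def __iter__(self) -> Iterator[SpeciesParams]:
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)


@functools.lru_cache(maxsize=1)
def species_table() -> SpeciesTable:
    """Load the default species catalogue shipped with the package."""
    with resources.files("forestdyn.data").joinpath("species_params.csv").open() as fh:
        return SpeciesTable.from_csv(fh)
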