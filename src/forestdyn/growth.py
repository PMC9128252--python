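"""Annual per-stand growth dynamics.

One grid cell carries one homogeneous stand summarised by its mean
diameter at breast height (DBH, cm), mean height (Hm, m), stem density
(N, trees/ha) and growing stock volume (V, m³/ha).  The yearly update
chains five operations in a fixed order:

1. age advances by one year;
2. DBH receives an increment from a Chapman–Richards potential curve,
   scaled by site index, suppressed by stand density and modulated by a
   temperature-anomaly response;
3. mean height is recomputed from the site-index curve;
4. density-dependent mortality removes stems when the self-thinning
   ceiling (a Reineke/Sterba-type maximum density) declines;
5. volume is recomputed from the allometric equation
   ``V = a · DBH^b · Hm^c · N`` (mixed forest types evaluate the mean of
   their two component species).

All operations accept scalars or NumPy arrays and are pure functions of
their inputs, which keeps whole-landscape simulation vectorised and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .params import BASE_AGE, DOMINANT_HEIGHT_RATIO, SpeciesParams

__all__ = [
    "GridCellState",
    "StepDiagnostics",
    "stand_volume",
    "height_from_site_index",
    "max_stand_density",
    "mortality_count",
    "dbh_increment",
    "step_stand",
    "step_arrays",
    "annual_growth",
]

#: Breast height (m): the floor of every height curve and the height
#: assigned to a freshly planted stand.
BREAST_HEIGHT = 1.3

#: Upper cap on the density-release modifier of the DBH increment; keeps
#: near-empty stands from receiving unbounded growth release.
MAX_DENSITY_RELEASE = 2.5

#: Mean DBH (cm) below which the self-thinning machinery is inactive in
#: the annual step: the Reineke-type ceiling diverges as DBH → 0, which
#: would impose absurd mortality on saplings that in reality are far
#: below canopy closure.
MORTALITY_DBH_FLOOR = 5.0


@dataclass(frozen=True)
class GridCellState:
    """State of one 1-km grid cell (one stand) in a given year."""

    cell_id: int
    species: str
    age: float
    si: float
    nha: float
    dbh: float
    hm: float
    volume: float
    manageable: bool = True

    def validate(self) -> None:
        if min(self.nha, self.dbh, self.hm, self.volume, self.age) < 0:
            raise ValueError(f"cell {self.cell_id}: negative state field")
        if self.nha == 0 and self.volume != 0:
            raise ValueError(f"cell {self.cell_id}: volume > 0 in an empty stand")


class StepDiagnostics(NamedTuple):
    """Volume bookkeeping for one annual step (per ha)."""

    gross_growth: np.ndarray  # volume added by DBH/height growth, pre-mortality
    mortality_volume: np.ndarray  # volume lost with dying stems
    mortality_trees: np.ndarray  # stems/ha lost


def _asfloat(*xs):
    return tuple(np.asarray(x, dtype=float) for x in xs)


def stand_volume(dbh, hm, nha, species: SpeciesParams):
    """Growing stock volume (m³/ha) from mean DBH, mean height and density.

    ``V = a · DBH^b · Hm^c · N`` with species coefficients; mixed forest
    types return the arithmetic mean of their component-species
    evaluations.  Linear in ``N``, hence zero for an empty stand.
    """
    dbh, hm, nha = _asfloat(dbh, hm, nha)
    if np.any(dbh < 0) or np.any(hm < 0) or np.any(nha < 0):
        raise ValueError("stand_volume: inputs must be non-negative")
    if species.is_mixed:
        parts = [stand_volume(dbh, hm, nha, c) for c in species.components]
        return sum(parts) / len(parts)
    v = species.vol_a * dbh**species.vol_b * hm**species.vol_c * nha
    return v if v.ndim else float(v)


def height_from_site_index(si, age, species: SpeciesParams):
    """Stand mean height (m) from site index and age.

    Chapman–Richards curve anchored so that height equals ``si`` exactly
    at the base age (30 yr) and tends to the breast-height floor of
    1.3 m as age → 0.  Monotone increasing in age with a finite
    asymptote.
    """
    si, age = _asfloat(si, age)
    if np.any(age < 0):
        raise ValueError("height_from_site_index: age must be >= 0")
    if np.any(si <= 0):
        raise ValueError("height_from_site_index: site index must be > 0")
    k, p = species.h_rate, species.h_shape
    anchor = (1.0 - np.exp(-k * BASE_AGE)) ** p
    h = BREAST_HEIGHT + (si - BREAST_HEIGHT) * (1.0 - np.exp(-k * age)) ** p / anchor
    return h if h.ndim else float(h)


def max_stand_density(dbh, hdom, species: SpeciesParams):
    """Maximum sustainable stem density (trees/ha) for a given mean size.

    Reineke-type power law in mean DBH with a linear dominant-height
    adjustment: ``Nmax = k1 · (1 + hcoef · Hdom) · DBH^k2`` with
    ``k2 < 0``, so the ceiling falls as trees grow.
    """
    dbh, hdom = _asfloat(dbh, hdom)
    if np.any(dbh <= 0) or np.any(hdom <= 0):
        raise ValueError("max_stand_density: dbh and hdom must be > 0")
    n = species.nmax_k1 * (1.0 + species.nmax_hcoef * hdom) * dbh**species.nmax_k2
    return n if n.ndim else float(n)


def mortality_count(nha, nmax_now, nmax_next, species: SpeciesParams):
    """Stems/ha lost in one year of self-thinning.

    ``mortality = a · exp(b · N/Nmax) · (Nmax_now − Nmax_next)``, clipped
    to ``[0, N]``.  Mortality scales with the decline of the density
    ceiling and grows exponentially with relative density, so stands at
    the ceiling shed trees while open stands barely do.
    """
    nha, nmax_now, nmax_next = _asfloat(nha, nmax_now, nmax_next)
    if np.any(nmax_next <= 0):
        raise ValueError("mortality_count: nmax_next must be > 0")
    if np.any(nmax_next > nmax_now * (1 + 1e-12)):
        raise ValueError(
            "mortality_count: nmax_next > nmax_now violates the self-thinning premise"
        )
    if np.any(nha < 0):
        raise ValueError("mortality_count: nha must be >= 0")
    m = species.mort_a * np.exp(species.mort_b * nha / nmax_now) * (nmax_now - nmax_next)
    m = np.clip(m, 0.0, nha)
    return m if m.ndim else float(m)


def dbh_increment(age, si, nha, temp_anomaly, species: SpeciesParams):
    """Annual mean-DBH increment (cm/yr) for the step age → age+1.

    The potential increment is the one-year difference of a
    Chapman–Richards curve ``A·(si/si_base)·(1 − e^{−k·age})^p``.  It is
    multiplied by a density modifier ``(N/N_ref)^{−γ}`` (capped) and a
    Gaussian temperature response ``exp(−((ΔT−μ)² − μ²)/(2σ²))``
    normalised to 1 at zero anomaly.  Species with a warm optimum
    (μ > 0) benefit mildly from small warming; conifer growth declines
    with any anomaly.
    """
    age, si, nha, temp_anomaly = _asfloat(age, si, nha, temp_anomaly)
    if np.any(age < 0):
        raise ValueError("dbh_increment: age must be >= 0")
    if np.any(si <= 0):
        raise ValueError("dbh_increment: site index must be > 0")
    if np.any(nha < 0):
        raise ValueError("dbh_increment: nha must be >= 0")
    a_scale = species.dbh_asym * si / species.base_si
    k, p = species.dbh_rate, species.dbh_shape

    def pot(t):
        return a_scale * (1.0 - np.exp(-k * t)) ** p

    base = pot(age + 1.0) - pot(age)
    dens = (np.maximum(nha, 1.0) / species.n_ref) ** (-species.dens_gamma)
    dens = np.minimum(dens, MAX_DENSITY_RELEASE)
    mu, sig = species.clim_opt, species.clim_width
    clim = np.exp(-((temp_anomaly - mu) ** 2 - mu**2) / (2.0 * sig**2))
    inc = base * dens * clim
    return inc if inc.ndim else float(inc)


def step_arrays(
    age: np.ndarray,
    si: np.ndarray,
    nha: np.ndarray,
    dbh: np.ndarray,
    hm: np.ndarray,
    temp_anomaly: np.ndarray | float,
    species: SpeciesParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, StepDiagnostics]:
    """Vectorised one-year update for all cells of a single species.

    Returns ``(age, nha, dbh, hm, volume, diagnostics)`` arrays.  Update
    order is fixed: age+1 → DBH increment → height → Nmax before/after →
    mortality → volume.  Empty stands (``nha == 0``) only age.  After the
    mortality step density is capped at the current maximum density, so
    ``N/Nmax ≤ 1`` always holds.
    """
    age, si, nha, dbh, hm = _asfloat(age, si, nha, dbh, hm)
    anom = np.broadcast_to(np.asarray(temp_anomaly, dtype=float), age.shape)
    live = nha > 0

    v_old = stand_volume(dbh, hm, nha, species)

    age_new = age + 1.0
    inc = dbh_increment(age, si, nha, anom, species)
    dbh_new = np.where(live, dbh + inc, dbh)
    hm_new = np.where(live, height_from_site_index(si, age_new, species), hm)

    # mortality only where a positive pre-step size exists and the
    # density ceiling actually declines
    mort = np.zeros_like(nha)
    nha_new = nha.copy()
    grown = live & (dbh >= MORTALITY_DBH_FLOOR)
    if np.any(grown):
        hdom_old = DOMINANT_HEIGHT_RATIO * hm[grown]
        hdom_new = DOMINANT_HEIGHT_RATIO * hm_new[grown]
        nmax_old = max_stand_density(dbh[grown], hdom_old, species)
        nmax_new = max_stand_density(dbh_new[grown], hdom_new, species)
        declining = nmax_new < nmax_old
        m = np.zeros_like(nmax_old)
        if np.any(declining):
            m[declining] = mortality_count(
                nha[grown][declining],
                nmax_old[declining],
                nmax_new[declining],
                species,
            )
        n_after = np.minimum(nha[grown] - m, nmax_new)
        n_after = np.maximum(n_after, 0.0)
        mort[grown] = nha[grown] - n_after
        nha_new[grown] = n_after

    v_grown = stand_volume(dbh_new, hm_new, nha, species)  # pre-mortality
    v_new = stand_volume(dbh_new, hm_new, nha_new, species)
    diag = StepDiagnostics(
        gross_growth=v_grown - v_old,
        mortality_volume=v_grown - v_new,
        mortality_trees=mort,
    )
    return age_new, nha_new, dbh_new, hm_new, v_new, diag


def step_stand(
    state: GridCellState, temp_anomaly: float, species: SpeciesParams
) -> GridCellState:
    """Advance a single stand one year (scalar wrapper of :func:`step_arrays`)."""
    state.validate()
    if species.code != state.species:
        raise ValueError(
            f"cell {state.cell_id}: species params {species.code!r} "
            f"do not match state species {state.species!r}"
        )
    arrays = tuple(np.array([v], dtype=float) for v in (state.age, state.si, state.nha, state.dbh, state.hm))
    age, nha, dbh, hm, vol, _ = step_arrays(*arrays, temp_anomaly, species)
    return replace(
        state, age=float(age[0]), nha=float(nha[0]), dbh=float(dbh[0]),
        hm=float(hm[0]), volume=float(vol[0]),
    )


def annual_growth(landscape_t, landscape_t1, harvested_per_ha=None):
    """Per-cell and national annual volume growth (m³/ha/yr).

    Growth is the change of standing volume between consecutive years
    with any harvest removal credited back, i.e. the biological net
    increment (net of mortality, gross of harvest).  The national value
    is the area-weighted mean over cells.

    Parameters
    ----------
    landscape_t, landscape_t1 :
        :class:`~forestdyn.synthetic.Landscape` states in consecutive years.
    harvested_per_ha :
        Optional per-cell harvested volume (m³/ha) removed during the
        interval, credited back into the growth figure.

    Returns
    -------
    (per_cell, national) : (np.ndarray, float)
    """
    a, b = landscape_t, landscape_t1
    if a.n_cells != b.n_cells or not np.array_equal(
        a.cells["cell_id"].to_numpy(), b.cells["cell_id"].to_numpy()
    ):
        raise ValueError("annual_growth: landscapes are not on the same grid")
    if b.year != a.year + 1:
        raise ValueError(
            f"annual_growth: years {a.year} and {b.year} are not consecutive"
        )
    growth = b.cells["volume"].to_numpy() - a.cells["volume"].to_numpy()
    if harvested_per_ha is not None:
        growth = growth + np.asarray(harvested_per_ha, dtype=float)
    national = float(np.sum(growth * a.cell_area) / (a.n_cells * a.cell_area))
    return growth, national
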