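"""Climate-sensitivity mapping: where does warming reduce growth?

A cell is *sensitive* when its growth under the warming climate falls
below what the fixed current climate would deliver.  Each RCP 8.5 run
is paired against a reference run on the same grid and horizon under
the baseline climate (the no-management current-climate scenario in
the standard analysis), and three measures are derived:

* a window measure — the per-cell decade-mean growth delta
  (warming − reference) over a named analysis window, graded into
  ordinal severity classes by quantiles of the negative deltas;
* a first-year measure — a cell becomes vulnerable the first year its
  trailing 5-yr mean growth delta turns negative (the trailing mean
  smooths interannual climate noise), and
  :func:`vulnerable_cumulative_area` counts the area of cells already
  vulnerable by a given year (monotone in time);
* an area-years measure — the per-year vulnerable area (cells whose
  trailing-mean delta is negative in that year) accumulated over years;
  this series prices the vulnerability-management cost line, which
  accrues every year a cell needs attention.

Growth here is the biological annual increment (harvest credited
back), so harvest events do not register as stock crashes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carbon import DECADE_WINDOWS
from .management import SimulationResult

__all__ = [
    "SensitivityMap",
    "growth_sensitivity",
    "vulnerable_cumulative_area",
    "vulnerable_area_in_window",
]

#: Trailing-mean length (yr) for the vulnerability detector.
TRAILING_YEARS = 5


@dataclass
class SensitivityMap:
    """Per-cell growth sensitivity of a warming run vs its reference run."""

    cell_ids: np.ndarray
    cell_area: float
    window: tuple[int, int]
    delta: np.ndarray  # decade-mean growth delta, m3/ha/yr (warming - reference)
    grade: np.ndarray  # 0 = not sensitive; 1..n_grades with n most severe
    first_year_vulnerable: np.ndarray  # float year, NaN if never
    annual_vulnerable_area: pd.Series  # ha per year (non-sticky)
    cumulative_area_years: pd.Series  # ha-years accumulated (cost-line measure)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def growth_sensitivity(
    run_reference: SimulationResult,
    run_rcp: SimulationResult,
    window="2050s",
    n_grades: int = 5,
) -> SensitivityMap:
    """Build a :class:`SensitivityMap` from a reference/warming run pair.

    ``delta`` is the decade-mean biological growth difference over
    ``window``; cells with ``delta < 0`` receive an ordinal grade from
    quantiles of the negative deltas (``n_grades`` most severe).
    Boundary values grade into the more severe class (half-open
    intervals closed on the severe side).  Runs must share grid and
    horizon.
    """
    if not np.array_equal(run_reference.cell_ids, run_rcp.cell_ids):
        raise ValueError("sensitivity pairing: runs are not on the same grid")
    if not np.array_equal(run_reference.years, run_rcp.years):
        raise ValueError("sensitivity pairing: runs do not share the horizon")
    if isinstance(window, str):
        window = DECADE_WINDOWS[window]
    lo, hi = int(window[0]), int(window[1])
    years = run_reference.years[1:]  # growth interval end-years
    in_win = (years >= lo) & (years <= hi)
    if not in_win.any():
        raise ValueError(f"window {window} outside simulated horizon")

    g_ref = run_reference.cell_growth()
    g_rcp = run_rcp.cell_growth()
    delta = g_rcp[in_win].mean(axis=0) - g_ref[in_win].mean(axis=0)

    grade = np.zeros(len(delta), dtype=int)
    neg = delta < 0
    if neg.any():
        qs = np.quantile(delta[neg], np.linspace(0, 1, n_grades + 1)[1:-1])
        # most negative delta -> highest grade; boundaries to the severe side
        grade[neg] = n_grades - np.searchsorted(qs, delta[neg], side="right")

    # trailing-mean detector
    diff = g_rcp - g_ref  # (n_years-1, n_cells)
    k = TRAILING_YEARS
    first = np.full(len(delta), np.nan)
    annual = np.zeros(len(years))
    csum = np.cumsum(diff, axis=0)
    for i in range(k - 1, diff.shape[0]):
        trail = (csum[i] - (csum[i - k] if i >= k else 0.0)) / k
        tripped = trail < 0
        annual[i] = tripped.sum() * run_reference.cell_area
        newly = np.isnan(first) & tripped
        first[newly] = years[i]
    annual_series = pd.Series(annual, index=years, dtype=float)
    return SensitivityMap(
        cell_ids=run_reference.cell_ids,
        cell_area=run_reference.cell_area,
        window=(lo, hi),
        delta=delta,
        grade=grade,
        first_year_vulnerable=first,
        annual_vulnerable_area=annual_series,
        cumulative_area_years=annual_series.cumsum(),
    )


def vulnerable_cumulative_area(smap: SensitivityMap, through_year: int) -> float:
    """Area (ha) of cells whose first vulnerable year is at or before
    ``through_year`` (monotone non-decreasing in ``through_year``)."""
    years = smap.annual_vulnerable_area.index
    if through_year > years[-1]:
        raise ValueError(
            f"through_year {through_year} beyond simulated horizon {years[-1]}"
        )
    first = smap.first_year_vulnerable
    return float((first <= through_year).sum() * smap.cell_area)


def vulnerable_area_in_window(smap: SensitivityMap) -> float:
    """Area (ha) of cells whose window decade-mean growth delta is negative."""
    return float((smap.delta < 0).sum() * smap.cell_area)
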