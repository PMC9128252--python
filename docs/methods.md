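# Methods

## Scope and data model

`forestdyn` simulates a forest estate as a raster of 1 km × 1 km cells,
each carrying one homogeneous stand (100 ha). The stand state is the
tuple (species, age, site index SI, stems/ha N, mean DBH, mean height
Hm, growing stock V, manageable flag). Seven species types are
catalogued: red pine (*Pinus densiflora*), Korean pine (*P.
koraiensis*), Japanese larch (*Larix kaempferi*), cork oak (*Quercus
variabilis*), Mongolian oak (*Q. mongolica*) and two mixed types (red
pine with each oak). Cell = stand keeps area bookkeeping exact: every
management action moves whole cells, so harvested-area ledgers are sums
of 100-ha units.

## Annual stand update

The year step applies, in a fixed order: age +1 → DBH increment →
height → density ceiling before/after → mortality → volume. The fixed
order makes the per-cell volume balance well defined:
`V(t+1) − V(t) = gross growth − mortality volume − harvest`, which the
engine tracks per cell-year and the test suite checks to 1e-6 relative.

**Volume.** `V = a·DBH^b·Hm^c·N` (m³/ha) with the national stem-volume
coefficients per species (e.g. red pine a = 0.000201, b = 1.7593,
c = 0.6583). Mixed types evaluate the arithmetic mean of their two
component species; this mirrors the carbon factor catalogue, where
every mixed factor equals the component mean at printed precision.

**DBH increment.** The calibrated diameter model behind the original
national analysis is not published, so the package uses a standard
yield-curve family with all coefficients in the species catalogue
(data-only recalibration):

    pot(age) = A · (SI/SI₀) · (1 − e^{−k·age})^p        [cm]
    ΔDBH     = [pot(age+1) − pot(age)] · (N/N_ref)^{−γ} · m(ΔT)

with SI₀ = 14 m, N_ref = 1000/ha, γ = 0.25, and a Gaussian climate
modifier `m(ΔT) = exp(−((ΔT−μ)² − μ²)/(2σ²))` normalised to 1 at zero
anomaly. Conifers have μ = 0 (any warming reduces growth; σ = 2.2–2.6
°C), oaks μ = 0.8, σ = 3.2 (a mild warm optimum), mixed types the
component means. The density modifier is capped at 2.5 so near-empty
stands do not receive unbounded release.

**Height.** Chapman–Richards anchored at the base age:
`Hm = 1.3 + (SI − 1.3)·[(1 − e^{−k_h·age})/(1 − e^{−k_h·30})]^{p_h}`,
so height equals the site index exactly at the base age of 30 years
(common Korean convention) and tends to the 1.3-m breast-height floor
at age 0.

**Self-thinning and mortality.** The maximum stem density is a
Reineke-type power law with a linear dominant-height adjustment,
`Nmax = k₁·(1 + 0.02·Hdom)·DBH^{−1.605}` (Hdom = 1.15·Hm, a fixed
dominant/mean ratio). The original Sterba formulation is cited but not
reproduced in the source analysis; slope −1.605 is the catalogued
default and a log-log regression test pins it. Mortality follows the
ceiling decline:

    M = a · e^{b·(N/Nmax)} · (Nmaxₜ − Nmaxₜ₊₁),   clipped to [0, N]

with a = 0.095, b = 2.0 — not published values; they were chosen to
give ~0.5–2%/yr stem loss on the default landscape and are flagged in
the catalogue as model defaults. After mortality, N is capped at the
current Nmax, so relative density never exceeds 1. Two numerical
guards: mortality is inactive below 5 cm mean DBH (the power-law
ceiling diverges as DBH → 0 and would kill saplings far below canopy
closure), and it is inactive in the rare young-stand years where the
ceiling momentarily rises (height growth outpacing diameter growth).

## Synthetic landscape and climate

The real inputs (national forest inventory plots, the 1:5,000
forest-type map rasterised to 1 km, a regional RCP 8.5 temperature
projection) are not public. The generator reproduces their *structure*:

* species drawn from a configurable mix (default ≈ 37% conifer, 32%
  oak, 26% mixed, 5% minor conifers) with exact largest-remainder
  counts and a seeded shuffle, so realised proportions match requests
  to within one cell;
* stand age = midpoint of a sampled 10-yr age class (I–IX → 5…85 yr),
  with default mass on classes III–V to emulate an estate in transition
  from young-matured to over-mature stands;
* site index uniform on 10–18 m (validated against 5–30 m plausibility
  bounds); the site-index estimation step of the original workflow is
  an inventory calibration with no published formula, so SI is sampled
  directly;
* a manageable mask realised exactly at the requested share (default
  52.48%, the national management zoning);
* initial N/DBH/Hm/V from a zero-anomaly spin-up of each stand from
  planting (3,000 stems/ha) with the growth module itself, so the
  initial state is consistent with the simulator's own dynamics;
* climate: per-cell reference mean temperatures ~N(11.2, 1.6²) °C
  (clipped to 5–16 °C, the South Korean annual-mean range). Baseline
  mode holds every year at the reference; warming mode adds a linear
  trend (default 0.55 °C/decade, the magnitude of regional RCP 8.5
  projections for Korea) plus seeded N(0, 0.3²) interannual noise.
  Baseline and warming series from one seed share their reference
  means, which is what makes paired sensitivity runs well defined.

What the generator does **not** emulate: spatial autocorrelation of
species, age, site quality or temperature (cells are exchangeable);
precipitation, soils and topography; disturbance history; and the
observation error structure of inventory data. Passing tests therefore
demonstrate the pipeline's internal consistency and qualitative
behaviour under realistic marginal distributions, not agreement with
any particular real landscape.

## Management

Clear-cutting is allowed on manageable cells at or above the statutory
final cutting age (larch 50 yr, all others 60 yr). Each year, eligible
cells are ranked oldest-first, ties broken by higher volume then lower
cell id (reproducibility), and taken while the selected area is under
the annual quota (overshoot ≤ one cell). Quotas are expressed as
fractions of landscape area so a desk-scale landscape reproduces the
national ratios: 15,000 (scenario 3) or 35,000 ha/yr (scenario 4) on a
6,056,400-ha estate. Cut cells are replanted at 3,000 stems/ha with a
species chosen from half-open temperature suitability bands evaluated
at the projected cut-year temperature (< 9 °C montane conifers, 9–11.5
°C pines, ≥ 11.5 °C oaks; a boundary value belongs to the warmer
band). A cell already suited to its band keeps its species.

Crown thinning removes 30% of stems from manageable cells within ±1 yr
of stand age 20 or 40 (the ±1 window tolerates annual stepping; a
cell is thinned at most once per window), ranked by volume descending,
under an annual area quota back-calculated from the national
programme's 15-yr cumulative thinned area (2,474,000 ha). The source
description "thinning twice a year" conflicts with "at ages 20 and
40"; it is read as two interventions per rotation, the only reading
consistent with the age rule. On a stand-mean model a true crown
thinning (which removes larger stems) cannot be represented, so
thinning removes stems at the stand mean: N drops 30%, DBH unchanged,
and — volume being linear in N — volume drops exactly 30%. This
assumption is flagged; it slightly overstates post-thinning volume
recovery.

Scenarios 1 and 2 are "overprotection": no management at all. All
management begins in 2016 (so the 2030 and 2050 accounting periods
accumulate over 15 and 35 years).

## Carbon accounting

Stock: `C = V·D·BEF·(1+RS)·0.5` tC/ha with the national
country-specific factors; pools are above- plus belowground live
biomass only (dead organic matter, soil carbon and harvested wood
products are out of scope). Sequestration: `ΔCO₂ = ΔC·44/12`.

National sequestration is computed from the **biological** stock
change: the standing-stock difference with harvest removals credited
back at the pre-harvest species' factors (net of mortality, gross of
harvest). Harvested carbon is neither an instantaneous emission nor
tracked into products — the accounting excludes harvest-related
emissions entirely. The alternative (harvest drops flowing through the
stock series) is available as `net_of_harvest=True` and is used by the
telescoping check (cumulative net change ≡ final − initial stock). The
gross-of-harvest choice is the only one under which managed scenarios
can out-sequester unmanaged ones while clear-cutting ~0.5% of the
estate per year, which is the comparison the scenario analysis is
built around.

## Vulnerability

Each warming run is paired with the current-climate no-management
reference on the same grid. Three measures: (i) the per-cell
decade-mean growth delta over an analysis window, graded into quintile
severity classes over the negative deltas (boundaries grade to the
severe side); (ii) the first year a cell's trailing 5-yr mean growth
delta turns negative (the trailing mean absorbs interannual climate
noise), from which the monotone cumulative vulnerable area derives;
(iii) vulnerable area-years (the per-year vulnerable area summed over
years), which prices the vulnerability-management cost line — that
budget accrues every year a cell needs attention, which is why the
national ledger's "cumulative vulnerable area" can exceed the estate's
physical area. Growth is always the biological increment, so harvest
timing does not masquerade as climate sensitivity.

## Economics

All ledger values are hundred-million KRW (억원) per year; USD figures
are display conversions (default 1,200 KRW/USD). Cost lines follow the
national budget structure: thinning `area·unit/years`; clear-cut
felling `area·mean volume·per-m³ cost/years`; logging overhead
`area·unit/years`; yarding `(area/years)·unit·0.30` (the 30% product
collection share); reforestation `area·mean species price/years`;
vulnerability `area-years·unit/years`. Scenario 1 totals the baseline
tending and reforestation budgets (2,090 + 1,122); scenario 2 adds the
vulnerability line; scenarios 3–4 total only the five
management-programme lines — the combination that reproduces the
published national totals exactly. Line items are carried at full
precision; totals round half-up to integer hundred-million KRW.

Simulation-driven ledgers price felling/transport and reforestation
from the per-species Korea Forest Service unit prices; the per-ha
thinning, overhead, yarding and vulnerability units are the national
reference averages. Carbon credit and log trading prices are **not**
published in the budget tables; the defaults (28,000 KRW/tCO₂;
70,000–90,000 KRW/m³ by species) are documented placeholders and must
be set by the user for any real costing, so benefit levels are
indicative only.

## Calibration

The growth-curve coefficients (A, k, p per species) are model defaults
for an unpublished calibrated diameter model. They were fixed in one
calibration pass against published magnitudes for Korean forests:
national mean growing stock ~150 m³/ha around 2010, mid-age stand
dimensions from yield tables, annual stem mortality 0.5–2%, and a
national mean annual growth near 2.9 m³/ha/yr in the 2030s under a
fixed climate with the default age structure. After that pass the
defaults were frozen. The self-thinning treadmill of the model family
(volume scales with DBH^1.76 while the density ceiling falls as
DBH^−1.605) makes late-age net growth decline faster than the national
projections it emulates; the simulated 2050s growth level is
correspondingly lower, while all decade-over-decade and
between-scenario orderings are preserved.

## Numerical and interface choices

* Deterministic everywhere: every random draw flows from a single
  `numpy` `default_rng(seed)`; categorical allocations use exact
  largest-remainder counts plus a seeded shuffle; schedulers break ties
  by cell id; outputs of one (config, seed) are byte-identical across
  runs, and the config hash is stamped in every CSV header.
* Degenerate inputs: empty stands (N = 0) only age; planted stands
  carry zero volume until diameter growth starts; zero-cost years in
  the benefit/cost ratio are flagged undefined and excluded from trend
  fits.
* Rasters are ESRI ASCII grids (plain text, nodata −9999, row-major
  from the northwest corner); tabular fixtures are CSV with full float
  precision and round-trip-exact parsing; metadata is YAML.
* Problem sizes: the standard analysis runs 10,000 cells (1 Mha) over
  2010–2055; the full four-scenario pipeline with ledgers takes a few
  seconds on one CPU, so the default test and acceptance configuration
  uses the full standard size.

## Known limitations

* Stand-mean state: no diameter distribution, so thinning selectivity
  and dominant-height dynamics are approximations.
* No spatial interaction: no adjacency constraints on harvest, no
  dispersal, no contagious disturbance; cells are independent.
* No disturbances or land-use change; no dead organic matter, soil
  carbon or harvested-wood-product pools; no CO₂ accounting of harvest
  operations.
* Temperature is the only climate driver; precipitation and extremes
  are out of scope.
* Economics exclude discounting, inflation and price dynamics; benefit
  levels depend on placeholder carbon/log prices.
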