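# Methods

## Problem and model

Regulatory air-quality networks are sparse, and their stations' readings
stand in for the exposure of everyone living away from a monitor. This
package quantifies how well a fixed-site monitoring (FSM) network represents
*population health risk* rather than raw concentration, in four stages.

**1. Rasterization.** Street-scale dispersion models emit an irregular point
mesh that is denser near sources. The analysis grid is a regular raster in
projected metres (default 45 m x 48 m cells); each cell's hourly value is the
arithmetic mean of the mesh points it contains, and cells without points are
missing, not interpolated (an unfilled cell is honest about model coverage).
Cells are half-open `[x0, x0+dx) x [y0, y0+dy)` rectangles indexed `(row,
col)` with row 0 at minimum y; a station exactly on a shared edge belongs to
the cell whose half-open interval contains it. Each station becomes a
*pseudo-station*: the modelled series of the cell containing it.

**2. Risk transform.** Hourly concentrations C (ug/m3) become additive
excess hospital-admission risks via the exponential concentration-response
form used by air-quality health indices:

    %AR = (exp(beta * C) - 1) * 100

The default slopes are the Hong Kong all-ages hospital-admission
coefficients (per ug/m3): beta_PM2.5 = 2.180567e-4, beta_PM10 = 2.821751e-4,
beta_NO2 = 4.462559e-4, beta_O3 = 5.116328e-4. They give 0.022%, 0.028%,
0.045% and 0.051% per unit concentration, i.e. 0.51% per 10 ug/m3 of O3 and
0.28% per 10 ug/m3 of PM10. All slopes are configurable; only short-term
(acute) coefficients are in scope. Gaseous fields in ppb are converted with
ug/m3 = ppb * M / V_m, using the conventional molar volume 24.45 L/mol at
25 degC and 1013.25 hPa (scaled ideal-gas for other conditions; both
configurable). The combined risk is

    %AR_total = %AR_NO2 + %AR_O3 + max(%AR_PM2.5, %AR_PM10)

taking the larger PM fraction because the two size fractions overlap
physically and should not be double-counted.

**3. Similarity frequency (SF).** For each cell and each pseudo-station, SF
is the fraction of timesteps at which the two %AR series differ by no more
than a relative threshold, default 20%. The *station* series is the
reference (denominator): the station is the object whose representativeness
is evaluated. A symmetric alternative (denominator = the larger value) is
available via `reference="max"`. Design choices the SF literature leaves
open, fixed here:

- Timesteps missing in either series are excluded from both numerator and
  denominator; with fewer than 75% of the period's timesteps valid
  (configurable `min_coverage`) SF is undefined rather than noisy.
- A reference value below eps = 1e-9 (e.g. %AR = 0 at zero concentration)
  switches to an absolute comparison |a - b| < eps, preventing division
  blow-up while still counting "both zero" as similar.
- The station's own cell has SF = 1 by reflexivity.
- Bands partition [0, 1]: low [0, 0.5), medium [0.5, 0.7), medium-to-high
  [0.7, 0.9], high (0.9, 1] — "well represented" requires SF *strictly*
  above 0.9, and area/population tallies use the same strict cutoff.

**4. Aggregation.** A cell's network representativeness R is the maximum SF
over all stations (undefined only where every station's SF is undefined).
The population-health network representation index over a domain d is

    PHNI_d = sum_{i in d} R_i * pop_i / sum_{i in d} pop_i

with both sums over the same domain (required for district PHNI <= 1) and
cells with undefined R excluded from both sums — missing model coverage
should not penalize the network. Per-station summaries tally the area (km2)
and population of cells with SF > 0.9 *per station*, so overlapping
stations' tallies can overlap. District membership is by cell-center
containment in the district polygon; fractional-area weighting is out of
scope. Seasonal analyses (spring Mar-May, summer Jun-Aug, autumn Sep-Nov,
winter Dec-Feb; within a single analysis year winter is that year's Jan, Feb
and Dec) recompute SF from scratch on each period's hours. Population
rasters coarser than the analysis grid are resampled by nearest coarse-cell
center, with each coarse count split *equally* among its assigned fine
cells: a literal nearest-neighbour value copy would inflate the city total
by the cell-area ratio, whereas the equal split conserves it exactly.

**Verification statistics.** Model-vs-observation agreement uses the
standard Willmott index of agreement,
IOA = 1 - sum(P_i - O_i)^2 / sum(|P_i - Obar| + |O_i - Obar|)^2, plus RMSE.
A variant with |P_i + Obar| in the denominator circulates in parts of the
applied literature; it is not bounded like the standard form and is only
available behind `printed_variant=True` for audit. IOA is undefined (NaN)
when the observations have zero variance.

## Synthetic scenarios

Real inputs (street-scale model output, gridded census counts) are large and
proprietary, so `aqrep.synthetic` generates scenarios carrying exactly the
statistical structure the conclusions rest on:

- **Regional background**: one AR(1) hourly series per pollutant, spatially
  constant — the regional-transport component that makes PM risk widely
  represented. Defaults (ug/m3, AR(1) coefficient): PM10 35 (0.85), PM2.5 20
  (0.85), NO2 25 (0.7), O3 70 (0.7); PM more persistent than the gases.
- **Local plumes**: point/line sources add `strength * exp(-dist/decay)`
  scaled by a diurnal traffic-like factor in [0.6, 1.4]. Defaults: two
  crossing "roads" contributing up to 50 ug/m3 of NO2 with a 120 m decay
  length — street-scale NO2 heterogeneity.
- **Conserved total oxidant** (`coupling="ox_conserved"`, the default): a
  spatially uniform hourly Ox series (mean 180 ug/m3) is drawn and
  O3 = Ox - NO2, clipped at 0. NO2 plumes then titrate O3 locally, giving
  the observed spatial anticorrelation while NO2 + O3 — and hence nearly the
  combined risk — stays spatially uniform. The Ox level is set high enough
  that clipping is rare under the default plumes, so conservation holds to
  machine precision.
- **PM intermediacy**: a regional mass fraction (default 0.65) keeps PM
  fields between the fully regional and fully local extremes, with weak
  road-linked plumes carrying the local share.
- **Population**: a mixture of Gaussian clusters (default 4 clusters,
  sd 120 m) scaled to the configured total (default 1e5 persons). The
  cluster width is chosen so the densest cells run roughly an order of
  magnitude above the domain mean — the density contrast of a high-rise
  city, which is what makes population- and area-based rankings diverge.
- **Stations**: general stations at population-cluster centers, roadside
  stations on the source lines, a background station at the corner farthest
  from all sources — mirroring real siting practice. Defaults: 3 general,
  1 roadside, 1 background.
- **Seasonality** is emulated by per-month scale factors on the background
  means; there is no meteorology, chemistry or terrain, so passing tests
  demonstrate the *mechanisms* (heterogeneity degrades representativeness;
  conserved Ox homogenizes combined risk) rather than any city's numbers.

Everything is deterministic given the seed. What the generator does *not*
emulate: realistic dispersion physics, emission inventories, coastlines or
terrain, instrument error, and covariance between population and emissions
beyond station siting.

`brute_force_phni` recomputes %AR, SF, R and PHNI with plain nested Python
loops sharing no code with the vectorized pipeline, as an independent
oracle; it refuses grids over 50x50 or more than 2000 hours.

## Problem sizes and numerics

The bundled checks run the mechanism reproduction on a 30x30 grid over 720
hours (one month of hourly data, 648,000 cell-hours) and the
pipeline-vs-oracle equivalence on 20x20 x 500 h scenarios over 10 seeds;
both complete in seconds on one core while exercising every pipeline stage
at full fidelity. Oracle equivalence is asserted to 1e-12 absolute — SF
ratios are integer counts divided by integer counts and match exactly;
population-weighted means differ only by float summation order. All
arithmetic is float64; no iterative solvers or tolerances beyond the
epsilon-floor in SF and the 1e-6 relative conservation check on population
resampling.

## Known limitations

- SF compares series pointwise in time; phase-shifted but otherwise
  identical diurnal patterns count as dissimilar.
- The per-station reference convention makes SF mildly asymmetric; the
  `reference="max"` option bounds the relative difference symmetrically.
- District PHNI by center containment misassigns cells straddling a border;
  negligible at 45 m resolution against km-scale districts.
- Long-term (chronic) risk coefficients, other pollutants (e.g. SO2), and
  station-placement optimization are out of scope.
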