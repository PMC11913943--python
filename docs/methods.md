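# Methods

## Scope and data model

The package analyses categorical land-cover grids (here three classes:
woody vegetation, grasses, bare areas) observed at a few dates on a common
lattice, together with continuous terrain covariates. All grids are
row-major with row 0 northernmost; the centre of cell (r, c) sits at
`origin + ((c + 0.5)·px, −(r + 0.5)·px)`. Multi-grid operations require
exact alignment (shape, pixel size, origin). Areas are carried in hectares
throughout (`pixel_size² / 10 000` ha per cell); percentages are carried at
full precision and rounded only in outputs.

## Terrain covariates

* **Slope/aspect** use the Horn 3×3 kernel. Aspect is degrees clockwise
  from north toward the steepest *downslope* direction; flat cells get the
  sentinel −1. Edges are handled by odd-reflection padding, which is exact
  for planes and acts as a one-sided difference; any 3×3 window containing
  nodata (including its centre) yields nodata.
* **TWI** is `ln(a / tan β)` with `a` the specific catchment area from D8
  flow accumulation (steepest descent among the 8 neighbours, deterministic
  tie-break in the order N, NE, E, SE, S, SW, W, NW; pits accumulate
  without breaching) and `β` the Horn slope. `tan β` is floored at a
  configurable ε (default 1e−6) so flat cells stay finite. The index is
  invariant to adding a constant to the DEM.
* **Road distance** is the exact Euclidean distance from each cell centre
  to the nearest polyline, evaluated per input geometry (not on a union:
  GEOS unions drop zero-length degenerate segments).
* Raster I/O supports single-band GeoTIFF (georeferencing via the
  ModelPixelScale/ModelTiepoint/GDAL-nodata tags) and ESRI ASCII grids;
  both round-trip values, nodata and geometry exactly. Bilinear resampling
  is refused for categorical grids.

## Transition matrices and completion

`crosstab` counts jointly valid cells; nodata at either date excludes the
cell (the count is reported, never folded into an extra class). Published
transition tables often print only the dominant cells; `complete_matrix`
solves the unknown cells from the row/column marginals by non-negative
least squares over the stacked constraints, reports the worst absolute
constraint residual, and raises if it exceeds a tolerance (default 0.5 ha,
chosen to absorb 2-decimal rounding of printed tables).

The packaged case-study tables have two internal inconsistencies that the
package preserves rather than repairs: (1) several printed percent-cover
entries disagree with their own hectare columns (worst in the 2019 row,
64.52% printed vs 63.48% recomputed), so percent covers are always
recomputed from hectares; (2) the 2019–2023 grasses→grasses cell (97.19 ha)
is incompatible with the grass marginals by ~17 ha, and 2014–2019 carries a
~1.2 ha column residual — only 2009–2014 completes within the default
tolerance, so the dataset loader relaxes the tolerance per interval and
reports the achieved residual. A consequence is that the extent-wide
uniform intensity recomputed from the completed matrices (~4.5 %/yr) does
not reproduce the study's printed 4.45 %/yr exactly; the discrepancy is
documented, not resolved.

## Intensity Analysis

Interval, category and transition levels follow the standard three-level
framework (see module docstring for the formulas). Numerical choices:

* Undefined intensities (zero denominators — a class absent at one date)
  are reported as missing and excluded from active/dormant and
  target/avoid flags, never coerced to 0.
* The uniform line for category-level comparison is the multi-interval `U`,
  not a per-interval rate.
* The loss-side transition intensities (`Q_tmj` relative to the
  destination's final size, `V_tm` over all non-m area at the end) are an
  extension following the same framework's conventions.
* A flag is *stationary* iff defined and identical across all intervals.

## Accuracy and disagreement

Kappa and the class-wise accuracies are computed directly from the count
matrix (rows = reference, the fixed dialect for all I/O); the test suite
cross-checks kappa against an independent implementation. Total
disagreement `D = 1 − Σ p_gg` is split into quantity
`Q = ½ Σ |p_g· − p_·g|` and allocation `A = D − Q`; the combined QADI index
is taken as the Euclidean norm `√(Q² + A²)` of the (Q, A) point — the
published source for the index states its 0–1 range but no formula, so the
combining rule is isolated in one function and can be swapped.

## CA–Markov simulation

Six phases: inputs, Pearson correlation screening of covariates, Markov
area change, MLP transition-potential modelling, CA allocation, validation.

* **Markov**: the row-normalized matrix of one observed interval projects
  class areas per step; zero-area rows act as identity. Hectare targets are
  converted to integer cell demands by largest-remainder rounding, so
  realized counts equal demands exactly and totals are conserved. The
  matrix is applied per interval as estimated; projecting an interval of a
  different calendar length with it is accepted and documented rather than
  annualized.
* **Potentials**: one binary MLP per transition (changed-to-j vs other
  source-class cells) over standardized covariates + current-class one-hot
  + 3×3 Moore class fractions. Training uses a seeded balanced sample
  capped at 5000 per side; transitions with fewer than 50 observed change
  cells fall back to their empirical base rate (zero when unobserved, so a
  no-change interval yields ~0 potentials everywhere). Balanced training
  makes potentials ranking scores, not calibrated probabilities — the
  Markov chain owns the quantities. MLP settings follow the common
  MOLUSCE-style convention (10 logistic hidden units, SGD, learning rate
  0.1, momentum 0.05, ≤1000 epochs), none of which the original study
  states.
* **Allocation**: per transition, score = potential × (Moore fraction of
  the destination class)^w (w ≥ 0, default 1; w = 0 disables the
  neighbourhood term), highest scores convert first, ties broken by a
  seeded shuffle. Demands above the available source cells raise an error
  naming the transition.
* The whole simulate path is a pure function of (inputs, seed).

## Synthetic landscape generator

The generator emulates the study conditions: a 374×374 lattice at 5 m
(~350 ha), DEM a smoothed seeded random field rescaled exactly to
720–840 m, initial class fractions (0.3769, 0.6025, 0.0206) matching the
2009 composition, three intervals of (5, 5, 4) years. Latent surfaces are
white noise smoothed with a uniform kernel — a cheap stand-in for a
Gaussian random field with a tunable correlation length (default 15 cells).

Transitions follow a per-interval logistic rule
`P(i→j) = expit(base + coef·x_std + neighbor_coef·f_j)` on standardized
covariates; the standardization constants are stored with each series for
recovery tests. The default dynamics reproduce the magnitude of the
published flows (grass→woody ≈ 0.25 per 5-year interval, woody→grass and
grass→bare a few percent, bare mostly reverting to grass) and give *every*
flow the spatial structure its real-world process has: encroachment climbs
from wet low ground and spreads from thicket edges (negative DEM, positive
TWI and woody-neighbourhood coefficients), reversion favours high dry
ground at grass edges, bare patches open near roads and revegetate from
adjacent grass. Spatially unstructured flows would make *any* allocation
model score below persistence on those flows by construction, which is not
how the underlying processes behave. Under these defaults the simulated
woody trajectory (0.38 → 0.71 of the landscape over three intervals)
closely tracks the observed one (0.38 → 0.74).

What the generator does **not** emulate: spectral/classification noise,
fire and grazing processes, climate forcing, sub-pixel mixtures, and
temporal autocorrelation of disturbance. Passing the end-to-end tests
therefore shows the pipeline recovers *known* logistic covariate-and-
neighbourhood dynamics at realistic scale and rates — not that an MLP would
achieve the same skill on real imagery.

## Problem sizes and determinism

Module tests run on 50–200-cell-wide lattices; the end-to-end recovery
checks use the full 374×374 reserve scale (≈140 000 cells), where fitting
and a simulation step complete in seconds. Every stochastic step consumes
an explicit seed through `numpy.random.SeedSequence` (with fixed per-stage
spawn keys), so identical inputs and seeds reproduce bit-identical outputs,
including across the CLI.

## Known limitations

* The matrix completion assumes the printed marginals are authoritative;
  where a published table contradicts them the residual is surfaced, but no
  attempt is made to guess which entry is wrong.
* Potentials are re-evaluated each simulation step on the evolving map, but
  the Markov chain is held fixed; long projections inherit any
  non-stationarity of the calibration interval.
* Accuracy assessment is unweighted (no stratified area estimation or
  confidence intervals).
* Reprojection between coordinate reference systems is out of scope; all
  inputs must share one projected system.
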