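# Methods

## Problem and scope

The package models the habitat of the Lake Erie Silver Chub, a rare and
patchily distributed minnow, from fishery-independent bottom-trawl
surveys and 90-m habitat rasters of the western basin. Two models are
distinguished: a *benchmark* (potential) model restricted to
anthropogenically resistant variables — depth, effective fetch,
distances to wetland types and major rivers, river density, SAV cover,
shoreline geomorphology — and a *disturbance* model that adds monthly
surface-temperature summaries and shoreline-modification percentages.
Their prediction maps are contrasted cell by cell to locate habitat that
is degraded relative to its potential.

The real observation data are agency-held. All numeric machinery is
therefore exercised on a synthetic study unit with known ground truth;
statistics that depend only on printed tables (confusion counts, cell
allocations, validation frequencies) are recomputed exactly.

## Spatial framework

Row-major grids, origin upper-left, half-open 90-m cells (a point on a
shared edge belongs to the lower-right cell); cell area is fixed at
cell_size², 8,100 m² at the native resolution. Rasters are ESRI ASCII
grids; a stack shares one nodata mask across variables. AHA zoning is an
integer raster; AHA CPUE means are unweighted arithmetic means of the
member tows (weighting by swept area is a defensible alternative; the
source procedure is stated only as averaging).

## Abundance classes

CPUE = count × 1,000 / area_swept. Mean CPUE maps to the ordinal classes
with boundaries 0.5, 1.5, 10.5 — i.e. rounding to the nearest labelled
density. These boundaries are not arbitrary: the published minimum
population estimates are reproduced exactly by lower representative
densities 10.5, 1.5 and 1.0 fish/1,000 m², which pins the rounding
semantics. A mean below 0.5 backed by at least one captured fish is
promoted to Marginal (the smallest positive CPUE on record, 0.32,
belongs to a presence); the flag is exposed so users can disable the
override.

## The network

One hidden logistic layer; by default a single logistic output trained
on class/3, so the net is a bounded regression on the ordinal scale and
the class is recovered by rounding (a 4-output one-hot variant sits
behind `NetConfig.output_mode`). Inputs are z-scored by training-set
statistics. Training is full-batch gradient descent on squared error
with momentum; a seeded 20% holdout never enters the gradients, the
returned weights are those of the best-holdout epoch, and training stops
after `patience` epochs without holdout improvement.

Optimizer defaults (learning rate 2.0, momentum 0.9, ≤ 20,000 epochs,
patience 200, init U(−0.5, 0.5)) were chosen for reliable convergence of
mean-gradient full-batch updates at this scale; the original commercial
tool's internals are unpublished, so these are free parameters, exposed
in `NetConfig`. With much smaller rates the optimizer stalls before the
holdout error moves at all.

Variable influence is the connection-weight trace Σ_h w_ih·w_ho, signed;
an optional normalization rescales the largest magnitude to a reference
value. Magnitudes are not comparable to the true data-generating weights
(the net is nonlinear); the sign pattern of dominant drivers is the
recoverable quantity, and that is what the recovery test asserts.

## Synthetic lakescape

The generator states a world and keeps it fixed:

- **Habitat fields.** Box-kernel-smoothed white noise (range 10 cells =
  900 m, a typical lakescape autocorrelation scale), affinely rescaled
  so over-water sample mean and sd equal the configured targets; means
  are the published basin means; sds are not published and default to
  plausible heterogeneity levels (≈ half the mean magnitude for
  distances and percentages, 3 m for depth). An elliptical mask plays
  the shoreline.
- **True suitability.** density = s · softplus(score − b), score the
  weighted sum of z-scored fields with signed weights following the
  published importance pattern. The two link constants are set by
  quantile matching so Optimal covers 10.3% and Unsuitable 17.1% of the
  lake — the benchmark map's shares. The two middle-class shares then
  follow from the link's shape rather than being controlled; the
  synthetic Marginal share (~7%) is below the study's (~30%). Matching
  all four shares would need a third constant and is deliberately not
  done.
- **AHA partition.** Seeded k-means on (row, col, depth, fetch) with
  position weighted up, giving contiguous-ish zones of similar
  depth/energy, 300 zones by default.
- **Catches.** Tow locations uniform over water; swept areas gamma
  (shape 4) around 3,125 m² — the area implied by the record's smallest
  positive CPUE of 0.32 from one fish; counts negative-binomial with
  mean density × area/1,000 and dispersion k = 0.10, frozen once by
  Monte-Carlo calibration so the positive-tow fraction matches the
  surveys' 676/2,066. Smaller k means more zero-inflation.

What a green test does and does not establish: the world has no
bathymetric realism, no gear or seasonal effects, no temporal trend, and
its AHAs are statistical clusters, not the hydrogeomorphic units of the
real framework. Tests on it establish that the algorithms are computed
correctly and that the pipeline can recover a known signal — not that
the published maps are right.

## Recovery experiment

`pipeline.recovery_experiment` trains the 46-neuron network on 2,066
rows whose features are the habitat values at simulated tow cells and
whose targets are the *true* classes there, then checks held-out
presence–absence kappa (substantial, ≥ 0.6) and the recovered driver
signs. Truth labels are used deliberately: labels derived from the
calibrated catch noise carry so little presence–absence information
(the measured label-vs-truth kappa ceiling is ≈ 0.1–0.3, because
overdispersion this strong makes zero catches nearly density-
independent, and AHA-mean densities of a right-skewed surface almost
never classify Unsuitable) that no model could reach the bar against
truth through them. The noisy-catch path is exercised separately:
classification, positive-tow fraction, AHA aggregation, and the
pipeline's own evaluation against observed labels.

## Numerical choices

- PCA on the correlation matrix (variables span metres to percentages);
  loadings are eigenvectors × √eigenvalue; eigenvector signs fixed by
  making each axis's largest-magnitude element positive; rank ties
  broken by input column order. Constant columns are rejected by name,
  with an O(eps) relative tolerance for float residue.
- Kappa: raises explicitly when chance agreement is 1 (degenerate
  marginals). Per-class kappa is one-vs-rest.
- Binned K-S: D = max |ΔCDF| over ordered bins; critical D = 1.36/√n
  asymptotic, with n supplied separately when tallies are fish counts
  but the sampling unit is the collection. Exact small-n tables are out
  of scope.
- Patches: 8-connectivity by default (the common FRAGSTATS default);
  Aggregation Index counts rook adjacencies against the largest-square
  maximum, per its definition; the two connectivities are configurable
  independently. Nearest-neighbour distance approximates edge-to-edge as
  boundary-cell center distance minus one cell size, floored at 0.
  Mean patch size is reported in hectares (total class area divided by
  patch count).
- Model contrast: the "same class" share is judged at the same grouping
  level as the transition table (Appropriate = Moderate + Optimal merged
  by default), so identical + transitions partition the area.
- Population error bands are user-supplied relative percentages carried
  as annotation; the published derivation from network RMSE is not
  reconstructable.
- Shannon patch diversity uses natural logs over renormalized area
  shares; this reproduces the published 1.26/1.34 from the percent-area
  columns.

## Known limitations

The network evaluation on the synthetic pipeline's own training rows is
an interpolating fit (agreement near 1.0), as expected when AHA-mean
features index a few hundred distinct zones; it mirrors the study-style
self-agreement table rather than out-of-sample skill. Middle-class area
shares of the synthetic truth are not calibrated. Reprojection, vector
outputs, catchability correction and cartographic styling are out of
scope.
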