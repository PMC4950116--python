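# Methods

## Scope and model

`nichedyn` measures change in the *realized* climatic niche of a species
between its native and alien ranges. The realized niche is represented as
an occupancy surface on a gridded two-axis ordination of climate
(PCA-env): occurrence density, corrected for the availability of climatic
conditions in the range's background, normalized to unit mass. All
downstream statistics — Schoener's D, the permutation tests, the bootstrap
optimum/breadth inference, and the expansion/stability/unfilling
decomposition — operate on these surfaces. The approach deliberately makes
no attempt to estimate fundamental niches or to fit distribution models;
it describes where the species actually occurs relative to what climates
were on offer.

Assumptions worth keeping in mind:

* occurrence records are an unbiased sample of the occupied climate within
  each background (density correction removes availability bias and
  range-level sampling-effort differences, not geographic sampling holes);
* the background (union of regions with ≥ 1 occurrence) adequately bounds
  the climates the species could have reached;
* two PCA axes capture the climate contrast that matters; variance
  fractions are reported so this can be checked per species.

## Environmental space

* **Variables.** Six bioclim-style variables: bio5, bio6, bio7 (= bio5 −
  bio6), bio9 (°C), bio15 (unitless), and annual water balance
  WBAL = Σ months (precipitation − PET) (mm). A correlation screen reports
  pairs with |r| ≥ 0.8 (advisory; highly correlated temperature variables
  are expected and retained).
* **Ordination.** PCA on the standardized climate of the pooled native +
  alien background cells; two axes kept. Axis signs are fixed so the
  largest-magnitude loading on each axis is positive, making shift signs
  reproducible.
* **Grid.** R × R (default 100) axis-aligned cells spanning the pooled
  score range plus a 5% margin per side, so kernel mass is not truncated
  at the extremes.
* **Densities.** Binned kernel estimates: points are counted on the grid
  and convolved with a Gaussian product kernel. Bandwidth per axis follows
  a Silverman-type rule h = σ · n^(−1/6) (overridable). Surfaces
  normalize to ∫ = 1 (cell-sum × cell-area).
* **Occupancy.** z = o/e where e exceeds ε = 10⁻¹⁰ × max(e), else 0, then
  normalized to unit sum. The ε floor prevents division blow-ups at the
  background fringe; z is invariant to positive rescaling of o or e.

## Inference

* **Equivalency test.** Pooled occurrences are randomly reallocated
  between ranges (sizes preserved; ordination, grid and availability
  surfaces fixed) n_perm = 99 times; p = (1 + #{D_perm ≤ D_obs}) /
  (n_perm + 1). The add-one estimator keeps p > 0.
* **Similarity test.** The moving range's occurrence density is translated
  so its centroid lands on a random available background cell, re-masked
  and renormalized; p = (1 + #{D_perm ≥ D_obs}) / (n_perm + 1). Both
  directions (native→alien, alien→native) are reported. Centroid
  translation was chosen over relocating raw points because it preserves
  the niche's shape while randomizing only its position.
* **Bootstrap.** B = 100 resamples of each range's occurrences (with
  replacement). Backgrounds stay fixed by default, so the per-replicate
  ordination refit is deterministic and is computed once; an option
  resamples background cells too, in which case each replicate's loadings
  are sign-aligned to the full-data reference (without alignment, shift
  signs across replicates are meaningless). Per replicate and range,
  P = 100 grid pixels are drawn with probability ∝ z at cell centers;
  optimum = median, breadth = 0.975 − 0.025 quantile span of the pixel
  coordinates. A replicate's breadth is floored at one grid cell width
  (the smallest resolvable breadth) to keep ratios finite.
* **Significance.** Central 95% of the B shift values excludes 0 → shift;
  of the B breadth ratios entirely above/below 1 → broadening/contraction.
* **Expansion/unfilling.** Niche extent defaults to the full observed
  support (cells with z > 0; the quantile is configurable, e.g. 0.75/0.90,
  trimming the lowest-density cells to the requested mass). E = alien mass
  outside the native extent, S = 1 − E, U = native mass outside the alien
  extent. "Analogous" mode first intersects the two backgrounds'
  available-climate masks and renormalizes, separating niche change from
  availability change.
* **Scenarios.** Shift significant on ≥ 1 axis counts as shifted;
  broadening/contraction on ≥ 1 axis (without the opposite on the other)
  counts as breadth change; opposite significant changes on the two axes
  leave the species unassigned. Mapping: (shift, contracted) → A,
  (shift, unchanged) → B, (shift, broadened) → C, (no shift, contracted)
  → D, (no shift, broadened) → E, (no shift, unchanged) → F. Expansion or
  unfilling strictly greater than 10% adds an E/U annotation.
* **Paired models.** Differences are sexual − apomictic. The mean of the
  pair differences is tested with a family-grouped random-intercept model;
  per-species expansion/unfilling are regressed on reproduction mode or
  native niche breadth with pair-grouped random intercepts (statsmodels
  MixedLM, REML). When the grouping factor is singular the model reduces
  to OLS and the reduction is logged. Reported degrees of freedom follow
  the simple fixed-effect convention df = n − 2 (11 for 13 pairs, 24 for
  26 species). Native niche breadth, where a scalar is needed, is the
  geometric mean of the two per-axis central-95% spans of the native
  occupancy.

## Synthetic data

The simulator emulates the ingredients of a global niche-comparison study
without any downloads:

* **Climate.** Gaussian random fields (smoothed white noise; smoothing σ
  sets the autocorrelation range) mixed through the matrix square root of
  a requested cross-variable correlation. Defaults place a temperature
  block (bio5/bio6/bio9, r ≈ 0.5–0.7) against weakly coupled water
  variables. Variable scales are realistic (e.g. bio5 ≈ 26 ± 6 °C,
  WBAL ≈ 150 ± 250 mm, floored at −460 mm so monthly stacks stay
  positive). bio7 is derived as bio5 − bio6. Optional monthly
  precipitation/PET stacks are constructed to sum exactly to the annual
  water balance.
* **Regions.** A Voronoi mosaic of random seed cells stands in for an
  ecoregion map.
* **Species.** Suitability is Gaussian in *standardized raw climate space*
  (not PCA space, so the pipeline's own ordination is exercised honestly),
  with native center μ and covariance Σ; the alien niche is centred at
  μ + δ with covariance ρ²Σ. Occurrence cells are drawn with probability ∝
  suitability (with replacement, jittered within the cell); an optional
  geographic mask withholds part of the alien range (unfilling imposed as
  a non-climatic constraint). Every table carries its generating
  parameters for recovery tests.

What the simulator does **not** emulate: geographic sampling bias,
spatially aggregated duplicate records beyond cell scale, coastlines/
missing data, climate non-stationarity, and real ecoregion geometry.
Passing calibration and recovery tests therefore demonstrates the
machinery is correct and well-calibrated under its own assumptions — not
that any particular real data set satisfies those assumptions.

## Validation experiments and their design

Calibration and recovery run on a fixed virtual-study condition: an
80 × 80 landscape of 0.25° cells, autocorrelation range 3 cells, the
default correlation structure, 16 regions, isotropic niche SD 0.45
landscape-SD per variable, n = 300 occurrences per range (100 for the
equivalency calibration, matching its typical use on thinned data).

Two range layouts are used deliberately:

* **Shared-environment design** (checkerboard masks): the two ranges are
  geographically disjoint but climatically interchangeable. This is the
  correct *null* for type-I checks — when the generating niches are
  identical and the available environments match, the equivalency test
  rejects at the nominal 5% and the bootstrap shift flag stays quiet.
* **Split design** (west/east halves): realistic invasions in which
  availability itself differs between ranges. Under this layout a species
  with an unchanged fundamental niche still shows realized-niche change,
  and the equivalency test rejects far above nominal — that is the
  phenomenon the method measures, not a test defect, and it is why null
  calibration must not use split ranges.

The native-breadth → expansion experiment builds 13 pairs on a split
landscape with native niche SDs spanning 0.35–0.9 landscape-SD, a fixed
0.8-SD optimum shift in a random direction, and alien breadth factor
ρ = 0.65/SD — narrow-niche natives under-fill a broader fundamental niche,
so their alien niches expand more, which the pair-grouped mixed model
recovers as a negative breadth coefficient.

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one rule (never 0); n_perm defaults
  to 99.
* Single points (zero Silverman bandwidth), constant climate variables,
  degenerate score ranges, empty ranges, all-zero suitability,
  backgrounds without analogous climates, and B/P < 2 are rejected with
  explicit errors rather than propagating NaNs.
* Spatial thinning uses greedy sequential elimination in seeded random
  order (kept points never lie within the radius of one another; the
  operation is idempotent); distances are great-circle by default, planar
  for flat synthetic landscapes. Native and alien points never suppress
  each other.
* Thinning precedes the 40-record minimum filter, so the filter judges
  analysis-ready data.
* All randomness flows through explicit integer seeds; identical seeds
  give bitwise-identical outputs, including whole pipeline runs.

## Known limitations

* The fringe behaviour of z depends on the bandwidth rule: occupancy at
  cells where e is tiny is noisy, and the full-support niche extent is
  therefore generous; the extent quantile exists for sensitivity checks.
* The equivalency test's permutation null assumes exchangeable ranges; for
  ranges with strongly different available climates it is anti-conservative
  as a test of *fundamental* niche identity (see above).
* Degrees of freedom for the mixed models are a convention, not a
  Satterthwaite approximation; with few pairs the tests are coarse.
* The simulator's Gaussian-suitability species cannot represent
  multimodal or threshold responses.
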