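# Methods

## Problem and approach

`phenocrown` implements an object-based pipeline for discriminating deciduous
tree species from a time series of very-high-resolution (decimetre-scale)
crown imagery. The unit of analysis is the individual, manually delineated
tree crown. For every survey date a stand is covered by two co-registered
3-band orthomosaics — one from a normal RGB camera and one from a modified
colour-infrared (CIR) camera recording NIR, R, G — and each crown is reduced
to a vector of spectral and texture metrics per (date, camera). Species are
then classified with repeated, class-balanced Random Forests scored by
averaged out-of-bag (OOB) error, and all one-, two- and three-date
combinations are ranked by that error to find the acquisition window(s) that
separate the species best.

The scientific mechanism the package encodes: species separability is not
driven by how colourful the canopy is, but by the *within-species* synchrony
of phenology. The within-species spectral variance is lowest at the end of
leaf flush and highest in early spring and late autumn; the best acquisition
window minimizes within-species variation while between-species differences
are still present.

## Crown metrics

1. **Crown narrowing.** Crown polygons are shrunk inward by a negative
   buffer (default 0.50 m, map units) to discard mixed border pixels.
   Crowns whose narrowed polygon is empty, or covers no pixel center, are
   dropped with a logged reason.
2. **Shadow masking.** Pixel intensity is the sum of the three band values;
   *relative intensity* is its min–max normalization over all valid pixels
   of the mosaic, scaled to [0, 100]. Crown pixels with relative intensity
   strictly below a threshold (default 20) are discarded as shadow; a pixel
   exactly at the threshold is kept. A constant-intensity mosaic maps to 100
   everywhere (nothing is shadow). The min–max reading of "normalized" was
   chosen over dividing by the theoretical maximum (3×255) because it is
   scale-free across dates with different exposures.
3. **Spectral metrics** on the surviving (sunlit) pixels: per-band mean and
   population SD; the three unordered band-ratio pairs of the means
   (unordered to avoid redundant reciprocals); normalized bands
   (mean over 3-band sum); and three normalized-difference indices computed
   from the crown-mean band values — NGRVI, NGBI, NRBI for RGB (bands
   B, G, R) and NDVI, GNDVI, NGRVI for CIR (bands NIR, R, G), with
   ND(x, y) = (x − y)/(x + y) and a 0-by-convention rule (logged) for zero
   denominators. Indices of means rather than means of per-pixel indices:
   stabler under 8-bit quantization, and the difference is second order.
4. **Texture metrics**: seven GLCM statistics (variance, homogeneity,
   contrast, dissimilarity, entropy, second moment, correlation) per band.
   The GLCM is *object-level*: values are quantized to 32 equal-width bins
   over the fixed [0, 255] scale, co-occurrences are counted for the four
   offsets (0,1), (1,0), (1,1), (1,−1) only where **both** pixels belong to
   the crown's sunlit mask, symmetrized, pooled over offsets and
   normalized. Entropy uses the natural logarithm; correlation is 0 by
   convention when the marginal variance is 0. An object-level GLCM has no
   window-size free parameter, unlike moving-window texture rasters averaged
   over the crown; results are therefore not numerically interchangeable
   with window-based implementations.
5. **Retention rule.** A crown enters the feature table only if it has at
   least `min_sunlit` (default 10) sunlit pixels and valid GLCM pairs in
   *every* requested layer, so the table has no absent cells. `n_sunlit` is
   stored per layer for bookkeeping but never used as a classifier feature —
   crown size would leak species identity through the sampling design.

## Classification protocol

Defaults: 20 repetitions, 500 trees, 50 crowns per class. Each repetition
draws a fresh balanced sample (without replacement) with seed `seed + r`,
fits a Random Forest with `floor(sqrt(p))` features tried per split (the
classical default; no tuning), and records OOB predictions — for each crown,
the majority vote of the trees whose bootstrap excluded it, with ties broken
toward the first class in sorted species order. The scenario's score is the
mean of the per-repetition OOB misclassification fractions; per-class errors
and a pooled confusion matrix (rows = truth, sorted species order) are
reported alongside. Rows with any absent metric for the scenario's columns
are excluded before balancing (exclusion, not imputation, since the feature
tables are complete by construction).

## Date-combination search

Scenarios are all size-k survey subsets (k = 1, 2, 3). Multi-date scenarios
always pool RGB+CIR features per survey — a "survey" is the pair of flights;
single-date camera comparisons (RGB-only / CIR-only / combined) run under
identical seeds and therefore identical balanced samples. Each scenario's
seed is a SHA-256 hash of (master seed, sorted survey ids, camera mode)
reduced mod 2^31, so results are independent of evaluation order and adding
scenarios never perturbs existing ones. Ranking is ascending by overall OOB
error with ties broken by earliest survey date, then lexicographic survey
id. Each scenario resamples independently; no balanced sample is shared
across scenarios.

## Synthetic scene generator

The generator emulates exactly the statistical structure the analysis
consumes, not radiative transfer:

- 5 species groups (birch, oak, maple, ash, poplar), a 4-band mean spectrum
  per species × date (8-bit DN), crown-level offsets with per-date SD
  (`between_tree_sd`), per-pixel noise (SD 4 DN), non-overlapping circular
  crowns placed by rejection sampling on a north-up metric grid at 0.20
  m/pixel, a dark textured background, and per date one RGB (B, G, R) and
  one CIR (NIR, R, G) layer sharing crown offsets and shadow geometry.
- **Shadows** are contiguous, randomly oriented angular sectors holding
  `shadow_fraction` (default 0.3) of each crown's pixels, attenuated ×0.1.
  A sector covers the same fraction of every concentric subregion, so the
  inward-buffered crown loses the nominal fraction too; only detectability
  by the 20 % relative-intensity rule matters downstream.
- **Optional degradations**: a multiplicative luminosity ramp across
  columns, and a CIR band-mixing toggle (off by default) that multiplies
  the CIR bands by a near-collinear matrix to emulate the modified camera's
  redundant NIR sensitivity.
- **Presets.** `null_world`: identical spectra and spreads for all species
  (between-tree SD 1 DN) — a pure chance-level control. `separable_world`:
  axis-aligned mean offsets of 30 DN against a between-tree SD of 2 DN
  (≥ 10 SD spacing at every date). `planted_optimum`: one seed-chosen date
  t* with 18 DN spacing at SD 2, all other dates ~5–7 DN spacing at SD
  ~6 — the separation ratio (min pairwise distance of species means over
  max between-tree SD) is strictly maximal at t*, and t* is exposed.
  `paper_like`: ten dates spanning day-of-year 117–319, logistic leaf-flush
  and senescence trajectories per species with species-specific onset and
  autumn colours, and a U-shaped between-tree SD (12 → 3 at the third
  date → 12 DN). Within-species variance magnitudes per date are free
  parameters of the generator (no published per-date values exist), so
  validation asserts rankings and bounds, not absolute error levels.

What the generator does **not** emulate: photogrammetric artifacts (blur,
misregistration), crown shape irregularity, mixed pixels beyond the border
buffer, understory, inter-annual phenology shifts, or true camera spectral
response. Passing tests therefore demonstrate that the pipeline recovers
known statistical structure, not a particular accuracy on real imagery.

## Validation experiments and problem sizes

`phenocrown.validation` holds the standing self-checks, at desk scale:

- Chance-level and separability controls: 2-date worlds, 55 crowns per
  species on a 420×420-pixel (84 m) grid, full protocol defaults
  (20 × 500 trees, 50 per class). Expected: overall OOB ≈ 0.8 (five
  balanced classes) and ≈ 0, respectively.
- Optimal-window recovery: 10 independently seeded `planted_optimum`
  worlds, 6 dates, 55 crowns per species, reduced forest settings
  (200 trees, 5 repetitions, 50 per class) to keep the 41-scenario search
  per world tractable. Scored by the rate at which the planted date wins
  the single-date ranking and appears in the top-5 two- and three-date
  combinations, and by the mean best OOB error per family.

## Numerical choices and edge cases

- Determinism: one seed drives crown placement, offsets, noise, shadows,
  balanced samples and forests; a repeated run is byte-identical including
  the GeoTIFFs (no timestamps are written).
- Seeds derived anywhere in the package are reduced mod 2^31.
- Rasterization uses the pixel-center rule (0-based row/col, top-left
  origin); pixel centers exactly on a polygon boundary are outside.
- Degenerate inputs have stated conventions rather than exceptions where a
  value is representable: constant mosaics (relative intensity 100), zero
  index denominators (0, logged), zero GLCM marginal variance
  (correlation 0), empty narrowed crowns (dropped, logged).
- GeoTIFFs are written with ModelPixelScale/ModelTiepoint and a minimal
  GeoKeyDirectory (projected CRS, metre units); co-registration is enforced
  as exact grid identity, never fixed by resampling.

## Known limitations

- Crown vectors are read from GeoJSON only.
- The generator's crowns are circles; texture metrics on real, irregular
  crowns will differ in level (though not in contract).
- Multi-date search is limited to three dates, matching the question the
  pipeline answers; it is exhaustive, so cost grows combinatorially.
- OOB error is a model-comparison statistic here, not a validated accuracy
  estimate for mapping.
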