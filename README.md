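# phenocrown

Object-based discrimination of deciduous tree species from a *time series* of
very-high-resolution crown imagery — and, centrally, the question of **when**
to fly: which acquisition window(s) in the growing season separate the
species best.

The package is for remote-sensing and precision-forestry researchers who have
(or want to simulate) co-registered per-date orthomosaics (one RGB and one
colour-infrared 3-band stack per survey, ~0.2 m/pixel) plus manually
delineated crown polygons with species labels, and who want a reproducible,
testable implementation of the full analysis chain:

1. **Crown metrics** — each crown polygon is narrowed by a negative buffer
   (0.50 m) to drop border pixels; shadowed pixels are removed with a
   relative-intensity rule (intensity = ΣBGR min–max normalized to [0, 100]
   over the mosaic; pixels < 20 discarded); the sunlit pixels yield per-band
   mean/SD, band ratios, normalized bands, normalized-difference indices
   (NGRVI, NGBI, NRBI on RGB; NDVI, GNDVI, NGRVI on CIR), and seven GLCM
   texture statistics per band from an object-level, mask-aware
   co-occurrence matrix.
2. **Classification** — repeated, class-balanced Random Forests: before every
   forest, 50 crowns per species are drawn; 20 forests of 500 trees are
   fitted and scored by out-of-bag (OOB) misclassification error,

   `OOB = mean_r [ (1/n) Σ_i 1{ ŷ_i^{oob,r} ≠ y_i } ]`,

   where ŷ_i^{oob,r} is the majority vote of the trees in repetition *r*
   whose bootstrap sample excluded crown *i*.
3. **Date-combination search** — every single date, date pair and date trio
   (C(10,1)=10, C(10,2)=45, C(10,3)=120 scenarios for a 10-date campaign) is
   classified independently and ranked by averaged OOB error; single dates
   can additionally be split RGB-only / CIR-only / RGB+CIR.
4. **Synthetic phenology scenes** — a first-class generator renders worlds
   with the statistical structure the analysis assumes (species-wise 4-band
   spectra over the season, within-species variance that is minimal at the
   end of leaf flush, crown-level and pixel-level noise, cast shadows,
   luminosity gradients), including a `planted_optimum` preset whose optimal
   date t\* is known by construction — so the whole pipeline is testable as
   a parameter-recovery problem without any external data.

## Worked example

Simulate a planted-optimum world (6 dates, 2 cameras, 15 crowns per
species), extract the feature table, and rank all single dates:

```bash
phenocrown simulate --preset planted_optimum --seed 7 --out demo/world \
    --n-dates 6 --n-crowns-per-species 15 --grid-size 300
phenocrown extract --manifest demo/world/manifest.yaml --out demo/features.csv
phenocrown search --features demo/features.csv --manifest demo/world/manifest.yaml \
    --out demo/rank --families k1 --n-trees 200 --n-repetitions 5 \
    --n-per-class 12 --seed 7
```

which prints (output of this exact command sequence):

```
wrote 12 rasters and 75 crowns; manifest: demo/world/manifest.yaml
planted optimal date: s06
feature table: 75 crowns x 444 metric columns -> demo/features.csv (0 crowns dropped)
-- k1: 6 scenarios --
rank	scenario	cameras	overall	ash	birch	maple	oak	poplar
1	s06	RGB+CIR	0.0	0	0	0	0	0
2	s01	RGB+CIR	62.0	65	93	48	67	37
3	s05	RGB+CIR	62.0	50	77	63	55	65
4	s03	RGB+CIR	64.3	70	75	55	77	45
5	s02	RGB+CIR	81.3	85	82	93	78	68
```

Reading this: the generator planted its optimal window at survey `s06`
(wide between-species spacing, small within-species spread there), and the
ranking recovers it — `s06` classifies the five species with 0 % OOB error
while every other date sits near chance level for five classes (80 %). The
per-species columns are OOB errors in percent, and the console shows the
top 5 scenarios (`--top` controls this); the full ranking is written to
`demo/rank/k1.csv` and `demo/rank/k1.json`. On a `paper_like` world the same commands explore a
realistic seasonal trajectory instead, and `--families k1,k2,k3` ranks the
date pairs and trios; `phenocrown classify --compare-cameras` contrasts
RGB-only, CIR-only and combined feature sets for one survey.

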