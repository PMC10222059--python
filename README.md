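# popvuln

Population-level climate-change vulnerability analysis for narrowly
distributed plants: an ensemble habitat-suitability model, a standardized
per-cell **Climate Change Vulnerability Index (CCVI)**, a stem-length-based
demographic census summarizer, and the statistical layer linking demography
to vulnerability.

## The problem

Species distribution models (SDMs) tell us *where* a species' climate will
deteriorate, but rarely whether its existing populations are already
responding. For an endangered Andean sub-shrub censused exhaustively
(1615 plants in 13 populations), stem length is a field-measurable age
proxy (stems add ≈ 0.6 leaves per cm at ≈ 3 leaves per year, so
age ≈ length × 0.6 / 3), and plants with stems ≤ 30 cm are classed as
young. The analysis asks: do populations projected to lose climatic
suitability already show shorter adults and more juveniles?

The chain is:

1. **Ensemble SDM** — presences deduplicated to one valid occurrence per
   ~1 km grid cell; 5 random pseudo-absence scenarios × 15 repetitions of a
   stratified 70/30 calibration/test split; members kept only if their test
   True Skill Statistic (TSS = sensitivity + specificity − 1, at each
   member's best threshold) exceeds 0.8; suitability is the TSS-weighted
   member mean on a 0–1000 integer scale, binarized at the ensemble's
   minimum-suitable-habitat threshold.
2. **CCVI** — for each of 10 future scenarios (5 GCMs × SSP1-RCP2.6 /
   SSP5-RCP8.5), take the future suitability *s* over the present binary
   footprint and standardize against the survival minimum *c* (the
   binarization threshold):

   CCVI = −(s − c) / σ,

   with σ the sample sd of the footprint values. CCVI ≤ 0 means the cell
   stays suitable; positive values mean increasing vulnerability. Because
   it is standardized, the index is comparable across species and
   suitability scales.
3. **Demography** — per-population counts by life stage and reproductive
   status, stem-length mean/sd/skewness, occupied area (convex hull or
   alpha-shape), inter-plant distances, densities per hectare.
4. **Association** — linear models for continuous parameters
   (mean stem length ~ mean CCVI), count-weighted binomial GLMs for the
   young-plant proportion, and MM-type robust regression (S-estimate
   initialization, Tukey-bisquare refinement) for plant-level
   fruiting-stem-length relations; slopes carry 95% CIs for
   between-scenario comparison.

The field coordinates of the real species are withheld, so the package
ships a first-class synthetic-data generator (`popvuln.synth`) that
reproduces the statistical structure of the system — autocorrelated
climate layers with a latitudinal gradient, a narrow edge niche, directional
warming futures, and censuses whose mean stem length falls (β = −100 cm per
vulnerability unit) and young fraction rises with a geographically planted
vulnerability — plus the published per-population census table as a
deterministic fixture (`popvuln.table1`).

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
system and write their products under `results/`:

```bash
python analysis/01_simulate.py          # landscape, 10 futures, 1615-plant census
python analysis/02_select_predictors.py # |r| <= 0.7 then VIF < 10 filter
python analysis/03_fit_sdm.py           # ensemble protocol + projections
python analysis/04_ccvi.py              # per-plant / per-population CCVI
python analysis/05_demography.py        # census parameters per population
python analysis/06_associate.py         # demography ~ CCVI model battery
python analysis/07_reproduce_tables.py  # published-table checks
```

`03_fit_sdm.py` prints, for the default seed:

```
1615 plants -> 13 valid occurrences
60 members passed TSS > 0.8
pooled-test ensemble TSS 0.884; minimum-suitable-habitat threshold 113/1000
```

and `06_associate.py`:

```
model                            slope     stat         p    fit
mean_stem~ccvi_2055              -8.63 F= 14.40   0.00297  0.567
young_prop~ccvi_2055              0.22 Z=  5.22  1.82e-07  0.474
mean_stem~ccvi_ssp585            -8.11 F= 13.37   0.00378  0.549
young_prop~ccvi_ssp585            0.20 Z=  5.06   4.1e-07  0.449
fruiting_stem~ccvi_2055          -2.95 F= 15.54  9.47e-05  0.047
fruiting_stem~ccvi_ssp585        -2.75 F= 14.80  0.000138  0.044
```

Reading: the planted structure is recovered end-to-end — populations with a
higher computed CCVI have significantly shorter mean stems (negative slope)
and a significantly higher young-plant fraction (positive slope), and
fruiting plants are smaller where vulnerability is higher.

The same stages are scriptable via the `popvuln` CLI
(`simulate`, `select-vars`, `fit-sdm`, `project`, `ccvi`, `demography`,
`associate`, `reproduce-paper`), which compose through files from one seed.

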