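# metstab

Analysis pipeline for a durum wheat multi-environment trial (MET):
phenology-windowed environmental covariates, nested variance partitioning
of genotype effects into photoperiod-allele combinations vs.
within-combination earliness per se (Eps), BLUP-based isolation of the Eps
signal and its correlation with yield formation, a five-index
genotype-by-environment yield-stability analysis, and a correlation-matrix
PCA of environment characteristics. Because no field data are deposited,
the package ships a first-class synthetic trial generator that emulates
the study design (3 sites at 41.63° N / 27.35° N / 19.52° N × 5 years ×
23 genotypes in 5 allele combinations × 3 complete blocks) with fully
known ground truth, so every downstream stage is testable end to end.

## Layout

| module | contents |
|---|---|
| `metstab.data` | domain types (plots, genotypes, weather, experiments), CSV I/O, derived traits, two-way cell means |
| `metstab.simulate` | synthetic weather + trial generator with `SimTruth` ground truth |
| `metstab.covariates` | CBM day length (twilight coefficient), photo-thermal units, the 11 phenology-window covariates |
| `metstab.anova` | balanced combined ANOVA with the between/within-allele-combination split and custom error term; Fisher's protected LSD with compact letter display |
| `metstab.blup` | per-experiment REML mixed model (fixed combination, random genotype-within-combination and replicate), BLUP extraction, Pearson correlation tables |
| `metstab.stability` | Finlay–Wilkinson slope, Lin–Binns Pi, Shukla σ², Wricke ecovalence, Kang rank-sum YS with selection rule |
| `metstab.pca` | environment-level means table and correlation-matrix PCA with collinearity screen |
| `metstab.pipeline` / `metstab.cli` | end-to-end orchestration, config echo, report |

## CLI

```sh
# generate a complete synthetic trial (plots/genotypes/weather/experiments + truth.json)
metstab simulate --out data/ --seed 1

# individual stages
metstab envcov --plots data/plots.csv --genotypes data/genotypes.csv \
    --weather data/weather.csv --experiments data/experiments.csv --out covariates.csv
metstab anova --plots data/plots.csv --genotypes data/genotypes.csv \
    --trait gy_g_m2 --out anova.csv means.csv
metstab eps --plots data/plots.csv --genotypes data/genotypes.csv \
    --out blups.csv correlations.csv
metstab stability --plots data/plots.csv --genotypes data/genotypes.csv \
    --trait gy_g_m2 --out stability_genotype.csv stability_ac.csv
metstab pca --env-table env.csv --out scores.csv loadings.csv variance.csv

# everything at once, from simulation to report.md
metstab run --simulate --seed 1 --out met-run/
```

Runs are deterministic: the same seed and configuration produce
byte-identical CSV outputs.

## Notes on conventions

- Environments are site-year pairs, identified as `SITE-YEAR`.
- All phenology windows are closed intervals (both stage dates included).
- Day length uses the CBM model with a configurable solar-depression
  coefficient (default 6°, civil twilight). Photo-thermal units are
  degree-days above a configurable base (default 0 °C) times day length.
- The between-combination F-test uses the within-combination mean square
  as its denominator; every other source is tested against the residual,
  with denominators labelled in the output.
- Significance stars everywhere: `*` < 0.05, `**` < 0.01, `***` < 0.001,
  `ns` otherwise. Negative Shukla σ² values are reported as-is.
- Strict balance is the default: missing cells are hard errors; a lenient
  mode averages the available plots.
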