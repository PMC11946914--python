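# heatmargin

Phylogenetically informed imputation of ectotherm heat-tolerance limits and
microhabitat-explicit overheating-risk assessment, exercised end-to-end on
synthetic data.

The pipeline:

1. **simulate** — generate a Yule phylogeny, a heat-tolerance trait table
   with lambda-structured species effects and heavy missingness, species
   occurrence ranges on a 1° grid, and daily maximum operative
   body-temperature series per cell × microhabitat × warming scenario.
2. **impute** — chained-equation imputation (five cycles) built on a
   Bayesian phylogenetic mixed model with inverse-sampling-variance
   weights, phylogenetic + independent species intercepts, and
   acclimatization random slopes; species without data are predicted by
   the phylogenetic conditional (kriging) mean. Emits standardized
   CT_max predictions (mean and SE) at three reference acclimatization
   temperatures per species, plus Pagel's λ as the phylogenetic share of
   the non-residual variance.
3. **plasticity** — per-species inverse-variance-weighted meta-regression
   of standardized CT_max on acclimatization temperature (the
   acclimatization response ratio), then daily plasticity-adjusted CT_max
   from trailing 7-day mean temperatures.
4. **expose** — restrict daily series to the 91 warmest consecutive days
   of each year (first year dropped as burn-in), carrying trailing-week
   statistics computed on the unrestricted series; range-wide temperature
   percentiles per species.
5. **assess** — per local species occurrence: thermal safety margin
   (weighted mean ± SE), expected overheating-day count with binomial SE
   from daily normal exceedance probabilities (CT_max SE capped at 1 °C),
   and binary overheating risk. Sensitivity variants: weekly-max
   acclimatization, 95th-percentile/maximum-temperature TSM, trimmed
   series, biological-range σ cap, CI-based risk.
6. **aggregate** — 1° grid-cell assemblage summaries and headline ratio
   statistics.
7. **validate** — species-holdout cross-validation and a full
   parameter-recovery harness against the synthetic truth.

## CLI

```bash
heatmargin simulate --n-species 50 --seed 1 --out inputs/
heatmargin validate --traits inputs/traits.csv --tree inputs/tree.nwk
heatmargin impute --traits inputs/traits.csv --tree inputs/tree.nwk \
    --cycles 5 --seed 1 --out imputed.csv
heatmargin plasticity --imputed imputed.csv --out plasticity.csv
heatmargin expose --temps inputs/temps_terrestrial_current.csv --out exposure.csv
heatmargin assess --exposure exposure.csv --plasticity imputed.csv \
    --occurrences inputs/occurrences.csv --out vulnerability.csv
heatmargin aggregate --vulnerability vulnerability.csv --out assemblages.csv
heatmargin crossval --traits inputs/traits.csv --tree inputs/tree.nwk --frac 0.05 --seed 1
heatmargin recover --reps 5 --seed 1
heatmargin run --config run.yaml          # full pipeline from YAML
```

`run.yaml` is a serialized `RunConfig` (see `heatmargin.io`); with a
`simulate:` section the pipeline generates its own inputs first.

## Layout

```
src/heatmargin/
  phylo.py          tree I/O, lambda-scaled phylogenetic covariance
  simulate.py       synthetic data generators (tree, traits, ranges, temps)
  impute.py         Gibbs sampler + chained-equation imputation (BACE)
  plasticity.py     per-species ARR meta-regression, daily CT_max projection
  exposure.py       warmest-quarter selection, trailing-week stats, percentiles
  vulnerability.py  TSM, exceedance probabilities, day counts, binary risk
  assemblage.py     grid-cell aggregation and headline ratios
  validation.py     holdout cross-validation, parameter-recovery harness
  io.py             schema-validated readers/writers, RunConfig, manifests
  pipeline.py       end-to-end orchestration
  cli.py            click command group
```
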