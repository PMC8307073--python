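# iwqi

Integrated-weight groundwater quality assessment toolkit.

The package scores water samples with an integrated water quality index
(IWQI) whose parameter weights combine two sources:

* **subjective weights** from Shannon entropy of the measured sample matrix;
* **objective weights** from a stochastic-simulation ensemble (default 2000
  draws) over the per-parameter mean/SD of a literature weight database
  (a 22-study, 14-parameter database ships with the package).

The two are fused through a preference coefficient `G` into the convex
combination `W = G*W_s + (1-G)*W_o`, samples are rated per parameter as
`Q = 100*(C - C_ideal)/(T - C_ideal)` against configurable standards, scored
as `sum_j W_j Q_j`, and classified into five bands (<25 excellent to >100
extremely poor). Supporting machinery includes:

* a charge-balance-error quality gate (|CBE| < 5% by default);
* index-removal sensitivity analysis that reruns the full weighting pipeline
  per left-out parameter;
* hydrochemical diagnostics: meq/L conversion, per-season descriptive
  statistics with exceedance rates, Piper trilinear coordinates and facies
  labels, Gibbs ratios with a coarse provenance-zone heuristic, and the six
  ion-ratio source-attribution panels with a fitted cation-exchange slope;
* a synthetic sample generator (truncated-normal marginals, optional rank
  correlation) seeded with the published two-season 28-well summary table,
  plus a noise-controlled cation-exchange fixture.

## CLI

Every pipeline stage is independently invocable via the `iwqi` entry point:

```sh
# generate a synthetic 28-sample table matching the packaged dry-season marginals
iwqi simulate --season dry --n-samples 28 --seed 1 --out samples.csv

# weight vectors only (entropy, simulated, integrated)
iwqi weights --samples samples.csv --n-sims 2000 --seed 1 --out weights.csv

# scores + classes
iwqi score --samples samples.csv --seed 1 --out scores.csv

# index-removal sensitivity
iwqi sensitivity --samples samples.csv --seed 1 --out sensitivity.csv

# Piper/Gibbs/ion-ratio diagnostics bundle
iwqi diagnostics --samples samples.csv --out diag/

# everything, with a provenance manifest
iwqi run --samples samples.csv --seed 1 --out bundle/
```

Common flags: `--weights-db PATH` (literature CSV; default: packaged
database), `--standards PATH` (YAML; default: packaged values),
`--n-sims`, `--seed`, `--season {dry,wet,all}`,
`--negative-policy {clip,resample}`, `--threshold-cbe FLOAT`.

Note that the synthetic generator draws ion columns independently, so
generated tables generally do **not** pass the 5% charge-balance gate;
raise `--threshold-cbe` when scoring synthetic data end to end.

## File formats

* **Sample CSV** — header `sample_id,season,<14 parameter columns>`
  (`pH,TDS,TH,Ca,Na,Mg,K,Fe,HCO3,SO4,Cl,NO3_N,F,NO2_N`), mg/L except pH;
  optional `x,y` coordinate columns. NO3_N/NO2_N are nitrogen-mass
  concentrations and are converted to ion mass internally.
* **Weight database CSV** — rows = studies, columns = `study` label + the 14
  parameter names, blank = the study did not weight that parameter.
* **Standards YAML** — `parameter: {T, C_ideal, limit}`; see
  `src/iwqi/data/default_standards.yaml`.

All report CSVs carry a commented provenance header (seed, config hash,
input paths).

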