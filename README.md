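# synsurv

Synthetic survival cohorts for registry-based cancer epidemiology:
decomposable log-linear graphical models fitted to a categorical cohort,
junction-tree simulation of large synthetic datasets, integrated-Brier-score
selection of the best per-stratum synthetic subsets, and a Bayesian
relative-survival model producing excess-mortality and crude-probability-of-
death indicators with credible intervals.

## What is in the box

| module | role |
| --- | --- |
| `synsurv.cohort_io` | Domain types (`PatientRecord`, `LifeTable`), eligibility filtering with an exclusion report, CSV readers/writers, reporting arithmetic |
| `synsurv.synth_registry` | Seeded registry-like cohort simulator with known ground truth (categorical covariates, additive excess hazard on top of a Gompertz life table, annual grid, administrative censoring at 10 years) |
| `synsurv.gm_engine` | Contingency tables, IPF fitting of decomposable models, backward stepwise edge elimination (penalties k = 1, 2, log N and a chi-square deletion test), conditional imputation, junction-tree forward sampling |
| `synsurv.comsynsur` | Kaplan–Meier and censoring-distribution estimation, censoring-weighted Brier score and IBS, age × stage partitioning, per-stratum argmin selection and merging |
| `synsurv.relsurv_bayes` | O/E/Y hazard series from a life table, Poisson model with a Gaussian random-walk prior on log-hazard offsets (blocked Metropolis, split-R̂/ESS diagnostics), posterior OS/RS/CRS/EM/PCa/POC |
| `synsurv.pipeline` / `synsurv.cli` | One-command orchestration with per-stage seed derivation and a run manifest |

## CLI

```bash
# simulate a registry-like cohort + matching life table
synsurv simulate-cohort --config registry.yaml --out cohort.csv --lifetable lt.csv

# fit one graphical model (k1 | aic | bic | test)
synsurv fit-gm cohort.csv --criterion aic --out model.json

# sample a synthetic dataset from the model's junction tree
synsurv simulate-syn model.json --n 1000000 --seed 1 --out synd.csv --reference cohort.csv

# score synthetic datasets per age×stage stratum and merge the IBS winners
synsurv combine cohort.csv synd_k1.csv synd_test.csv synd_aic.csv synd_bic.csv \
    --tstar 10 --out combined.csv --report scores.csv

# Bayesian relative-survival indicators
synsurv relsurv combined.csv --lifetable lt.csv --draws 5000 --warmup 5000 \
    --chains 4 --seed 1 --by age_group,stage,adherence --out indicators.csv

# or everything at once from a YAML config
synsurv pipeline --config pipeline.yaml
```

A pipeline YAML lists `cohort_path`, `lifetable_path`, `output_dir`,
`synd_size`, `mcmc_draws`, `mcmc_warmup`, `mcmc_chains`, `master_seed` and
optionally `by`. Every stage derives its own seed from the master seed, and
the run manifest records all of them, so reruns are bit-identical.

## Conventions worth knowing

- Follow-up lives on a discrete annual grid (years 1..10); administrative
  censoring at 10 years.
- Censoring-distribution Kaplan–Meier uses the deaths-before-censorings
  risk-set convention; Brier weights are 1/G(tᵢ⁻) for deaths and 1/G(t) for
  survivors (the variant dividing both terms by G(t) is available behind
  `printed_variant=True` for sensitivity checks).
- Expected deaths give half a person-year to subjects exiting inside an
  interval and a full year to subjects censored alive at the horizon.
- The random-walk prior is parameterized by precision 0.001 (variance 1000).
- Crude probabilities of death use the exact constant-hazard within-interval
  average of OS, making PCa(T) + POC(T) = 1 − OS(T) an exact identity.
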