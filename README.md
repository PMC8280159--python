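# dlnmkit

Distributed lag non-linear modelling (DLNM) of registry count data with
lagged exposure histories.

The package fits a negative-binomial GLM whose log mean combines a
population-at-risk offset, an exposure-lag **cross-basis** (natural cubic
splines over exposure and lag, tensor-product summed over each stratum's
lagged exposure history), and categorical covariates (country, age group,
gender, outcome year, age×gender). The lag basis excludes its intercept and
is anchored at lag 0, so the predicted incidence rate ratio (IRR) is exactly
1 at lag 0. Standard errors are cluster-robust (sandwich estimator, registry
clusters). Effects are reported from the backward perspective as IRR and
cumulative IRR surfaces relative to a reference exposure level (default
50%), with delta-method confidence intervals, plus "what-if" scenario
calculations for sustained or time-varying exposure changes. Model adequacy
is checked with simulation-based scaled (quantile) residuals, and candidate
models are compared by AIC.

## Layout

| module | purpose |
| --- | --- |
| `dlnmkit.data` | stratum records, CSV IO, cohort-matched lagged exposure histories |
| `dlnmkit.splines` | restricted cubic (natural) spline bases, knot placement |
| `dlnmkit.crossbasis` | cross-basis matrix and point-basis vectors |
| `dlnmkit.negbin` | NB2 GLM (IRLS + ML dispersion), design assembly, AIC comparison |
| `dlnmkit.cluster` | cluster-robust sandwich covariance |
| `dlnmkit.effects` | IRR / cumulative-IRR surfaces, scenarios |
| `dlnmkit.diagnostics` | randomized-PIT residuals, QQ tables |
| `dlnmkit.simulate` | synthetic registry panels with a known true surface |
| `dlnmkit.cli` | `dlnmkit` command-line pipeline |
| `dlnmkit.bundle` | YAML fit-bundle serialization |

## CLI

```sh
# synthetic end-to-end run (simulate -> fit -> predict -> diagnose)
dlnmkit run --seed 1 --outdir out/

# or stage by stage, with your own data
dlnmkit simulate --seed 1 --outdir out/
dlnmkit fit --strata out/strata.csv --panel out/panel.csv --outdir out/
dlnmkit predict --bundle out/fit_bundle.yaml --outdir out/ --reference 50
dlnmkit scenario --bundle out/fit_bundle.yaml --outdir out/ --new 40 --horizon 10
dlnmkit diagnose --bundle out/fit_bundle.yaml --strata out/strata.csv \
    --panel out/panel.csv --outdir out/ --seed 1
```

Inputs are plain CSV: a long-format strata table (`country, registry,
age_group, gender, outcome_year, cases, population`; columns renamable via a
YAML schema config) and a prevalence panel (`country, gender, age_band,
year, prevalence`). Outputs are tidy CSV tables, a YAML fit bundle, PNG
figures and a pipeline log; runs are deterministic given config + seed.

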