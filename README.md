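# edudist

Estimation and forecasting of within-population single-year distributions of
educational attainment (0–18 completed years, top-coded at 18), from
heterogeneous survey/census tabulations.

The package implements a multi-stage pipeline:

1. **synthetic** — generates a synthetic world (logistic cohort growth of
   attainment per country–sex, mixture-shaped distributions) and simulated
   survey tabulations with provider biases, age-binned reporting and
   multinomial sampling noise, so every stage can be tested by parameter
   recovery without any external data.
2. **adjust** — removes systematic inter-provider biases with a mixed-effects
   regression on the logit scale (random provider intercepts plus nested
   location:provider intercepts), referencing regional/location gold-standard
   providers.
3. **cohort** — builds all qualifying repeat cohort observation pairs
   (≤ 10 years apart, both after 1990, ages ≥ 25), removes per-survey-pairing
   inter-wave bias (average annual change of cohorts aged 60–70), fits a
   natural-spline aging model (knot at age 70, location-within-super-region
   intercepts), and extrapolates every observation across ages/years.
4. **ageperiod** — per sex × region mixed model (secular trend, age spline
   with knots at 45 and 65, country–age random intercepts) producing a
   complete 1970–2018 prior surface.
5. **gpr** — exact Gaussian process regression of the prior residuals over
   calendar time with a Matérn covariance (ν = 2, ℓ = 40), amplitude from
   super-region × sex residual pools, per-point noise from squared standard
   errors plus extrapolation error; 1,000 antithetic posterior draws by
   default.
6. **ensemble** — reconstructs the full 19-bin distribution per
   location–age–sex–year and draw: Mahalanobis K-nearest-neighbour search
   (K = 80) over the library of observed distributions on
   (logit(mean/18), logit(prop₀)) features, distance weights from age,
   cohort and spatial closeness (P_age = 0.25, P_cohort = 0.85,
   P_space = 0.7, ψ = 2.5), then per-bin Loess smoothing (span 0.5).
7. **forecast** — projects each bin to 2030 with the average annual logit
   rate of change over the last 15 years, renormalizing yearly; staged start
   years by age group (2019 / 2024 / 2029).
8. **metrics** — attainment proportions (≥ 6/12/15 years), mean years,
   male−female gaps with primary/secondary/tertiary decomposition, the
   average interpersonal difference (AID) and the Gini coefficient
   (AID = 2 · mean · Gini exactly), with population-weighted aggregation and
   percentile uncertainty intervals over draws.
9. **pipeline** — orchestration with a single seed driving all randomness,
   CSV stage interfaces, a CLI, and an out-of-sample block-holdout
   validation harness.

## CLI

```sh
# full synthetic run, all artifacts as CSV in out/
edudist run-all --workdir out/ --seed 1

# or stage by stage from a config file
edudist simulate  --config run.cfg --workdir out/
edudist adjust    --config run.cfg --workdir out/
edudist cohort    --config run.cfg --workdir out/
edudist ageperiod --config run.cfg --workdir out/
edudist gpr       --config run.cfg --workdir out/

# out-of-sample block-holdout validation
edudist validate --seed 1 --out holdout.csv
```

`run.cfg` is a plain-text `key = value` file mirroring the fields of
`edudist.pipeline.RunConfig` (all hyperparameter defaults as documented
above).  Every stage reads only its predecessor's CSV, so any stage can be
re-run in isolation.

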